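"""End-to-end orchestration: interactions → network → centralities →
expression → enrichment → ranking, from one validated config.

`run_all` executes the full workflow and leaves a self-describing run
directory: every stage output as TSV/SIF plus a JSON manifest recording
input checksums, the seed and the package version, so a rerun with the same
config is byte-comparable.  `replay_fixture` is the shortcut entry point
that rebuilds a ranking directly from a published table of printed folds
and summed degrees (bypassing the graph and expression stages); the
packaged ``table3.tsv`` fixture holds the published top-25 ranking this
package reproduces.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, FormatError, StageError
from . import expression as expr
from . import interactions as inter
from . import network as net
from . import ranking as rk
from . import stats as st

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "replay_fixture", "table3_path"]


@dataclass
class RunConfig:
    """Validated configuration of one full run (flat YAML document)."""

    interactions: list[dict] = field(default_factory=list)  # [{path, source}, ...]
    graph: str = ""
    plates: str = ""
    universe: str | None = None
    gene_sets: str | None = None
    reference: str = "P69"
    case: str = "M12"
    calibrator: str = "cal-spike"
    min_fold: float = 2.0
    extreme_fold: float = 8.0
    degree_threshold: str | float = "mean"
    min_sum_degree: float = 1000.0
    alpha: float = 0.05
    seed: int = 1
    seed_network_mode: str = "induced"
    max_bridge_len: int = 2
    degrees_from: str = "global"  # "global" | "seed-network"
    n_perm: int = 999

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not self.interactions:
            raise ConfigError("config needs at least one interactions entry")
        for entry in self.interactions:
            if "path" not in entry or "source" not in entry:
                raise ConfigError("each interactions entry needs 'path' and 'source'")
        for label, p in [("graph", self.graph), ("plates", self.plates)]:
            if not p:
                raise ConfigError(f"config key '{label}' is required")
        paths = [e["path"] for e in self.interactions] + [self.graph, self.plates]
        paths += [p for p in (self.universe, self.gene_sets) if p]
        for p in paths:
            if not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        for name in ("min_fold", "extreme_fold", "alpha", "min_sum_degree"):
            if float(getattr(self, name)) <= 0:
                raise ConfigError(f"config key '{name}' must be positive")
        if self.degrees_from not in ("global", "seed-network"):
            raise ConfigError("degrees_from must be 'global' or 'seed-network'")
        if isinstance(self.degree_threshold, str) and self.degree_threshold != "mean":
            raise ConfigError("degree_threshold must be 'mean' or a number")

    def threshold(self) -> rk.DegreeThreshold:
        if self.degree_threshold == "mean":
            return rk.DegreeThreshold("mean")
        return rk.DegreeThreshold("fixed", float(self.degree_threshold))


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_all(cfg: RunConfig, out_dir: str | Path) -> Path:
    """Run the full workflow; returns the run directory.

    On a stage failure the partial outputs are moved under ``failed/`` and a
    :class:`StageError` naming the stage is raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}
    stage = "setup"
    try:
        stage = "interactions"
        tables = [
            inter.load_interactions(e["path"], e["source"]) for e in cfg.interactions
        ]
        table = inter.merge_tables(tables)
        if cfg.universe:
            table = inter.filter_by_universe(table, inter.read_universe(cfg.universe))
        inter.write_interactions(table, out / "merged_interactions.tsv")
        artifacts["merged_interactions"] = "merged_interactions.tsv"

        stage = "network"
        global_graph = net.load_graph(cfg.graph)
        seeds = table.genes() & set(global_graph.nodes())
        seed_graph = net.build_seed_network(
            global_graph, seeds, mode=cfg.seed_network_mode, max_bridge_len=cfg.max_bridge_len
        )
        background = set(global_graph.nodes())
        random_seeds = st.sample_random_proteins(background, len(seeds), seed=cfg.seed)
        random_graph = net.build_seed_network(
            global_graph, random_seeds, mode=cfg.seed_network_mode, max_bridge_len=cfg.max_bridge_len
        )
        net.write_graph(seed_graph, out / "seed_network.sif", fmt="sif")
        net.write_graph(random_graph, out / "random_network.sif", fmt="sif")
        artifacts["seed_network"] = "seed_network.sif"
        artifacts["random_network"] = "random_network.sif"

        stage = "centralities"
        prof_t = net.centrality_profile(seed_graph, "targets")
        prof_r = net.centrality_profile(random_graph, "random")
        prof_t.to_frame().to_csv(out / "centralities_targets.tsv", sep="\t", index=False)
        prof_r.to_frame().to_csv(out / "centralities_random.tsv", sep="\t", index=False)
        artifacts["centralities_targets"] = "centralities_targets.tsv"
        artifacts["centralities_random"] = "centralities_random.tsv"
        comparison = st.compare_networks(prof_t, prof_r, n_perm=cfg.n_perm, seed=cfg.seed)
        pd.DataFrame([vars(c) for c in comparison]).to_csv(
            out / "network_comparison.tsv", sep="\t", index=False
        )
        artifacts["network_comparison"] = "network_comparison.tsv"

        stage = "expression"
        ct = expr.load_ct(cfg.plates)
        ct = expr.interplate_calibrate(ct, cfg.calibrator)
        dct = expr.global_mean_normalize(ct)
        fct = expr.fold_changes(dct, cfg.reference, cfg.case, min_fold=cfg.min_fold)
        expr.write_fold_changes(fct, out / "fold_changes.tsv")
        artifacts["fold_changes"] = "fold_changes.tsv"
        report = expr.dysregulation_report(fct, extreme_threshold=cfg.extreme_fold)

        stage = "enrichment"
        if cfg.gene_sets:
            dys = fct.summary.index[fct.summary["dysregulated"]]
            query = set()
            for mirna in dys:
                query |= inter.targets_of(table, mirna)
            results = st.hypergeometric_enrichment(
                query, st.read_gmt(cfg.gene_sets), background, alpha=cfg.alpha
            )
            st.write_enrichment(results, out / "enrichment.tsv")
            artifacts["enrichment"] = "enrichment.tsv"

        stage = "ranking"
        degree_graph = global_graph if cfg.degrees_from == "global" else seed_graph
        degrees = net.degree_centrality(degree_graph)
        ranking = rk.rank_mirnas(fct, table, degrees, threshold=cfg.threshold())
        rk.write_ranking(ranking, out / "ranking.tsv")
        artifacts["ranking"] = "ranking.tsv"
        rk.export_quadrant_plot_data(ranking).to_csv(
            out / "quadrant_plot.tsv", sep="\t", index=False
        )
        artifacts["quadrant_plot"] = "quadrant_plot.tsv"
        candidates = rk.select_candidates(ranking, cfg.min_sum_degree)

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config": dataclasses.asdict(cfg),
            "inputs": {
                str(p): _sha256(p)
                for p in [e["path"] for e in cfg.interactions]
                + [cfg.graph, cfg.plates]
                + [x for x in (cfg.universe, cfg.gene_sets) if x]
            },
            "artifacts": artifacts,
            "summary": {
                "n_interactions": len(table),
                "n_dysregulated": report.n_dysregulated,
                "n_oncomirs": report.n_oncomirs,
                "n_suppressors": report.n_suppressors,
                "n_extreme": report.n_extreme,
                "candidates": candidates,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        failed = out / "failed"
        failed.mkdir(exist_ok=True)
        for name in artifacts.values():
            src = out / name
            if src.exists():
                shutil.move(str(src), failed / name)
        logger.error("stage '%s' failed: %s", stage, exc)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc
    return out


def table3_path() -> Path:
    """Path of the packaged published top-25 ranking fixture."""
    return Path(resources.files("mirdegree").joinpath("data/table3.tsv"))


def replay_fixture(
    fixture: str | Path | None = None,
    min_sum_degree: float = 1000.0,
    threshold: rk.DegreeThreshold | None = None,
) -> rk.MiRNARanking:
    """Rebuild a ranking from a table of printed folds and summed degrees.

    Expected TSV columns: ``mirna``, ``fold``, ``sum_degree`` (an optional
    ``mir2disease`` flag column is carried through unused).  With no
    argument the packaged published fixture is replayed.
    """
    path = Path(fixture) if fixture is not None else table3_path()
    try:
        df = pd.read_csv(path, sep="\t", dtype={"mirna": str})
    except Exception as exc:
        raise FormatError(f"cannot parse fixture {path}: {exc}") from exc
    for col in ("mirna", "fold", "sum_degree"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    try:
        records = [
            (inter.normalize_mirna_id(m), float(f), float(d))
            for m, f, d in zip(df["mirna"], df["fold"], df["sum_degree"])
        ]
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric fold or sum_degree: {exc}") from exc
    ranking = rk.ranking_from_records(records, threshold=threshold)
    n_cand = len(rk.select_candidates(ranking, min_sum_degree))
    logger.info("replayed %d miRNAs, %d candidates above %.0f", len(ranking), n_cand, min_sum_degree)
    return ranking
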