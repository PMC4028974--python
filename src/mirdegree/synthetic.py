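"""Synthetic inputs for every pipeline stage: scale-free PPI graphs,
hub-biased miRNA→target maps, and two-condition duplicate qPCR plates with
planted fold changes.

The generator emulates the statistical structure of the real study inputs
rather than any particular database: a preferential-attachment (scale-free)
protein network, miRNAs that pick targets with probability proportional to
``(degree + 1) ** hub_bias_alpha`` (``alpha = 0`` is the uniform null,
``alpha = 1`` plants the hub preference the method is designed to detect),
and Ct plates built as ``baseline + plate offset − planted log2 effect
(case sample only) + Gaussian noise``, with a noise-free spike-in
calibrator per plate and values above the detection limit emitted as
undetected.

Everything is a pure function of the spec: the same
:class:`SyntheticSpec` yields byte-identical outputs.  Randomness flows
from the single ``seed`` through independent named substreams (graph /
targets / plates), so regenerating one artifact never perturbs another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConfigError
from .interactions import InteractionRecord, InteractionTable

__all__ = [
    "SyntheticSpec",
    "generate_ppi",
    "assign_targets",
    "balanced_log2fc",
    "generate_plates",
    "write_synthetic_inputs",
]

REFERENCE_SAMPLE = "P69"
CASE_SAMPLE = "M12"
REPLICATES = ("rep25", "rep50")  # duplicate RNA inputs, as on the real arrays
CALIBRATOR_ID = "cal-spike"
_CAL_BASELINE_CT = 20.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset (see module docstring)."""

    n_nodes: int = 500
    edges_per_new_node: int = 2
    n_mirnas: int = 40
    targets_per_mirna: int = 10
    hub_bias_alpha: float = 1.0
    planted_log2fc: Mapping[str, float] = field(default_factory=dict)
    ct_noise_sd: float = 0.2
    plate_offsets: Mapping[str, float] = field(default_factory=dict)
    detection_limit: float = 37.0
    seed: int = 1

    def __post_init__(self):
        if self.n_nodes <= self.edges_per_new_node or self.edges_per_new_node < 1:
            raise ConfigError("need n_nodes > edges_per_new_node >= 1")
        if min(self.n_mirnas, self.targets_per_mirna) < 1:
            raise ConfigError("counts must be positive")
        if self.targets_per_mirna > self.n_nodes:
            raise ConfigError("targets_per_mirna cannot exceed n_nodes")
        if self.ct_noise_sd < 0 or self.hub_bias_alpha < 0:
            raise ConfigError("ct_noise_sd and hub_bias_alpha must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])

    def mirna_ids(self) -> list[str]:
        width = len(str(self.n_mirnas))
        return [f"sim-miR-{i + 1:0{width}d}" for i in range(self.n_mirnas)]


def generate_ppi(spec: SyntheticSpec) -> nx.Graph:
    """Connected preferential-attachment graph over symbols G0001..G<n>."""
    graph_seed = int(np.random.SeedSequence([spec.seed, 0]).generate_state(1)[0] % 2**31)
    g = nx.barabasi_albert_graph(spec.n_nodes, spec.edges_per_new_node, seed=graph_seed)
    width = len(str(spec.n_nodes))
    return nx.relabel_nodes(g, {i: f"G{i + 1:0{width}d}" for i in g.nodes()})


def assign_targets(g: nx.Graph, spec: SyntheticSpec) -> InteractionTable:
    """Sample each miRNA's targets without replacement, hub-biased by alpha.

    Inclusion probability is proportional to ``(degree + 1) ** alpha``; the
    +1 keeps isolated nodes sampleable.
    """
    rng = spec.rng(1)
    nodes = sorted(g.nodes())
    weights = np.array([(g.degree(v) + 1) ** spec.hub_bias_alpha for v in nodes], dtype=float)
    probs = weights / weights.sum()
    records = []
    for mirna in spec.mirna_ids():
        chosen = rng.choice(len(nodes), size=spec.targets_per_mirna, replace=False, p=probs)
        for i in sorted(chosen):
            records.append(InteractionRecord(mirna, nodes[i], frozenset({"synthetic"})))
    return InteractionTable(records=records)


def balanced_log2fc(
    mirna_ids: Sequence[str],
    n_up: int,
    n_down: int,
    magnitude: float = 2.0,
) -> dict[str, float]:
    """Direction-balanced planted effects: first ``n_up`` ids up by
    ``magnitude`` log2 units, next ``n_down`` down, the rest null.

    With ``n_up == n_down`` the planted effects cancel in the per-sample
    mean, so global-mean normalisation recovers them without bias — the
    synthetic counterpart of "most miRNAs are unchanged".
    """
    if n_up + n_down > len(mirna_ids):
        raise ConfigError("more planted effects than miRNAs")
    effects = dict.fromkeys(mirna_ids, 0.0)
    for m in mirna_ids[:n_up]:
        effects[m] = magnitude
    for m in mirna_ids[n_up : n_up + n_down]:
        effects[m] = -magnitude
    return effects


def plate_ids() -> list[str]:
    return [f"{s}_{r}" for s in (REFERENCE_SAMPLE, CASE_SAMPLE) for r in REPLICATES]


def generate_plates(spec: SyntheticSpec, mirna_ids: Sequence[str] | None = None) -> pd.DataFrame:
    """Ct plates for two samples x duplicate inputs, one plate each.

    Per miRNA: a baseline Ct ~ U(18, 28) shared across plates; the case
    sample's Ct is lowered by the planted log2 fold change (one PCR cycle
    per twofold change).  The calibrator is emitted noise-free so plate
    offsets are exactly recoverable.  Ct values above ``detection_limit``
    become undetected (NaN).
    """
    mirna_ids = list(mirna_ids) if mirna_ids is not None else spec.mirna_ids()
    unknown = set(spec.planted_log2fc) - set(mirna_ids)
    if unknown:
        raise ConfigError(f"planted_log2fc refers to unknown miRNAs: {sorted(unknown)[:3]}")
    rng = spec.rng(2)
    baselines = dict(zip(mirna_ids, rng.uniform(18.0, 28.0, size=len(mirna_ids))))
    rows = []
    for sample in (REFERENCE_SAMPLE, CASE_SAMPLE):
        for rep in REPLICATES:
            plate = f"{sample}_{rep}"
            offset = float(spec.plate_offsets.get(plate, 0.0))
            for mirna in mirna_ids:
                effect = spec.planted_log2fc.get(mirna, 0.0) if sample == CASE_SAMPLE else 0.0
                ct = baselines[mirna] + offset - effect + rng.normal(0.0, spec.ct_noise_sd)
                rows.append((plate, sample, rep, mirna, ct if ct < spec.detection_limit else np.nan))
            rows.append((plate, sample, rep, CALIBRATOR_ID, _CAL_BASELINE_CT + offset))
    return pd.DataFrame(rows, columns=["plate_id", "sample_id", "replicate_id", "mirna_id", "ct"])


def write_synthetic_inputs(spec: SyntheticSpec, out_dir: str | Path) -> dict[str, Path]:
    """Write graph (SIF), interactions (TSV), plates (TSV) and a ground-truth
    manifest (TSV) for test harnesses; returns the path of each artifact."""
    from .expression import write_ct
    from .interactions import write_interactions
    from .network import write_graph

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g = generate_ppi(spec)
    table = assign_targets(g, spec)
    plates = generate_plates(spec)
    paths = {
        "graph": out / "ppi.sif",
        "interactions": out / "interactions.tsv",
        "plates": out / "plates.tsv",
        "truth": out / "ground_truth.tsv",
    }
    write_graph(g, paths["graph"], fmt="sif")
    write_interactions(table, paths["interactions"])
    write_ct(plates, paths["plates"])
    truth = pd.DataFrame(
        {
            "mirna": spec.mirna_ids(),
            "planted_log2fc": [spec.planted_log2fc.get(m, 0.0) for m in spec.mirna_ids()],
        }
    )
    truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths
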