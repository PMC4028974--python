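"""Rank dysregulated miRNAs by the summed PPI degree of their targets.

The score of a miRNA is the plain sum of node degrees over its validated
targets that appear in the chosen PPI graph — a proxy for how much
regulatory leverage the miRNA holds over the proteome.  Ranked miRNAs fall
into four quadrants of the expression-vs-connectivity plane: the horizontal
split is a degree threshold (by default the mean summed degree over the
ranked set), the vertical split is log10 fold change = 0, separating
oncomiRs (up in the case condition) from candidate tumour suppressors
(down).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError
from .expression import FoldChangeTable
from .interactions import InteractionTable, targets_of

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeThreshold",
    "MiRNARanking",
    "sum_target_degree",
    "rank_mirnas",
    "select_candidates",
    "export_quadrant_plot_data",
    "plot_quadrants",
    "write_ranking",
]

RANKING_COLUMNS = [
    "mirna_id",
    "fold",
    "log10_fc",
    "n_targets_in_network",
    "sum_degree",
    "quadrant",
    "rank",
]


@dataclass
class DegreeThreshold:
    """Horizontal quadrant split: 'mean' of the ranked set, or a fixed value."""

    method: str = "mean"  # "mean" | "fixed"
    value: float | None = None

    def resolve(self, sum_degrees: Sequence[float]) -> float:
        if self.method == "mean":
            if len(sum_degrees) == 0:
                return 0.0
            return float(sum(sum_degrees) / len(sum_degrees))
        if self.method == "fixed":
            if self.value is None:
                raise ConfigError("fixed degree threshold needs a value")
            return float(self.value)
        raise ConfigError(f"unknown threshold method '{self.method}'")


@dataclass
class MiRNARanking:
    """Ranked table (one row per dysregulated miRNA) plus the resolved threshold."""

    table: pd.DataFrame  # RANKING_COLUMNS, sorted by rank
    degree_threshold: float

    def __len__(self) -> int:
        return len(self.table)


def sum_target_degree(
    mirna_id: str,
    interactions: InteractionTable,
    degrees: Mapping[str, int],
) -> tuple[int, int]:
    """(summed degree, number of targets present) for one miRNA.

    Targets absent from the degree map contribute 0 and are not counted.
    """
    targets = targets_of(interactions, mirna_id)
    in_net = [t for t in targets if t in degrees]
    return sum(int(degrees[t]) for t in in_net), len(in_net)


def _quadrant(sum_degree: float, log10_fc: float, threshold: float) -> str:
    vertical = "high" if sum_degree > threshold else "low"
    horizontal = "onco" if log10_fc > 0 else "supp"
    return f"{vertical}-{horizontal}"


def _assemble(rows: list[dict], threshold: DegreeThreshold) -> MiRNARanking:
    df = pd.DataFrame(rows, columns=RANKING_COLUMNS[:-2])
    resolved = threshold.resolve(df["sum_degree"].tolist())
    if df.empty:
        logger.warning("ranking an empty dysregulated set")
        df["quadrant"] = pd.Series(dtype=str)
        df["rank"] = pd.Series(dtype=int)
        return MiRNARanking(table=df, degree_threshold=resolved)
    df["quadrant"] = [
        _quadrant(sd, lfc, resolved) for sd, lfc in zip(df["sum_degree"], df["log10_fc"])
    ]
    df = df.sort_values(
        by=["sum_degree", "mirna_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = range(1, len(df) + 1)
    return MiRNARanking(table=df, degree_threshold=resolved)


def rank_mirnas(
    fct: FoldChangeTable,
    interactions: InteractionTable,
    degrees: Mapping[str, int],
    threshold: DegreeThreshold | None = None,
) -> MiRNARanking:
    """Score and rank every dysregulated miRNA of a fold-change table.

    Rank 1 is the largest summed degree; ties break lexicographically on the
    miRNA id so ranks are bit-stable.  A "mean" threshold is resolved over
    the ranked set before quadrants are assigned.  miRNAs whose consensus
    fold is undefined (discordant dropouts) are excluded.
    """
    threshold = threshold or DegreeThreshold("mean")
    dys = fct.summary[fct.summary["dysregulated"]]
    dys = dys[dys["log10_fc"].notna()]
    rows = []
    for mirna, rec in dys.iterrows():
        sd, n_in = sum_target_degree(mirna, interactions, degrees)
        rows.append(
            {
                "mirna_id": mirna,
                "fold": rec["fc_consensus"],
                "log10_fc": rec["log10_fc"],
                "n_targets_in_network": n_in,
                "sum_degree": sd,
            }
        )
    return _assemble(rows, threshold)


def ranking_from_records(
    records: Sequence[tuple[str, float, float]],
    threshold: DegreeThreshold | None = None,
    fc_cap: float = 2.0**12,
) -> MiRNARanking:
    """Build a ranking directly from (mirna_id, fold, sum_degree) triples.

    Used to replay published tables where folds and degrees are given rather
    than computed; a printed fold of 0 (case-side dropout) enters with
    log10 fold at the floored cap, matching :mod:`mirdegree.expression`.
    """
    threshold = threshold or DegreeThreshold("mean")
    rows = []
    for mirna, fold, sum_degree in records:
        log10_fc = math.log10(fold) if fold > 0 else -math.log10(fc_cap)
        rows.append(
            {
                "mirna_id": mirna,
                "fold": float(fold),
                "log10_fc": log10_fc,
                "n_targets_in_network": pd.NA,
                "sum_degree": float(sum_degree),
            }
        )
    return _assemble(rows, threshold)


def select_candidates(ranking: MiRNARanking, min_sum_degree: float) -> list[str]:
    """miRNAs whose summed degree strictly exceeds the cut, in rank order."""
    t = ranking.table
    return t.loc[t["sum_degree"] > min_sum_degree, "mirna_id"].tolist()


def export_quadrant_plot_data(ranking: MiRNARanking) -> pd.DataFrame:
    """Per-miRNA (log10_fc, sum_degree, quadrant) plus the two reference lines.

    The reference lines are encoded as rows with ``kind`` = "vline"/"hline"
    so the table alone reproduces the plot.
    """
    t = ranking.table
    points = t[["mirna_id", "log10_fc", "sum_degree", "quadrant"]].copy()
    points.insert(0, "kind", "point")
    lines = pd.DataFrame(
        [
            {"kind": "vline", "mirna_id": "", "log10_fc": 0.0, "sum_degree": math.nan, "quadrant": ""},
            {
                "kind": "hline",
                "mirna_id": "",
                "log10_fc": math.nan,
                "sum_degree": ranking.degree_threshold,
                "quadrant": "",
            },
        ]
    )
    if points.empty:
        return points
    return pd.concat([points, lines], ignore_index=True)


def plot_quadrants(ranking: MiRNARanking, path: str | Path, annotate_top: int = 5) -> None:
    """Render the expression-vs-connectivity scatter with quadrant lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = ranking.table
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(t["log10_fc"], t["sum_degree"], s=25, c="#30548c", zorder=3)
    ax.axvline(0.0, color="grey", lw=1)
    ax.axhline(ranking.degree_threshold, color="grey", lw=1)
    for _, row in t.head(annotate_top).iterrows():
        ax.annotate(row["mirna_id"], (row["log10_fc"], row["sum_degree"]), fontsize=7,
                    xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("log10 fold change (case / reference)")
    ax.set_ylabel("sum of target node degrees")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_ranking(ranking: MiRNARanking, path: str | Path) -> None:
    ranking.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
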