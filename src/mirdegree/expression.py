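"""qPCR Ct processing: interplate calibration, global-mean normalisation
and 2^-ddCt fold changes with a concordant dysregulation filter.

A Ct table is a tidy :class:`pandas.DataFrame` with columns ``plate_id``,
``sample_id``, ``replicate_id``, ``mirna_id`` and ``ct`` (float cycles;
``NaN`` marks an undetected assay).  The processing chain mirrors standard
two-condition array-card analysis:

1. :func:`interplate_calibrate` — a synthetic spike-in calibrator run on
   every plate absorbs between-plate shifts: each plate's detected Ct values
   are reduced by that plate's calibrator offset from the grand calibrator
   mean, then calibrator rows are dropped.
2. :func:`global_mean_normalize` — dCt = Ct minus the mean Ct of all
   detected assays in the same (sample, replicate); the global mean replaces
   fixed reference genes.  Unbiased only when most assays are unchanged
   between conditions (or changes cancel), the usual assumption.
3. :func:`fold_changes` — per replicate, ddCt = dCt(case) − dCt(reference)
   and fold = 2^−ddCt (amplification efficiency fixed at 2).  A case-only
   dropout floors the fold at 0; a reference-only dropout caps it at
   ``fc_cap``; the consensus fold is the geometric mean of the finite
   replicate folds.  A miRNA is *dysregulated* when every replicate shows at
   least a ``min_fold`` change in the same direction — the concordance
   filter ("in both sets of arrays").
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .interactions import normalize_mirna_id

logger = logging.getLogger(__name__)

__all__ = [
    "CT_COLUMNS",
    "FoldChangeTable",
    "DysregulationSummary",
    "load_ct",
    "write_ct",
    "interplate_calibrate",
    "global_mean_normalize",
    "fold_changes",
    "dysregulation_report",
    "write_fold_changes",
]

CT_COLUMNS = ("plate_id", "sample_id", "replicate_id", "mirna_id", "ct")
_KEY = ["plate_id", "sample_id", "replicate_id", "mirna_id"]
UNDETECTED_TOKENS = {"", "undetermined", "undetected", "na", "nan"}


@dataclass
class FoldChangeTable:
    """Per-replicate and consensus fold changes, case vs reference.

    ``per_replicate``: miRNA × replicate fold matrix (0 = floored dropout,
    ``fc_cap`` = capped dropout, NaN = undefined).  ``summary``: per-miRNA
    ``fc_consensus``, ``log10_fc``, ``dysregulated``, ``reg_class``
    ("oncomiR" / "suppressor" / "unclassified"), ``floored``, ``capped``.
    """

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    reference_sample: str
    case_sample: str
    min_fold: float
    fc_cap: float


@dataclass
class DysregulationSummary:
    n_mirnas: int
    n_dysregulated: int
    n_oncomirs: int
    n_suppressors: int
    n_extreme: int
    extreme_threshold: float
    histogram: pd.DataFrame  # bin_left, bin_right, count over log10 consensus folds


def _validate_keys(df: pd.DataFrame, where: str) -> None:
    dup = df.duplicated(subset=_KEY)
    if dup.any():
        first = df.loc[dup.idxmax(), _KEY].tolist()
        raise FormatError(f"{where}: duplicate (plate, sample, replicate, miRNA) key {first}")


def load_ct(
    path: str | Path,
    plate_col: str = "plate_id",
    sample_col: str = "sample_id",
    replicate_col: str = "replicate_id",
    mirna_col: str = "mirna_id",
    ct_col: str = "ct",
    detection_limit: float = 37.0,
) -> pd.DataFrame:
    """Read a Ct plate TSV into the canonical tidy schema.

    Empty cells, "Undetermined" (and case variants) and Ct values at or
    above ``detection_limit`` become NaN (undetected).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = {
        plate_col: "plate_id",
        sample_col: "sample_id",
        replicate_col: "replicate_id",
        mirna_col: "mirna_id",
        ct_col: "ct",
    }
    for col in mapping:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df = df[list(mapping)].rename(columns=mapping)
    df["mirna_id"] = df["mirna_id"].map(normalize_mirna_id)

    def parse_ct(x) -> float:
        if pd.isna(x) or str(x).strip().lower() in UNDETECTED_TOKENS:
            return np.nan
        value = float(x)
        if not 0.0 < value < 50.0:
            raise FormatError(f"{path}: Ct value {value} outside (0, 50)")
        return value

    df["ct"] = df["ct"].map(parse_ct)
    df.loc[df["ct"] >= detection_limit, "ct"] = np.nan
    _validate_keys(df, str(path))
    return df.reset_index(drop=True)


def write_ct(df: pd.DataFrame, path: str | Path) -> None:
    """Write a Ct table as TSV; undetected values are written as 'Undetermined'."""
    out = df.copy()
    out["ct"] = out["ct"].map(lambda v: "Undetermined" if pd.isna(v) else repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


def estimate_plate_offsets(df: pd.DataFrame, calibrator_id: str) -> pd.Series:
    """Per-plate calibrator offset from the grand calibrator mean (cycles)."""
    cal = normalize_mirna_id(calibrator_id)
    cal_rows = df[df["mirna_id"] == cal]
    plate_means = {}
    for plate in sorted(df["plate_id"].unique()):
        cts = cal_rows.loc[cal_rows["plate_id"] == plate, "ct"].dropna()
        if cts.empty:
            raise ConfigError(f"calibrator '{calibrator_id}' missing or undetected on plate '{plate}'")
        plate_means[plate] = cts.mean()
    grand = float(np.mean(list(plate_means.values())))
    return pd.Series({p: m - grand for p, m in plate_means.items()}, name="offset")


def interplate_calibrate(df: pd.DataFrame, calibrator_id: str) -> pd.DataFrame:
    """Remove per-plate shifts using the spike-in calibrator, then drop it."""
    offsets = estimate_plate_offsets(df, calibrator_id)
    cal = normalize_mirna_id(calibrator_id)
    out = df[df["mirna_id"] != cal].copy()
    out["ct"] = out["ct"] - out["plate_id"].map(offsets)
    return out.reset_index(drop=True)


def global_mean_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """dCt against the mean of all detected assays per (sample, replicate)."""
    out = df.copy()
    for (sample, rep), idx in out.groupby(["sample_id", "replicate_id"]).groups.items():
        cts = out.loc[idx, "ct"]
        detected = cts.dropna()
        if detected.empty:
            raise ConfigError(f"sample '{sample}' replicate '{rep}' has no detected miRNA")
        out.loc[idx, "ct"] = cts - detected.mean()
    return out.rename(columns={"ct": "dct"})


def _consensus(folds: pd.Series, fc_cap: float) -> tuple[float, bool, bool]:
    """Geometric-mean consensus over replicate folds.

    Floored (0) and capped (``fc_cap``) dropout folds are excluded from the
    geometric mean when the finite replicates agree with their direction;
    a direction conflict leaves the consensus undefined.  Returns
    (consensus, floored_any, capped_any).
    """
    defined = folds.dropna()
    floored = bool((defined == 0.0).any())
    capped = bool((defined >= fc_cap).any())
    finite = defined[(defined > 0.0) & (defined < fc_cap)]
    if finite.empty:
        if floored and capped:
            return math.nan, floored, capped
        if floored:
            return 0.0, floored, capped
        if capped:
            return fc_cap, floored, capped
        return math.nan, False, False
    geo = float(np.exp(np.log(finite).mean()))
    if floored and geo >= 1.0:
        return math.nan, floored, capped  # dropout says down, replicate says up
    if capped and geo <= 1.0:
        return math.nan, floored, capped
    return geo, floored, capped


def fold_changes(
    dct: pd.DataFrame,
    reference_sample: str,
    case_sample: str,
    min_fold: float = 2.0,
    fc_cap: float = 2.0**12,
) -> FoldChangeTable:
    """Per-miRNA 2^-ddCt fold changes of ``case_sample`` over ``reference_sample``.

    The dysregulation flag requires every replicate to be defined and to
    show a concordant >= ``min_fold`` change (folds of 0 count as down,
    ``fc_cap`` as up).  miRNAs undetected in both samples on every replicate
    are dropped.
    """
    samples = set(dct["sample_id"].unique())
    for s in (reference_sample, case_sample):
        if s not in samples:
            raise ConfigError(f"sample '{s}' not present in the dCt table")
    wide = dct.pivot_table(
        index="mirna_id", columns=["sample_id", "replicate_id"], values="dct", dropna=False
    )
    replicates = sorted(
        set(r for s, r in wide.columns if s == reference_sample)
        & set(r for s, r in wide.columns if s == case_sample)
    )
    if not replicates:
        raise ConfigError("reference and case share no replicate ids")

    fold_rows = {}
    for mirna, row in wide.iterrows():
        folds = {}
        for rep in replicates:
            d_ref = row.get((reference_sample, rep), np.nan)
            d_case = row.get((case_sample, rep), np.nan)
            if pd.isna(d_ref) and pd.isna(d_case):
                folds[rep] = np.nan
            elif pd.isna(d_case):
                folds[rep] = 0.0  # detected in reference only: expression lost
            elif pd.isna(d_ref):
                folds[rep] = fc_cap  # detected in case only: capped gain
            else:
                folds[rep] = 2.0 ** -(d_case - d_ref)
        fold_rows[mirna] = folds
    per_rep = pd.DataFrame.from_dict(fold_rows, orient="index")[replicates]
    per_rep.index.name = "mirna_id"

    all_nan = per_rep.isna().all(axis=1)
    if all_nan.any():
        logger.info("dropped %d miRNAs undetected in both samples on every replicate", int(all_nan.sum()))
        per_rep = per_rep[~all_nan]

    records = []
    for mirna, folds in per_rep.iterrows():
        consensus, floored, capped = _consensus(folds, fc_cap)
        complete = not folds.isna().any()
        up = complete and bool((folds >= min_fold).all())
        down = complete and bool((folds <= 1.0 / min_fold).all())
        dysregulated = up or down
        if math.isnan(consensus) or consensus == 1.0:
            reg_class = "unclassified"
        elif consensus > 1.0:
            reg_class = "oncomiR"
        else:
            reg_class = "suppressor"
        if math.isnan(consensus):
            log10_fc = math.nan
        elif consensus == 0.0:
            log10_fc = -math.log10(fc_cap)  # floored dropout: most extreme loss representable
        else:
            log10_fc = math.log10(consensus)
        records.append(
            {
                "mirna_id": mirna,
                "fc_consensus": consensus,
                "log10_fc": log10_fc,
                "dysregulated": dysregulated,
                "reg_class": reg_class,
                "floored": floored,
                "capped": capped,
            }
        )
    summary = pd.DataFrame.from_records(records).set_index("mirna_id").sort_index()
    per_rep = per_rep.sort_index()
    n_capped = int(summary["capped"].sum())
    if n_capped:
        logger.warning("%d miRNAs hit the fold-change cap %.0f", n_capped, fc_cap)
    return FoldChangeTable(
        per_replicate=per_rep,
        summary=summary,
        reference_sample=reference_sample,
        case_sample=case_sample,
        min_fold=min_fold,
        fc_cap=fc_cap,
    )


def dysregulation_report(
    fct: FoldChangeTable,
    extreme_threshold: float = 8.0,
    bin_width: float = 0.25,
) -> DysregulationSummary:
    """Counts of dysregulated / oncomiR / suppressor / extreme miRNAs plus a
    log10 fold-change frequency distribution (over dysregulated miRNAs)."""
    s = fct.summary
    dys = s[s["dysregulated"]]
    extreme = dys[
        (dys["fc_consensus"] >= extreme_threshold)
        | (dys["fc_consensus"] <= 1.0 / extreme_threshold)
    ]
    logs = dys["log10_fc"].dropna()
    if logs.empty:
        hist = pd.DataFrame(columns=["bin_left", "bin_right", "count"])
    else:
        lo = math.floor(logs.min() / bin_width) * bin_width
        hi = math.ceil(logs.max() / bin_width) * bin_width
        edges = np.arange(lo, hi + bin_width / 2, bin_width)
        if len(edges) < 2:
            edges = np.array([lo, lo + bin_width])
        counts, edges = np.histogram(logs, bins=edges)
        hist = pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        )
    return DysregulationSummary(
        n_mirnas=len(s),
        n_dysregulated=len(dys),
        n_oncomirs=int((dys["reg_class"] == "oncomiR").sum()),
        n_suppressors=int((dys["reg_class"] == "suppressor").sum()),
        n_extreme=len(extreme),
        extreme_threshold=extreme_threshold,
        histogram=hist,
    )


def write_fold_changes(fct: FoldChangeTable, path: str | Path) -> None:
    """Fold-change report TSV: per-replicate folds plus consensus columns."""
    rep_cols = fct.per_replicate.rename(columns=lambda r: f"fc_{r}")
    out = rep_cols.join(fct.summary)
    out.to_csv(path, sep="\t", float_format="%.6g")
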