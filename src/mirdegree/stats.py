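"""Statistical comparisons and gene-set over-representation.

Three jobs:

* sample random protein baselines (the "chosen without regard to miRNA
  status" control) and compare centrality distributions between a target
  network and such a baseline, by one-way ANOVA and by a label-permutation
  test — the permutation test is the recommended one, since degree and
  stress distributions in scale-free networks are far from normal;
* exact hypergeometric over-representation of a query gene set against a
  GMT collection with Bonferroni correction over the pathways actually
  tested;
* small shared utilities (GMT reading, result serialisation).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, FormatError
from .network import METRICS, CentralityProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonResult",
    "EnrichmentResult",
    "sample_random_proteins",
    "one_way_anova",
    "permutation_test",
    "compare_networks",
    "hypergeometric_enrichment",
    "read_gmt",
    "write_enrichment",
]


@dataclass
class ComparisonResult:
    """ANOVA (+ optional permutation) comparison of one centrality metric."""

    metric: str
    group_means: tuple[float, float]
    F: float
    p_anova: float
    p_perm: float | None = None
    n_perm: int = 0


@dataclass
class EnrichmentResult:
    """Hypergeometric over-representation of one pathway."""

    pathway_id: str
    overlap: int
    pathway_size: int
    query_size: int
    background_size: int
    p_raw: float
    p_bonferroni: float
    neg_log10_p: float
    significant: bool


def sample_random_proteins(background: Iterable[str], n: int, seed: int) -> set[str]:
    """Uniform sample of ``n`` proteins without replacement; deterministic per seed."""
    pool = sorted(set(background))
    if n > len(pool):
        raise ConfigError(f"cannot sample {n} proteins from a background of {len(pool)}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return {pool[i] for i in idx}


def one_way_anova(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Classical one-way ANOVA F and upper-tail p with (k-1, N-k) df."""
    if len(groups) < 2:
        raise ConfigError("one_way_anova needs at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ConfigError("every group needs at least two values")
    allv = np.concatenate(arrays)
    if np.all(allv == allv[0]):
        raise ConfigError("ANOVA undefined when all values are identical")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 999,
    seed: int = 1,
    exhaustive: bool = False,
) -> float:
    """Two-sided permutation p for the difference in group means.

    Random mode draws ``n_perm`` label permutations and applies add-one
    smoothing: ``p = (1 + #{perm >= observed}) / (n_perm + 1)``.  Exhaustive
    mode enumerates every distinct assignment of labels (all C(n, |a|)
    groupings, the identity included) and uses the same formula with the
    enumeration count in place of ``n_perm``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    na, n = a.size, pooled.size
    observed = abs(a.mean() - b.mean())
    total = pooled.sum()

    def diff_from_a_sum(a_sum: float) -> float:
        return abs(a_sum / na - (total - a_sum) / (n - na))

    if exhaustive:
        hits = sum(
            diff_from_a_sum(sum(pooled[i] for i in comb)) >= observed - 1e-12
            for comb in itertools.combinations(range(n), na)
        )
        n_done = math.comb(n, na)
        return (1 + hits) / (n_done + 1)
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    # permutation matrix via argsort of uniforms: each row a random labelling
    ranks = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_a_sums = pooled[ranks[:, :na]].sum(axis=1)
    diffs = np.abs(perm_a_sums / na - (total - perm_a_sums) / (n - na))
    hits = int(np.sum(diffs >= observed - 1e-12))
    return (1 + hits) / (n_perm + 1)


def compare_networks(
    prof_a: CentralityProfile,
    prof_b: CentralityProfile,
    n_perm: int = 999,
    seed: int = 1,
) -> list[ComparisonResult]:
    """Compare the per-node centrality distributions of two graphs.

    Returns one result per metric (degree, closeness, stress); ANOVA is
    always run, the permutation test when ``n_perm >= 1``.
    """
    if not prof_a.degree or not prof_b.degree:
        raise ConfigError("both centrality profiles must be non-empty")
    results = []
    for i, metric in enumerate(METRICS):
        va = [float(x) for x in prof_a.metric(metric).values()]
        vb = [float(x) for x in prof_b.metric(metric).values()]
        f, p = one_way_anova([va, vb])
        p_perm = (
            permutation_test(va, vb, n_perm=n_perm, seed=seed + i) if n_perm >= 1 else None
        )
        results.append(
            ComparisonResult(
                metric=metric,
                group_means=(float(np.mean(va)), float(np.mean(vb))),
                F=f,
                p_anova=p,
                p_perm=p_perm,
                n_perm=n_perm if p_perm is not None else 0,
            )
        )
    return results


def hypergeometric_enrichment(
    query: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Over-representation of ``query`` in each pathway, Bonferroni-corrected.

    ``p_raw = P(X >= overlap)`` for a hypergeometric draw of |query| genes
    from |background| of which |pathway ∩ background| are successes.  The
    Bonferroni multiplier is the number of pathways actually tested (those
    with a non-empty background intersection).  Results sorted by corrected
    p, ties by pathway id.
    """
    bg = set(background)
    if not bg:
        raise ConfigError("background must be non-empty")
    q = set(query) & bg
    dropped = len(set(query)) - len(q)
    if dropped:
        logger.info("dropped %d query genes absent from the background", dropped)
    tested = {}
    for name, members in gene_sets.items():
        inter = set(members) & bg
        if inter:
            tested[name] = inter
    n_tests = len(tested)
    results = []
    for name, members in tested.items():
        k = len(q & members)
        # P(X >= k); sf(k-1) is exact for the discrete hypergeometric
        p_raw = float(sps.hypergeom.sf(k - 1, len(bg), len(members), len(q)))
        p_bonf = min(1.0, p_raw * n_tests)
        results.append(
            EnrichmentResult(
                pathway_id=name,
                overlap=k,
                pathway_size=len(members),
                query_size=len(q),
                background_size=len(bg),
                p_raw=p_raw,
                p_bonferroni=p_bonf,
                neg_log10_p=-math.log10(p_bonf) if p_bonf > 0 else math.inf,
                significant=p_bonf < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_bonferroni, r.pathway_id))
    return results


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs name, description and genes")
        sets[fields[0]] = {g.strip().upper() for g in fields[2:] if g.strip()}
    return sets


def write_enrichment(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in results]).to_csv(path, sep="\t", index=False)
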