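"""Validated miRNA→target interaction tables.

Curated interaction databases (Tarbase, miRecords, ...) ship overlapping,
inconsistently capitalised dumps.  This module loads them into a single
non-redundant table keyed on the normalised (miRNA id, gene symbol) pair,
merges tables from several sources while tracking provenance, filters the
target genes against an expressed-gene universe, and serves per-miRNA
target sets for downstream degree scoring.

Normalisation rule (applied everywhere a miRNA id or gene symbol enters the
package): gene symbols are whitespace-trimmed and upper-cased; miRNA ids are
whitespace-trimmed, split on "-", and every token lower-cased except that
the token "mir" is rendered "miR" — so ``HSA-MIR-1``, ``hsa-mir-1`` and
``hsa-miR-1`` are one identifier, and ``hsa-let-7a`` is left alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import ConfigError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionRecord",
    "InteractionTable",
    "normalize_mirna_id",
    "normalize_gene_symbol",
    "load_interactions",
    "merge_tables",
    "filter_by_universe",
    "targets_of",
    "read_universe",
    "write_interactions",
]


def normalize_mirna_id(raw: str) -> str:
    """Canonicalise a miRNA identifier (see module docstring for the rule)."""
    tokens = str(raw).strip().split("-")
    out = []
    for tok in tokens:
        low = tok.lower()
        out.append("miR" if low == "mir" else low)
    return "-".join(out)


def normalize_gene_symbol(raw: str) -> str:
    return str(raw).strip().upper()


@dataclass(frozen=True)
class InteractionRecord:
    """One validated miRNA→gene interaction with database provenance."""

    mirna_id: str
    gene_symbol: str
    sources: frozenset[str]

    def __post_init__(self):
        if not self.mirna_id or not self.gene_symbol:
            raise ValueError("mirna_id and gene_symbol must be non-empty")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mirna_id, self.gene_symbol)


@dataclass
class InteractionTable:
    """Non-redundant collection of interaction records.

    No two records share a (mirna_id, gene_symbol) pair; if ``universe`` is
    set every gene_symbol is a member of it.
    """

    records: list[InteractionRecord] = field(default_factory=list)
    universe: frozenset[str] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, InteractionTable):
            return NotImplemented
        return set(self.records) == set(other.records) and self.universe == other.universe

    def pairs(self) -> set[tuple[str, str]]:
        return {r.pair for r in self.records}

    def mirnas(self) -> set[str]:
        return {r.mirna_id for r in self.records}

    def genes(self) -> set[str]:
        return {r.gene_symbol for r in self.records}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.mirna_id, r.gene_symbol, ";".join(sorted(r.sources)))
            for r in sorted(self.records, key=lambda r: r.pair)
        ]
        return pd.DataFrame(rows, columns=["mirna", "gene", "sources"])


def load_interactions(
    path: str | Path,
    source_label: str,
    mirna_col: str = "mirna",
    gene_col: str = "gene",
    species_prefix: str | None = None,
) -> InteractionTable:
    """Load a TSV dump of one interaction database into a table.

    Duplicate rows (after normalisation) collapse to one record; every
    record carries ``sources == {source_label}``.  ``species_prefix`` (e.g.
    ``"hsa"``) optionally drops records whose miRNA id does not start with
    that prefix — species selection is otherwise the caller's job.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("interaction file %s is empty", path)
        return InteractionTable()
    for col in (mirna_col, gene_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    seen: dict[tuple[str, str], InteractionRecord] = {}
    n_dropped = 0
    for raw_mir, raw_gene in zip(df[mirna_col], df[gene_col]):
        if pd.isna(raw_mir) or pd.isna(raw_gene):
            continue
        mir = normalize_mirna_id(raw_mir)
        gene = normalize_gene_symbol(raw_gene)
        if not mir or not gene:
            continue
        if species_prefix is not None and not mir.startswith(species_prefix.lower() + "-"):
            n_dropped += 1
            continue
        key = (mir, gene)
        if key not in seen:
            seen[key] = InteractionRecord(mir, gene, frozenset({source_label}))
    if n_dropped:
        logger.info("%s: dropped %d records outside species '%s'", path, n_dropped, species_prefix)
    logger.info("%s: %d non-redundant interactions (source=%s)", path, len(seen), source_label)
    return InteractionTable(records=list(seen.values()))


def merge_tables(tables: Sequence[InteractionTable]) -> InteractionTable:
    """Union several tables into one non-redundant table.

    A pair present in k tables appears once with the union of their source
    labels.  Idempotent: merging a table with itself returns an equal table.
    """
    if len(tables) < 1:
        raise ConfigError("merge_tables requires at least one table")
    merged: dict[tuple[str, str], frozenset[str]] = {}
    for table in tables:
        for rec in table.records:
            merged[rec.pair] = merged.get(rec.pair, frozenset()) | rec.sources
    records = [InteractionRecord(m, g, src) for (m, g), src in merged.items()]
    return InteractionTable(records=records)


def filter_by_universe(table: InteractionTable, universe: Iterable[str]) -> InteractionTable:
    """Keep only records whose target gene is in the expressed-gene universe."""
    uni = frozenset(normalize_gene_symbol(g) for g in universe)
    if not uni:
        raise ConfigError("universe must be non-empty")
    kept = [r for r in table.records if r.gene_symbol in uni]
    n_dropped = len(table) - len(kept)
    if n_dropped:
        logger.info("universe filter dropped %d of %d records", n_dropped, len(table))
    return InteractionTable(records=kept, universe=uni)


def targets_of(table: InteractionTable, mirna_id: str) -> set[str]:
    """Set of validated target gene symbols of one miRNA (empty if absent)."""
    mir = normalize_mirna_id(mirna_id)
    return {r.gene_symbol for r in table.records if r.mirna_id == mir}


def read_universe(path: str | Path) -> frozenset[str]:
    """Read a one-symbol-per-line universe file; '#' lines are comments."""
    symbols = set()
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbols.add(normalize_gene_symbol(line))
    return frozenset(symbols)


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    """Write a table as TSV with columns mirna, gene, sources (sorted, ';'-joined)."""
    table.to_frame().to_csv(path, sep="\t", index=False)
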