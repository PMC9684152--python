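"""Lineage parsing and per-rank feature construction.

Greengenes-style lineage strings (``"k__Bacteria; p__Firmicutes; ..."``)
are parsed into seven Linnaean ranks; count tables are aggregated to any
rank by summing child taxa, with an explicit ``Unassigned`` bin so that
per-sample totals are conserved.  Relative-abundance and log normalization
provide the feature matrices the ordination and traceability stages use.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError, UsageError
from .table_io import TaxonTable

logger = logging.getLogger(__name__)

#: Linnaean ranks in the Greengenes prefix convention, shallow to deep.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")
RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")
#: Ranks used as feature levels (the kingdom level carries no signal here).
FEATURE_RANKS = RANKS[1:]

UNASSIGNED = "Unassigned"


@dataclass(frozen=True)
class Lineage:
    """Ranked names for kingdom..species; ``None`` where unassigned.

    The prefix property holds by construction: once a rank is missing all
    deeper ranks are missing too.
    """

    names: tuple[str | None, ...]

    def __post_init__(self) -> None:
        assert len(self.names) == len(RANKS)

    def name_at(self, rank: str) -> str | None:
        return self.names[RANKS.index(rank)]

    @property
    def depth(self) -> int:
        """Number of leading assigned ranks."""
        d = 0
        for n in self.names:
            if n is None:
                break
            d += 1
        return d


def parse_lineage(s: str) -> Lineage:
    """Parse a ``"k__X; p__Y; ..."`` string into a :class:`Lineage`.

    An empty payload after a prefix (``"p__"``) marks that rank missing, and
    every deeper rank is dropped (truncation enforces the prefix property).
    Unrecognized tokens make the whole lineage unassigned (logged), never an
    exception: annotation quality is data, not a usage error.
    """
    names: list[str | None] = [None] * len(RANKS)
    if s is None:
        return Lineage(tuple(names))
    tokens = [t.strip() for t in str(s).split(";") if t.strip()]
    for i, token in enumerate(tokens):
        if i >= len(RANKS):
            break
        if not token.startswith(RANK_PREFIXES[i]):
            logger.warning("unrecognized lineage token %r in %r; "
                           "treating lineage as unassigned from rank %s",
                           token, s, RANKS[i])
            break
        payload = token[len(RANK_PREFIXES[i]):].strip()
        if not payload:
            break
        names[i] = payload
    # truncate after the first missing rank
    for i in range(1, len(names)):
        if names[i - 1] is None:
            names[i] = None
    return Lineage(tuple(names))


def _rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank)
    except ValueError:
        raise UsageError(f"unknown rank {rank!r}; expected one of {RANKS}") from None


def aggregate_to_rank(
    table: TaxonTable, rank: str, keep_unassigned: bool = True
) -> TaxonTable:
    """Sum child-taxon counts into the distinct names at ``rank``.

    With ``keep_unassigned`` the counts of taxa lacking a name at ``rank``
    go to an ``Unassigned`` row, so column sums are conserved exactly
    (integer arithmetic).  Rows are ordered by first appearance.
    """
    if table.value_kind != "counts":
        raise UsageError("aggregation requires a counts table")
    ridx = _rank_index(rank)
    groups: dict[str, np.ndarray] = {}
    for lineage_str, row in zip(table.lineages, table.values):
        name = parse_lineage(lineage_str).names[ridx]
        key = UNASSIGNED if name is None else name
        if key in groups:
            groups[key] = groups[key] + row
        else:
            groups[key] = row.copy()
    if not keep_unassigned:
        groups.pop(UNASSIGNED, None)
    # Unassigned last, for readability
    names = [n for n in groups if n != UNASSIGNED]
    if UNASSIGNED in groups:
        names.append(UNASSIGNED)
    values = (
        np.vstack([groups[n] for n in names])
        if names
        else np.zeros((0, table.n_samples), dtype=np.int64)
    )
    prefix = RANK_PREFIXES[ridx]
    return TaxonTable(
        taxon_ids=list(names),
        lineages=[prefix + n if n != UNASSIGNED else "" for n in names],
        sample_ids=list(table.sample_ids),
        values=values,
        value_kind="counts",
    )


def count_taxa_per_rank(table: TaxonTable) -> dict[str, int]:
    """Number of distinct assigned names per rank (``Unassigned`` excluded)."""
    counts: dict[str, int] = {}
    parsed = [parse_lineage(s) for s in table.lineages]
    for i, rank in enumerate(RANKS):
        counts[rank] = len({p.names[i] for p in parsed if p.names[i] is not None})
    return counts


def relative_abundance(table: TaxonTable) -> TaxonTable:
    """Divide each sample column by its total; output columns sum to 1.

    Idempotent: applying to an already-relative table returns it unchanged.
    """
    if table.value_kind == "log":
        raise UsageError("cannot renormalize a log-transformed table")
    sums = table.values.sum(axis=0).astype(float)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        bad = [table.sample_ids[i] for i in zero]
        raise DataError(f"all-zero sample column(s): {bad}")
    return TaxonTable(
        taxon_ids=list(table.taxon_ids),
        lineages=list(table.lineages),
        sample_ids=list(table.sample_ids),
        values=table.values / sums,
        value_kind="relative",
    )


def log_normalize(table: TaxonTable, epsilon: float = 1e-6) -> TaxonTable:
    """Entrywise natural log of (relative abundance + epsilon).

    ``epsilon`` keeps zeros finite; the default 1e-6 sits below the smallest
    observable relative abundance at the sequencing depths modeled here
    (1 / 150,000 ~ 6.7e-6).
    """
    if table.value_kind != "relative":
        raise UsageError("log_normalize expects a relative-abundance table")
    if not epsilon > 0:
        raise UsageError("epsilon must be positive")
    return TaxonTable(
        taxon_ids=list(table.taxon_ids),
        lineages=list(table.lineages),
        sample_ids=list(table.sample_ids),
        values=np.log(table.values + epsilon),
        value_kind="log",
    )


@dataclass
class RankTableSet:
    """One aggregated counts table per feature rank (phylum..species)."""

    tables: dict[str, TaxonTable]

    def __getitem__(self, rank: str) -> TaxonTable:
        return self.tables[rank]

    @property
    def ranks(self) -> list[str]:
        return list(self.tables)


def build_rank_set(table: TaxonTable) -> RankTableSet:
    """Aggregate ``table`` at every feature rank, keeping the unassigned bin."""
    return RankTableSet(
        {rank: aggregate_to_rank(table, rank, keep_unassigned=True)
         for rank in FEATURE_RANKS}
    )


def feature_matrix(
    table: TaxonTable,
    epsilon: float = 1e-6,
    drop_unassigned: bool = True,
    log: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Samples x features matrix for ordination, from a counts table.

    Relative abundance is computed on the full column (including the
    unassigned bin, so compositions reflect true totals); the unassigned
    feature itself is then dropped by default because it encodes annotation
    quality rather than biology.  Returns ``(X, feature_names)`` with X of
    shape (n_samples, n_features).
    """
    rel = relative_abundance(table) if table.value_kind == "counts" else table
    out = log_normalize(rel, epsilon) if log else rel
    keep = [i for i, t in enumerate(out.taxon_ids)
            if not (drop_unassigned and t == UNASSIGNED)]
    X = out.values[keep, :].T.astype(float)
    names = [out.taxon_ids[i] for i in keep]
    return X, names
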