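"""Readers and writers for taxon tables, sample metadata, and phylogenies.

Every downstream stage consumes only the containers defined here: a
:class:`TaxonTable` (taxa x samples numeric matrix with one Greengenes-style
lineage string per taxon), a :class:`SampleMetadata` (per-sample categorical
factors), and a :class:`PhyloTree` (rooted tree with branch lengths, used by
Faith's PD).

Two tab-separated taxon-table dialects are accepted:

``tsv``
    ``taxon_id <tab> <sample columns...> <tab> lineage`` with the lineage in
    a column named ``lineage`` (or as the trailing column).
``biom-tsv``
    the "classic" BIOM export: ``#OTU ID`` header cell, a trailing
    ``taxonomy`` column.

Lines starting with ``#`` are treated as comments, except a ``#OTU ID``
header line which is the header row of the biom-tsv dialect.  Lineage
strings are carried verbatim; parsing happens in :mod:`gutrace.taxonomy_agg`
so malformed lineages fail where they matter.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from .errors import AlignmentError, FormatError

logger = logging.getLogger(__name__)

#: Markers interpreted as missing metadata values.
MISSING_MARKERS = frozenset({"", "NA", "na", "NaN", "nan"})
MISSING = "<missing>"

VALUE_KINDS = ("counts", "relative", "log")


@dataclass
class TaxonTable:
    """Taxa x samples abundance matrix with per-taxon lineage strings.

    Parameters
    ----------
    taxon_ids : list of str
        Unique row identifiers (OTU ids or aggregated taxon names).
    lineages : list of str
        One lineage string per taxon (``"k__...; p__...; ..."``).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray of shape (n_taxa, n_samples)
        Non-negative matrix; integers when ``value_kind == "counts"``.
    value_kind : {"counts", "relative", "log"}
        What the entries represent; "relative" columns sum to 1.
    """

    taxon_ids: list[str]
    lineages: list[str]
    sample_ids: list[str]
    values: np.ndarray
    value_kind: str = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.value_kind not in VALUE_KINDS:
            raise FormatError(f"unknown value_kind {self.value_kind!r}")
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(self.lineages) != len(self.taxon_ids):
            raise FormatError("one lineage string required per taxon")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError("duplicate taxon ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if self.value_kind == "counts":
            if np.any(self.values < 0):
                raise FormatError("negative counts")
            if not np.allclose(self.values, np.round(self.values)):
                raise FormatError("counts must be integers")
            self.values = np.round(self.values).astype(np.int64)
        elif self.value_kind == "relative":
            sums = self.values.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise FormatError("relative-abundance columns must sum to 1")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.taxon_ids, columns=self.sample_ids)

    def select_samples(self, sample_ids: list[str]) -> "TaxonTable":
        """Restrict (and reorder) the table to ``sample_ids``."""
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return TaxonTable(
            taxon_ids=list(self.taxon_ids),
            lineages=list(self.lineages),
            sample_ids=list(sample_ids),
            values=self.values[:, idx],
            value_kind=self.value_kind,
        )


@dataclass
class SampleMetadata:
    """Per-sample categorical factors.

    ``factors`` is a DataFrame indexed by sample id; missing entries hold the
    sentinel :data:`MISSING`.
    """

    sample_ids: list[str]
    factors: pd.DataFrame

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in metadata")
        self.factors = self.factors.astype(str)

    @property
    def factor_names(self) -> list[str]:
        return list(self.factors.columns)

    def levels(self, factor: str) -> list[str]:
        """Distinct non-missing levels of ``factor``, in first-seen order."""
        seen: dict[str, None] = {}
        for v in self.factors[factor]:
            if v != MISSING:
                seen.setdefault(v, None)
        return list(seen)

    def select_samples(self, sample_ids: list[str]) -> "SampleMetadata":
        return SampleMetadata(list(sample_ids), self.factors.loc[sample_ids].copy())


@dataclass
class PhyloTree:
    """Rooted phylogeny with non-negative branch lengths over taxon leaves."""

    tree: TreeNode
    leaf_names: list[str] = field(init=False)

    def __post_init__(self) -> None:
        names = [t.name for t in self.tree.tips()]
        if len(set(names)) != len(names):
            raise FormatError("duplicate leaf labels in tree")
        for node in self.tree.traverse(include_self=False):
            if node.length is None:
                raise FormatError("tree branch lengths are required")
            if node.length < 0:
                raise FormatError("negative branch length")
        self.leaf_names = names

    def total_length(self) -> float:
        return sum(n.length for n in self.tree.traverse(include_self=False))


def _dataframe_to_table(df: pd.DataFrame, lineage_col: str) -> TaxonTable:
    if df.index.has_duplicates:
        raise FormatError("duplicate taxon ids")
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample columns")
    lineages = df[lineage_col].astype(str).tolist()
    data = df.drop(columns=[lineage_col])
    try:
        values = data.to_numpy(dtype=float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance entry: {exc}") from exc
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise FormatError("negative or non-finite abundance entries")
    return TaxonTable(
        taxon_ids=[str(t) for t in df.index],
        lineages=lineages,
        sample_ids=[str(s) for s in data.columns],
        values=values,
        value_kind="counts",
    )


def read_taxon_table(path, dialect: str = "tsv") -> TaxonTable:
    """Read a taxon x sample count table.

    Parameters
    ----------
    path : path or file-like
        TSV source.
    dialect : {"tsv", "biom-tsv"}
        ``tsv`` expects a ``lineage`` column (or unlabeled trailing column);
        ``biom-tsv`` expects the classic BIOM export with a trailing
        ``taxonomy`` column.
    """
    if dialect not in ("tsv", "biom-tsv"):
        raise FormatError(f"unknown dialect {dialect!r}")
    text = _read_text(path)
    lines = [
        ln
        for ln in text.splitlines()
        if not (ln.startswith("#") and not ln.startswith("#OTU ID"))
    ]
    if not lines:
        raise FormatError("empty taxon table")
    header = lines[0].split("\t")
    if len(set(header[1:])) != len(header[1:]):
        raise FormatError("duplicate sample columns")  # pandas would mangle
    df = pd.read_csv(
        io.StringIO("\n".join(lines)), sep="\t", index_col=0, dtype=str,
        keep_default_na=False,
    )
    if df.columns.has_duplicates:
        raise FormatError("duplicate sample columns")
    lineage_col = "taxonomy" if dialect == "biom-tsv" else "lineage"
    if lineage_col not in df.columns:
        if dialect == "tsv" and len(df.columns) > 0:
            lineage_col = df.columns[-1]  # unlabeled trailing lineage field
            try:
                float(df[lineage_col].iloc[0])
                raise FormatError("no lineage column found")
            except (ValueError, IndexError):
                pass
        else:
            raise FormatError(f"missing {lineage_col!r} column")
    return _dataframe_to_table(df, lineage_col)


def write_taxon_table(table: TaxonTable, path, dialect: str = "tsv") -> None:
    """Write ``table`` in the given dialect (see :func:`read_taxon_table`)."""
    lineage_col = "taxonomy" if dialect == "biom-tsv" else "lineage"
    df = table.to_frame()
    df[lineage_col] = table.lineages
    header_cell = "#OTU ID" if dialect == "biom-tsv" else "taxon_id"
    df.index.name = header_cell
    df.to_csv(path, sep="\t")


def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata TSV (first column ``sample_id``).

    Empty strings and ``NA`` are recorded as missing.  Extra columns beyond
    the canonical factors are retained as additional factors.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment=None)
    if df.columns[0] != "sample_id":
        raise FormatError("metadata must start with a sample_id column")
    df = df.set_index("sample_id")
    df = df.map(lambda v: MISSING if str(v).strip() in MISSING_MARKERS else str(v).strip())
    return SampleMetadata([str(s) for s in df.index], df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.factors.copy()
    df.index.name = "sample_id"
    df.replace(MISSING, "NA").to_csv(path, sep="\t")


def align_table_metadata(
    table: TaxonTable, meta: SampleMetadata
) -> tuple[TaxonTable, SampleMetadata]:
    """Restrict table and metadata to their shared samples, table order first.

    Samples present in only one input are dropped (logged); an empty
    intersection raises :class:`AlignmentError`.
    """
    meta_set = set(meta.sample_ids)
    shared = [s for s in table.sample_ids if s in meta_set]
    if not shared:
        raise AlignmentError("table and metadata share no samples")
    dropped = (set(table.sample_ids) | meta_set) - set(shared)
    if dropped:
        logger.info("align_table_metadata dropped %d samples: %s",
                    len(dropped), sorted(dropped))
    return table.select_samples(shared), meta.select_samples(shared)


def read_tree(path) -> PhyloTree:
    """Read a rooted newick tree with branch lengths."""
    text = _read_text(path)
    try:
        tree = TreeNode.read(io.StringIO(text), format="newick")
    except Exception as exc:  # skbio raises several parse error types
        raise FormatError(f"unparseable newick: {exc}") from exc
    return PhyloTree(tree)


def write_tree(tree: PhyloTree, path) -> None:
    tree.tree.write(str(path), format="newick")


def _read_text(path) -> str:
    if hasattr(path, "read"):
        return path.read()
    with open(path, encoding="utf-8") as fh:
        return fh.read()
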