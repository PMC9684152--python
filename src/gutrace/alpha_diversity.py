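"""Per-sample alpha diversity and between-group comparisons.

Four indices: Shannon entropy (natural log), Gini-Simpson (1 - sum p_i^2),
bias-corrected Chao1 richness, and Faith's phylogenetic diversity.  Index
values are computed through scikit-bio; this module owns input validation,
the per-sample sweep over a table, depth bookkeeping, and the pairwise
rank-sum comparison between host groups.

Rarefaction is deliberately not applied; sequencing depth is recorded next
to every index so depth confounding stays visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import alpha as _skb_alpha

from .errors import DataError, UsageError
from .table_io import MISSING, PhyloTree, SampleMetadata, TaxonTable

INDICES = ("shannon", "simpson", "chao1", "pd_tree")

#: At or below this per-group size the rank-sum test uses exact enumeration.
EXACT_RANKSUM_MAX_N = 10


def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1 or np.any(c < 0):
        raise DataError("counts must be a 1-D non-negative vector")
    if c.sum() == 0:
        raise DataError("all-zero count vector")
    return c


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i over positive entries."""
    return float(_skb_alpha.shannon(_check_counts(counts), base=np.e))


def simpson(counts) -> float:
    """Gini-Simpson index 1 - sum p_i^2 (bounded in [0, 1])."""
    return float(_skb_alpha.simpson(_check_counts(counts)))


def chao1(counts) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    return float(_skb_alpha.chao1(_check_counts(counts), bias_corrected=True))


def faith_pd(presence, taxon_ids: list[str], tree: PhyloTree) -> float:
    """Total branch length of the minimal subtree spanning root and present taxa."""
    p = np.asarray(presence)
    present = {t for t, v in zip(taxon_ids, p) if v > 0}
    missing = present - set(tree.leaf_names)
    if missing:
        raise DataError(f"taxa absent from tree: {sorted(missing)}")
    return float(
        _skb_alpha.faith_pd((p > 0).astype(int), taxa=list(taxon_ids), tree=tree.tree)
    )


@dataclass
class DiversityResult:
    """Per-sample alpha-diversity values with the parameters that produced them."""

    sample_ids: list[str]
    values: pd.DataFrame  # samples x indices
    depths: np.ndarray  # reads per sample, for depth-confound inspection
    parameters: dict = field(default_factory=dict)

    def to_tidy(self, meta: SampleMetadata | None = None,
                group_factor: str | None = None) -> pd.DataFrame:
        """Long-format (sample_id, index, value[, group]) table."""
        rows = []
        for s in self.sample_ids:
            for idx in self.values.columns:
                row = {"sample_id": s, "index": idx,
                       "value": self.values.loc[s, idx]}
                if meta is not None and group_factor is not None:
                    row["group"] = meta.factors.loc[s, group_factor]
                rows.append(row)
        return pd.DataFrame(rows)


def alpha_diversity_table(
    table: TaxonTable,
    tree: PhyloTree | None = None,
    indices: tuple[str, ...] = ("shannon", "simpson", "chao1"),
) -> DiversityResult:
    """Compute the requested indices for every sample of a counts table.

    ``pd_tree`` requires ``tree``; include it in ``indices`` explicitly.
    """
    if table.value_kind != "counts":
        raise UsageError("alpha diversity is defined on counts")
    unknown = set(indices) - set(INDICES)
    if unknown:
        raise UsageError(f"unknown indices: {sorted(unknown)}")
    if "pd_tree" in indices and tree is None:
        raise UsageError("pd_tree requires a phylogenetic tree")
    funcs = {"shannon": shannon, "simpson": simpson, "chao1": chao1}
    out = {}
    for j, s in enumerate(table.sample_ids):
        col = table.values[:, j]
        row = {name: funcs[name](col) for name in indices if name != "pd_tree"}
        if "pd_tree" in indices:
            row["pd_tree"] = faith_pd(col, table.taxon_ids, tree)
        out[s] = row
    values = pd.DataFrame.from_dict(out, orient="index")[list(indices)]
    return DiversityResult(
        sample_ids=list(table.sample_ids),
        values=values,
        depths=table.values.sum(axis=0),
        parameters={"indices": list(indices), "rarefied": False},
    )


def compare_alpha_by_group(
    div: DiversityResult,
    meta: SampleMetadata,
    grouping: str,
    index: str,
) -> pd.DataFrame:
    """Pairwise two-sided rank-sum p-values between groups for one index.

    Exact enumeration when both groups have <= 10 samples, normal
    approximation otherwise.  No multiple-testing correction is applied
    (flagged in ``df.attrs``); diagonal and degenerate pairs (a group with
    < 2 samples) are NaN.
    """
    if index not in div.values.columns:
        raise UsageError(f"index {index!r} was not computed")
    groups: dict[str, np.ndarray] = {}
    for level in meta.levels(grouping):
        ids = [s for s in div.sample_ids
               if meta.factors.loc[s, grouping] == level and level != MISSING]
        groups[level] = div.values.loc[ids, index].to_numpy()
    levels = list(groups)
    if len(levels) < 2:
        raise DataError(f"grouping {grouping!r} has fewer than 2 levels")
    pmat = pd.DataFrame(np.nan, index=levels, columns=levels)
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            x, y = groups[a], groups[b]
            if len(x) < 2 or len(y) < 2:
                continue  # degenerate pair stays NaN
            method = ("exact"
                      if max(len(x), len(y)) <= EXACT_RANKSUM_MAX_N
                      else "asymptotic")
            p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                   method=method).pvalue
            pmat.loc[a, b] = pmat.loc[b, a] = float(min(p, 1.0))
    pmat.attrs["correction"] = "none"
    pmat.attrs["test"] = "two-sided rank-sum (Mann-Whitney U)"
    return pmat
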