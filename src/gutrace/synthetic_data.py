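"""Synthetic gut-microbiota communities with known factor structure.

The generator emulates the study design the analysis pipeline assumes:
multiple host insect species collected from several geographic areas (with
nested sites), each sample a 16S count vector over a nested 7-rank
taxonomy, sequenced to a depth uniform in a stated range.

Sample composition follows an additive log-ratio model: per-taxon log
abundance is a global baseline plus independent Gaussian shift vectors for
host species, developmental stage, sex, and geographic area.  The
geography shift is constant within blocks of taxa that share a name at a
configurable ``signal_rank``, so the geographic signal is exactly
recoverable at that rank (and diluted at finer ones) — making the
"which taxonomic level carries geographic information" question a testable
parameter-recovery target.  The softmax of the log abundances is perturbed
with a Dirichlet draw (overdispersion) and counts are multinomial.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from skbio import TreeNode

from .errors import UsageError
from .table_io import (PhyloTree, SampleMetadata, TaxonTable, write_metadata,
                       write_taxon_table, write_tree)
from .taxonomy_agg import RANKS

import pandas as pd

#: Distinct-name counts per rank (phylum..species) mirroring the breadth of
#: a broad multi-host 16S survey.
DEFAULT_TAXONOMY_SHAPE = (40, 98, 178, 277, 598, 900)


@dataclass
class SimulationSpec:
    """Parameters of one synthetic study.

    Effect sizes are standard deviations of the per-level Gaussian shifts
    on log abundance, ordered by construction
    species > stage > geography > sex to match the relative factor
    importance the analysis is meant to recover.
    """

    n_host_species: int = 22
    n_geographic_areas: int = 5
    sites_per_area: int = 2
    samples_per_cell: int = 2
    areas_per_species: int = 4
    taxonomy_shape: tuple[int, ...] = DEFAULT_TAXONOMY_SHAPE
    depth_range: tuple[int, int] = (50_000, 150_000)
    effect_species: float = 1.0
    effect_stage: float = 0.55
    effect_geography: float = 0.35
    effect_sex: float = 0.15
    signal_rank: str = "class"
    baseline_sd: float = 1.5
    dirichlet_concentration: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        shape = tuple(self.taxonomy_shape)
        if len(shape) != 6 or any(a > b for a, b in zip(shape, shape[1:])):
            raise UsageError("taxonomy_shape must be 6 non-decreasing counts "
                             "(phylum..species)")
        for name in ("effect_species", "effect_stage", "effect_geography",
                     "effect_sex"):
            if getattr(self, name) < 0:
                raise UsageError(f"{name} must be non-negative")
        if self.depth_range[0] <= 0 or self.depth_range[0] > self.depth_range[1]:
            raise UsageError("depth_range must be positive and ordered")
        if self.samples_per_cell < 2:
            raise UsageError("samples_per_cell must be >= 2")
        if self.signal_rank not in RANKS[1:]:
            raise UsageError(f"signal_rank must be one of {RANKS[1:]}")
        if not 1 <= self.areas_per_species <= self.n_geographic_areas:
            raise UsageError("areas_per_species out of range")
        self.taxonomy_shape = shape


@dataclass
class SyntheticDataset:
    """A generated table + metadata + tree with its full ground truth."""

    table: TaxonTable
    metadata: SampleMetadata
    tree: PhyloTree
    ground_truth: dict = field(default_factory=dict)


def make_taxonomy(spec: SimulationSpec) -> tuple[list[str], PhyloTree]:
    """Random nested 7-rank taxonomy and an ultrametric tree over its leaves.

    Every leaf gets a complete lineage (prefix property holds trivially);
    each rank's names all appear at least once, so distinct-name counts are
    exactly ``spec.taxonomy_shape`` and non-decreasing from phylum to
    species.  The tree topology follows the taxonomy; node heights are
    equal steps per rank, so the tree is ultrametric.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101]))
    shape = spec.taxonomy_shape
    labels = ("P", "C", "O", "F", "G", "S")
    # parent index of each name at rank r among names at rank r-1
    parents: list[np.ndarray] = []
    for r in range(1, len(shape)):
        n_parent, n_child = shape[r - 1], shape[r]
        # surjective: first n_parent children cover every parent
        par = np.concatenate([
            rng.permutation(n_parent),
            rng.integers(0, n_parent, size=n_child - n_parent),
        ])
        parents.append(par)

    def ancestry(leaf_i: int) -> list[int]:
        idx = [0] * len(shape)
        idx[-1] = leaf_i
        for r in range(len(shape) - 1, 0, -1):
            idx[r - 1] = int(parents[r - 1][idx[r]])
        return idx

    lineages = []
    for leaf in range(shape[-1]):
        idx = ancestry(leaf)
        parts = ["k__Bacteria"] + [
            f"{RANKS[r + 1][0]}__{labels[r]}{idx[r] + 1:03d}"
            for r in range(len(shape))
        ]
        lineages.append("; ".join(parts))

    # ultrametric tree: equal height steps per rank below the root
    heights = np.linspace(1.0, 0.0, len(shape) + 1)  # root, P, C, O, F, G, leaf
    root = TreeNode(name="root")
    # a bifurcating root (two zero-length children) keeps the tree rooted
    # in the sense Faith's PD requires while preserving ultrametry
    halves = [TreeNode(name="rootL"), TreeNode(name="rootR")]
    for h in halves:
        h.length = 0.0
        root.append(h)
    nodes: dict[tuple[int, int], TreeNode] = {}

    def get_node(rank_r: int, idx: int) -> TreeNode:
        # rank_r: 0=phylum .. 4=genus internal levels
        key = (rank_r, idx)
        if key in nodes:
            return nodes[key]
        node = TreeNode(name=f"{labels[rank_r]}{idx + 1:03d}")
        if rank_r == 0:
            parent = halves[idx % 2]
            parent_h = heights[0]
        else:
            parent = get_node(rank_r - 1, int(parents[rank_r - 1][idx]))
            parent_h = heights[rank_r]
        node.length = float(parent_h - heights[rank_r + 1])
        parent.append(node)
        nodes[key] = node
        return node

    for leaf in range(shape[-1]):
        idx = ancestry(leaf)
        genus_node = get_node(len(shape) - 2, idx[-2])
        tip = TreeNode(name=f"S{leaf + 1:03d}")
        tip.length = float(heights[len(shape) - 1] - 0.0)
        genus_node.append(tip)
    return lineages, PhyloTree(root)


def _softmax(eta: np.ndarray) -> np.ndarray:
    e = np.exp(eta - eta.max())
    return e / e.sum()


def simulate_dataset(spec: SimulationSpec) -> SyntheticDataset:
    """Generate a full synthetic study from ``spec``.

    Design: each host species occurs in ``areas_per_species`` randomly
    chosen areas; every occupied (species, area) cell contributes
    ``samples_per_cell`` samples with random site (nested in area), sex,
    and developmental stage.  Counts are Dirichlet-multinomial around the
    softmax of the factor-structured log abundances.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 202]))
    lineages, tree = make_taxonomy(spec)
    n_taxa = spec.taxonomy_shape[-1]
    taxon_ids = [f"S{i + 1:03d}" for i in range(n_taxa)]

    # block structure of the geography signal at signal_rank
    ridx = RANKS.index(spec.signal_rank) - 1  # 0=phylum..5=species
    block_of_taxon = np.array(
        [_lineage_field(lin, ridx) for lin in lineages])
    blocks, block_idx = np.unique(block_of_taxon, return_inverse=True)

    areas = [f"Area{i + 1}" for i in range(spec.n_geographic_areas)]
    sites = {a: [f"{a}-Site{j + 1}" for j in range(spec.sites_per_area)]
             for a in areas}
    species = [f"Host{i + 1:02d}" for i in range(spec.n_host_species)]
    sexes = ["female", "male"]
    stages = ["larva", "adult"]

    shifts = {
        "species": rng.normal(0, spec.effect_species, (len(species), n_taxa)),
        "stage": rng.normal(0, spec.effect_stage, (len(stages), n_taxa)),
        "sex": rng.normal(0, spec.effect_sex, (len(sexes), n_taxa)),
        # geography: one value per (area, block), broadcast to member taxa
        "geography_block": rng.normal(0, spec.effect_geography,
                                      (len(areas), len(blocks))),
    }
    baseline = rng.normal(0, spec.baseline_sd, n_taxa)

    rows = []
    sample_meta = []
    counts = []
    k = 0
    for si, sp in enumerate(species):
        occupied = rng.choice(len(areas), size=spec.areas_per_species,
                              replace=False)
        for ai in np.sort(occupied):
            for _ in range(spec.samples_per_cell):
                k += 1
                sid = f"Sample{k:04d}"
                sxi = int(rng.integers(0, 2))
                sti = int(rng.integers(0, 2))
                site = sites[areas[ai]][int(rng.integers(0, spec.sites_per_area))]
                eta = (baseline
                       + shifts["species"][si]
                       + shifts["stage"][sti]
                       + shifts["sex"][sxi]
                       + shifts["geography_block"][ai][block_idx])
                p = _softmax(eta)
                p = rng.dirichlet(np.maximum(p * spec.dirichlet_concentration,
                                             1e-8))
                depth = int(rng.integers(spec.depth_range[0],
                                         spec.depth_range[1] + 1))
                counts.append(rng.multinomial(depth, p))
                sample_meta.append({
                    "sample_id": sid, "geographic_area": areas[ai],
                    "site": site, "insect_species": sp,
                    "sex": sexes[sxi], "developmental_stage": stages[sti],
                })
                rows.append(sid)

    values = np.vstack(counts).T  # taxa x samples
    table = TaxonTable(taxon_ids=taxon_ids, lineages=lineages,
                       sample_ids=rows, values=values, value_kind="counts")
    meta_df = pd.DataFrame(sample_meta).set_index("sample_id")
    metadata = SampleMetadata(rows, meta_df)
    ground_truth = {
        "spec": _spec_dict(spec),
        "baseline": baseline.tolist(),
        "shifts": {kk: v.tolist() for kk, v in shifts.items()},
        "signal_blocks": blocks.tolist(),
        "block_of_taxon": block_idx.tolist(),
    }
    return SyntheticDataset(table=table, metadata=metadata, tree=tree,
                            ground_truth=ground_truth)


def expected_composition(dataset: SyntheticDataset, sample_id: str) -> np.ndarray:
    """Softmax composition implied by the ground truth for one sample."""
    gt = dataset.ground_truth
    meta = dataset.metadata.factors.loc[sample_id]
    spec = gt["spec"]
    areas = [f"Area{i + 1}" for i in range(spec["n_geographic_areas"])]
    species = [f"Host{i + 1:02d}" for i in range(spec["n_host_species"])]
    ai = areas.index(meta["geographic_area"])
    si = species.index(meta["insect_species"])
    sxi = ["female", "male"].index(meta["sex"])
    sti = ["larva", "adult"].index(meta["developmental_stage"])
    sh = gt["shifts"]
    eta = (np.array(gt["baseline"])
           + np.array(sh["species"])[si]
           + np.array(sh["stage"])[sti]
           + np.array(sh["sex"])[sxi]
           + np.array(sh["geography_block"])[ai][np.array(gt["block_of_taxon"])])
    return _softmax(eta)


def write_fixture(dataset: SyntheticDataset, out_dir) -> dict[str, str]:
    """Write table TSV, metadata TSV, newick tree, and ground-truth JSON.

    The files round-trip through :mod:`gutrace.table_io` into an equal
    dataset; regeneration with the same seed is bitwise identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": str(out / "taxon_table.tsv"),
        "metadata": str(out / "metadata.tsv"),
        "tree": str(out / "tree.nwk"),
        "ground_truth": str(out / "ground_truth.json"),
    }
    write_taxon_table(dataset.table, paths["table"])
    write_metadata(dataset.metadata, paths["metadata"])
    write_tree(dataset.tree, paths["tree"])
    with open(paths["ground_truth"], "w", encoding="utf-8") as fh:
        json.dump(dataset.ground_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def _lineage_field(lineage: str, ridx: int) -> str:
    return lineage.split("; ")[ridx + 1]


def _spec_dict(spec: SimulationSpec) -> dict:
    d = asdict(spec)
    d["taxonomy_shape"] = list(spec.taxonomy_shape)
    d["depth_range"] = list(spec.depth_range)
    return d
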