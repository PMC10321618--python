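"""Synthetic trees, occurrence grids, and status tables.

The generator emulates the statistical structure of a regional endemic
flora so every pipeline stage can be exercised without external data:

* a pure-birth (Yule) ultrametric phylogeny whose tips are grouped into
  monophyletic genera, calibrated to root depth 100;
* log-normally skewed range sizes placed as contiguous grid-cell blocks
  within a long, narrow extent (Chile-like: a few cells wide, many tall);
* an IUCN status table with a fixed count per category over the evaluated
  subset (defaults 7 CR / 54 EN / 23 VU / 7 NT / 4 LC over 95 evaluated
  species), optionally coupled to range size so the most narrowly
  distributed evaluated species receive the most severe categories —
  the regime under which a range-weighted index is expected to track
  threat-weighted EDGE;
* a placement plan withholding a fraction of species from the backbone
  for random within-genus re-imputation.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .metrics import CATEGORIES, NOT_EVALUATED
from .placement import RANDOM_IN_GENUS, PlacementDirective, PlacementPlan
from .ranges import Cell, OccurrenceGrid
from .tree import calibrate_root_depth, genus_of, prune_tips, tip_depths, tip_labels

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_ranges",
    "simulate_statuses",
    "simulate_plan",
    "simulate_dataset",
    "SyntheticDataset",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 200 species in 85 genera, 95 evaluated."""

    n_species: int = 200
    n_genera: int = 85
    birth_rate: float = 1.0
    tree_depth: float = 100.0
    #: log-normal parameters of range size in grid cells (median ~6 cells,
    #: long right tail), truncated below at 1 and clipped to the extent
    range_log_mean: float = 1.8
    range_log_sd: float = 1.1
    #: extent in cells: long and narrow, like a 0.5-degree grid over Chile
    extent_cols: int = 12
    extent_rows: int = 80
    cell_size: float = 0.5
    #: evaluated-species counts per category, most to least severe
    status_counts: dict[str, int] = field(
        default_factory=lambda: {"CR": 7, "EN": 54, "VU": 23, "NT": 7, "LC": 4}
    )
    #: fraction of species withheld from the backbone and re-imputed
    missing_fraction: float = 0.25

    @property
    def n_evaluated(self) -> int:
        return sum(self.status_counts.values())

    def validate(self) -> None:
        if self.n_genera < 1 or self.n_species < self.n_genera:
            raise ValueError("need n_species >= n_genera >= 1")
        if self.n_evaluated > self.n_species:
            raise ValueError("more evaluated species than species")
        if not 0 <= self.missing_fraction < 1:
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.birth_rate <= 0 or self.tree_depth <= 0:
            raise ValueError("birth_rate and tree_depth must be positive")
        if set(self.status_counts) != set(CATEGORIES):
            raise ValueError(f"status_counts must cover exactly {CATEGORIES}")


def _genus_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Partition n_species into n_genera monophyletic blocks, each >= 1,
    with a right-skewed size distribution (many monotypic genera, a few
    speciose ones)."""
    extra = config.n_species - config.n_genera
    weights = rng.dirichlet(np.full(config.n_genera, 0.4))
    sizes = np.ones(config.n_genera, dtype=int)
    if extra:
        sizes += rng.multinomial(extra, weights)
    return sizes


def _yule(n_tips: int, rate: float, rng: np.random.Generator) -> dendropy.Tree:
    """Crown-conditioned pure-birth tree: the root splits at time zero,
    waiting times between births are Exp(rate * k) for k active lineages,
    and all lineages extend to the present, so the tree is exactly
    ultrametric with strictly positive branch lengths."""
    t = dendropy.Tree()
    t.is_rooted = True
    root = t.seed_node
    root.edge.length = None
    if n_tips == 1:
        root.taxon = t.taxon_namespace.require_taxon(label="t0")
        return t
    start: dict[dendropy.Node, float] = {}
    active: list[dendropy.Node] = []
    for _ in range(2):
        c = root.new_child()
        start[c] = 0.0
        active.append(c)
    now = 0.0
    while len(active) < n_tips:
        now += rng.exponential(1.0 / (rate * len(active)))
        parent = active.pop(int(rng.integers(len(active))))
        parent.edge.length = now - start[parent]
        for _ in range(2):
            c = parent.new_child()
            start[c] = now
            active.append(c)
    now += rng.exponential(1.0 / (rate * n_tips))
    for i, leaf in enumerate(active):
        leaf.edge.length = now - start[leaf]
        leaf.taxon = t.taxon_namespace.require_taxon(label=f"t{i}")
    return t


def simulate_tree(
    config: SimulationConfig, rng: np.random.Generator
) -> dendropy.Tree:
    """Genus-structured ultrametric Yule tree, depth-calibrated.

    A genus-level Yule backbone is simulated first; each genus with more
    than one species is then expanded by grafting a within-genus Yule
    subtree onto the genus terminal branch, so genera are monophyletic by
    construction. Tips are labeled ``"GenusXXX speciesYY"``.
    """
    config.validate()
    sizes = _genus_sizes(config, rng)
    backbone = _yule(config.n_genera, config.birth_rate, rng)
    calibrate_root_depth(backbone, config.tree_depth)
    genus_leaves = list(backbone.leaf_node_iter())
    rng.shuffle(genus_leaves)
    for g, (leaf, size) in enumerate(zip(genus_leaves, sizes)):
        genus = f"Genus{g:03d}"
        if size == 1:
            leaf.taxon.label = f"{genus} species00"
            continue
        # crown age of the genus: a uniform fraction of its terminal branch
        sub = _yule(int(size), config.birth_rate * 3.0, rng)
        sub.seed_node.edge.length = None  # stem is set explicitly below
        sub_height = max(tip_depths(sub).values())
        crown = rng.uniform(0.2, 0.8) * leaf.edge.length
        factor = crown / sub_height
        for edge in sub.preorder_edge_iter():
            if edge.length is not None:
                edge.length *= factor
        parent = leaf.parent_node
        stem_length = leaf.edge.length - crown
        parent.remove_child(leaf)
        sub_root = sub.seed_node
        sub_root.edge.length = stem_length
        parent.add_child(sub_root)
        for s, lf in enumerate(sub.leaf_node_iter()):
            lf.taxon = backbone.taxon_namespace.require_taxon(
                label=f"{genus} species{s:02d}"
            )
    calibrate_root_depth(backbone, config.tree_depth)
    return backbone


def simulate_ranges(
    species: list[str], config: SimulationConfig, rng: np.random.Generator
) -> OccurrenceGrid:
    """Log-normal range sizes placed as contiguous cell blocks.

    Cells of the extent are ordered column-major (south to north, then
    east); each species occupies a run of consecutive cells starting at a
    random position, clipped at the end of the extent. Contiguous blocks
    give internal branches realistically nested cell-set unions.
    """
    config.validate()
    n_cells = config.extent_cols * config.extent_rows
    cells: dict[str, frozenset[Cell]] = {}
    for sp in species:
        size = int(round(rng.lognormal(config.range_log_mean, config.range_log_sd)))
        size = max(1, min(size, n_cells))
        start = int(rng.integers(n_cells))
        run = range(start, min(start + size, n_cells))
        cells[sp] = frozenset(
            (idx // config.extent_rows, idx % config.extent_rows) for idx in run
        )
    return OccurrenceGrid(config.cell_size, cells)


def simulate_statuses(
    species: list[str],
    config: SimulationConfig,
    rng: np.random.Generator,
    couple_to_range: bool = True,
    grid: OccurrenceGrid | None = None,
) -> pd.Series:
    """Status table with exact per-category counts over a random evaluated
    subset; remaining species are NE.

    With *couple_to_range* (requires *grid*), evaluated species are sorted
    by ascending range size and categories assigned most-severe-first, so
    the narrowest ranges receive CR/EN — the structure under which RED is
    expected to rank like EDGE. Without coupling, categories are assigned
    at random within the evaluated subset.
    """
    config.validate()
    if couple_to_range and grid is None:
        raise ValueError("couple_to_range requires an occurrence grid")
    species = list(species)
    evaluated_idx = rng.choice(len(species), size=config.n_evaluated, replace=False)
    evaluated = [species[i] for i in sorted(evaluated_idx)]
    if couple_to_range:
        # ties in range size broken at random but reproducibly
        jitter = rng.random(len(evaluated))
        order = sorted(
            range(len(evaluated)),
            key=lambda i: (grid.range_size(evaluated[i]), jitter[i]),
        )
        evaluated = [evaluated[i] for i in order]
    else:
        evaluated = [evaluated[i] for i in rng.permutation(len(evaluated))]
    statuses = pd.Series(NOT_EVALUATED, index=pd.Index(species, name="species"))
    pos = 0
    for cat in reversed(CATEGORIES):  # CR first: most severe -> smallest ranges
        count = config.status_counts[cat]
        statuses.loc[evaluated[pos : pos + count]] = cat
        pos += count
    return statuses.rename("category")


def simulate_plan(
    tree: dendropy.Tree, config: SimulationConfig, rng: np.random.Generator
) -> tuple[dendropy.Tree, PlacementPlan]:
    """Withhold a fraction of species from *tree* into a placement plan.

    Only species with at least one congener remaining in the backbone are
    eligible, so every directive is a ``random_in_genus`` placement; the
    pruned backbone and the plan are returned together.
    """
    config.validate()
    labels = tip_labels(tree)
    n_missing = int(round(config.missing_fraction * len(labels)))
    by_genus: dict[str, list[str]] = {}
    for lab in labels:
        by_genus.setdefault(genus_of(lab), []).append(lab)
    eligible = [
        lab for lab in labels if len(by_genus[genus_of(lab)]) > 1
    ]
    rng.shuffle(eligible)
    withheld: list[str] = []
    remaining = {g: len(v) for g, v in by_genus.items()}
    for lab in eligible:
        if len(withheld) == n_missing:
            break
        g = genus_of(lab)
        if remaining[g] > 1:  # keep >= 1 backbone congener per genus
            withheld.append(lab)
            remaining[g] -= 1
    backbone = tree.clone(depth=1)
    if withheld:
        prune_tips(backbone, set(withheld))
    plan = PlacementPlan(
        [
            PlacementDirective(sp, RANDOM_IN_GENUS, genus_of(sp))
            for sp in sorted(withheld)
        ]
    )
    return backbone, plan


@dataclass
class SyntheticDataset:
    """A complete simulated study: full tree, backbone + plan, grid, statuses."""

    config: SimulationConfig
    full_tree: dendropy.Tree
    backbone: dendropy.Tree
    plan: PlacementPlan
    grid: OccurrenceGrid
    statuses: pd.Series


def simulate_dataset(
    config: SimulationConfig | None = None,
    seed: int = 0,
    couple_to_range: bool = True,
) -> SyntheticDataset:
    """Generate a full synthetic study from one master seed."""
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    rng_tree, rng_range, rng_status, rng_plan = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    tree = simulate_tree(config, rng_tree)
    species = tip_labels(tree)
    grid = simulate_ranges(species, config, rng_range)
    statuses = simulate_statuses(
        species, config, rng_status, couple_to_range=couple_to_range, grid=grid
    )
    backbone, plan = simulate_plan(tree, config, rng_plan)
    return SyntheticDataset(config, tree, backbone, plan, grid, statuses)
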