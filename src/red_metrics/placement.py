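"""Grafting species without sequence data onto an ultrametric backbone tree.

Two placement modes are supported:

* ``midpoint_sister`` — deterministic: the new tip becomes the sister of a
  named tip or clade, attached at the midpoint of the branch subtending the
  target. Used for species whose position is known from the literature
  (typically monotypic genera with a known sister group).
* ``random_in_genus`` — stochastic: the new tip is grafted at a uniformly
  chosen point within its genus. An edge is drawn uniformly at random among
  the edges of the genus clade (terminal edges of congeners, internal edges
  wholly inside the clade, and the edge subtending the genus MRCA), then an
  attachment height uniform along that edge. For a genus with a single
  backbone tip the attachment point is uniform along that tip's terminal
  branch, producing a cherry.

Random placements are replicated (100 times in typical use) to propagate
the topological uncertainty of imputed species into downstream scores; a
master seed makes every replicate an independent pure function of
``(backbone, plan, seed, replicate_index)``.

All grafts preserve ultrametricity exactly: the new terminal branch length
equals the height of the attachment point above the tip level, so the tree
height never changes.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .tree import TreeError, genus_of

__all__ = [
    "PlacementDirective",
    "PlacementPlan",
    "read_placement_plan",
    "place_midpoint_sister",
    "add_species_to_genus_random",
    "generate_replicates",
]

MIDPOINT_SISTER = "midpoint_sister"
RANDOM_IN_GENUS = "random_in_genus"


@dataclass(frozen=True)
class PlacementDirective:
    species: str
    mode: str  # MIDPOINT_SISTER or RANDOM_IN_GENUS
    target: str  # tip/clade label for midpoint, genus name for random

    def __post_init__(self) -> None:
        if self.mode not in (MIDPOINT_SISTER, RANDOM_IN_GENUS):
            raise ValueError(f"unknown placement mode {self.mode!r}")


@dataclass
class PlacementPlan:
    directives: list[PlacementDirective] = field(default_factory=list)

    def validate(self, tree: dendropy.Tree) -> None:
        """Check every directive can be applied to *tree* (in plan order)."""
        tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        genera = {genus_of(t) for t in tips}
        for d in self.directives:
            if d.species in tips:
                raise TreeError(f"planned species {d.species!r} already in tree")
            if d.mode == MIDPOINT_SISTER:
                if d.target not in tips and d.target not in genera:
                    raise TreeError(
                        f"midpoint target {d.target!r} is neither a tip nor a genus"
                    )
            else:
                if d.target not in genera:
                    raise TreeError(f"genus {d.target!r} has no backbone tip")
            # earlier additions are valid context for later directives
            tips.add(d.species)
            genera.add(genus_of(d.species))

    def __len__(self) -> int:
        return len(self.directives)

    def __iter__(self):
        return iter(self.directives)


def read_placement_plan(path: str | Path) -> PlacementPlan:
    """Read a plan from CSV with columns ``species,mode,target``.

    Underscores in species/target names are normalized to spaces to match
    tip-label normalization on Newick read.
    """
    directives = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.DictReader(fh)):
            try:
                directives.append(
                    PlacementDirective(
                        species=row["species"].replace("_", " ").strip(),
                        mode=row["mode"].strip(),
                        target=row["target"].replace("_", " ").strip(),
                    )
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"bad plan row {i + 1}: {exc}") from exc
    return PlacementPlan(directives)


def _node_heights(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Height of every node above the tip level (0 at tips on ultrametric trees)."""
    depths: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    for node in tree.preorder_node_iter():
        if node is not tree.seed_node:
            depths[node] = depths[node.parent_node] + (node.edge.length or 0.0)
    height = max(d for n, d in depths.items() if n.is_leaf())
    return {n: height - d for n, d in depths.items()}


def _mrca(nodes: list[dendropy.Node]) -> dendropy.Node:
    """Most recent common ancestor by ancestor-path intersection; robust on
    trees whose bipartition caches are stale after grafting."""
    paths = []
    for node in nodes:
        path = []
        while node is not None:
            path.append(node)
            node = node.parent_node
        paths.append(path[::-1])
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        candidates = {id(p[depth]) for p in paths}
        if len(candidates) > 1:
            break
        mrca = paths[0][depth]
    return mrca


def _find_target_node(tree: dendropy.Tree, target: str) -> dendropy.Node:
    """Resolve *target* to a node: a tip label, a genus clade, or an internal label."""
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == target:
            return leaf
    genus_tips = [
        leaf for leaf in tree.leaf_node_iter() if genus_of(leaf.taxon.label) == target
    ]
    if genus_tips:
        if len(genus_tips) == 1:
            return genus_tips[0]
        return _mrca(genus_tips)
    for node in tree.preorder_internal_node_iter():
        if node.label == target:
            return node
    raise TreeError(f"placement target {target!r} not found in tree")


def _graft_on_edge(
    tree: dendropy.Tree,
    child: dendropy.Node,
    attach_height: float,
    new_species: str,
) -> None:
    """Insert a new node at *attach_height* on the edge above *child* and
    hang a new tip named *new_species* from it."""
    heights = _node_heights(tree)
    parent = child.parent_node
    lower, upper = heights[child], heights[parent]
    if not (lower <= attach_height <= upper):
        raise TreeError(
            f"attachment height {attach_height} outside edge [{lower}, {upper}]"
        )
    edge_len = child.edge.length
    parent.remove_child(child)
    joint = parent.new_child(edge_length=upper - attach_height)
    joint.add_child(child)
    child.edge.length = edge_len - (upper - attach_height)
    taxon = tree.taxon_namespace.require_taxon(label=new_species)
    joint.new_child(taxon=taxon, edge_length=attach_height)


def place_midpoint_sister(
    tree: dendropy.Tree, new_species: str, target: str
) -> dendropy.Tree:
    """Attach *new_species* as sister to *target* at the midpoint of the
    branch subtending the target tip or clade. Deterministic; preserves
    ultrametricity and tree height."""
    node = _find_target_node(tree, target)
    if node is tree.seed_node or node.parent_node is None:
        raise TreeError(f"target {target!r} has no subtending branch to bisect")
    if not node.edge.length or node.edge.length <= 0:
        raise TreeError(f"branch above target {target!r} has zero length")
    heights = _node_heights(tree)
    attach = heights[node] + node.edge.length / 2.0
    _graft_on_edge(tree, node, attach, new_species)
    return tree


def _genus_clade_edges(
    tree: dendropy.Tree, genus: str
) -> list[dendropy.Node]:
    """Child nodes of the eligible attachment edges for a genus with >= 2 tips:
    every edge inside the genus MRCA clade plus the MRCA's subtending edge."""
    genus_tips = [
        leaf for leaf in tree.leaf_node_iter() if genus_of(leaf.taxon.label) == genus
    ]
    mrca = _mrca(genus_tips)
    nodes = [n for n in mrca.preorder_iter()]
    if mrca.parent_node is None:  # genus MRCA is the root: no subtending edge
        nodes.remove(mrca)
    return [n for n in nodes if n.edge.length and n.edge.length > 0]


def add_species_to_genus_random(
    tree: dendropy.Tree,
    new_species: str,
    genus: str,
    rng: np.random.Generator,
) -> dendropy.Tree:
    """Graft *new_species* at a random position within *genus*.

    The attachment edge is drawn uniformly among eligible edges (not
    length-weighted), then the attachment height uniformly along it.
    Deterministic for a fixed generator state.
    """
    genus_tips = [
        leaf for leaf in tree.leaf_node_iter() if genus_of(leaf.taxon.label) == genus
    ]
    if not genus_tips:
        raise TreeError(f"genus {genus!r} absent from tree")
    if len(genus_tips) == 1:
        child = genus_tips[0]
    else:
        candidates = _genus_clade_edges(tree, genus)
        if not candidates:
            raise TreeError(f"genus {genus!r} clade has no positive-length edge")
        child = candidates[rng.integers(len(candidates))]
    heights = _node_heights(tree)
    lower = heights[child]
    upper = lower + child.edge.length
    attach = rng.uniform(lower, upper)
    _graft_on_edge(tree, child, attach, new_species)
    return tree


def apply_plan(
    tree: dendropy.Tree,
    plan: PlacementPlan,
    rng: np.random.Generator | None = None,
) -> dendropy.Tree:
    """Apply every directive of *plan* to a copy of *tree*, in plan order."""
    out = tree.clone(depth=1)
    for d in plan:
        if d.mode == MIDPOINT_SISTER:
            place_midpoint_sister(out, d.species, d.target)
        else:
            if rng is None:
                raise ValueError("random_in_genus directives require an rng")
            add_species_to_genus_random(out, d.species, d.target, rng)
    return out


def generate_replicates(
    tree: dendropy.Tree,
    plan: PlacementPlan,
    n: int = 100,
    seed: int = 0,
) -> list[dendropy.Tree]:
    """Build *n* replicate trees, each with every planned species grafted.

    Midpoint directives are applied identically in every replicate; random
    directives are re-drawn per replicate from independent substreams of
    the master seed, so replicate ``i`` depends only on
    ``(tree, plan, seed, i)``.
    """
    plan.validate(tree)
    streams = np.random.SeedSequence(seed).spawn(n)
    replicates = []
    for i, ss in enumerate(streams):
        try:
            replicates.append(apply_plan(tree, plan, np.random.default_rng(ss)))
        except TreeError as exc:
            raise TreeError(f"replicate {i}: {exc}") from exc
    return replicates
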