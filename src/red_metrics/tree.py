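"""Phylogeny I/O and manipulation on rooted ultrametric trees.

Trees are represented as :class:`dendropy.Tree` objects throughout the
package. Tip labels are binomials of the form ``"Genus species"``;
underscores in Newick labels are normalized to spaces on read and written
back as underscores. The root edge carries no information for any of the
indices computed here (it would contribute equally to every tip), so any
root edge length present in the input is discarded.
"""

from __future__ import annotations

from pathlib import Path

import dendropy

__all__ = [
    "read_newick",
    "parse_newick",
    "write_newick",
    "tree_to_newick",
    "tip_labels",
    "tip_depths",
    "tree_height",
    "genus_of",
    "check_ultrametric",
    "calibrate_root_depth",
    "prune_tips",
    "total_branch_length",
]

DEFAULT_ULTRAMETRIC_RTOL = 1e-6


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


def genus_of(label: str) -> str:
    """Genus of a binomial tip label: the token before the first space."""
    return label.split()[0] if label else ""


def _validate(tree: dendropy.Tree) -> dendropy.Tree:
    tree.is_rooted = True
    # a Newick root edge length parses as a unifurcation above the true
    # root; drop it along with the root edge, which is meaningless here
    while len(tree.seed_node.child_nodes()) == 1 and not tree.seed_node.is_leaf():
        new_root = tree.seed_node.child_nodes()[0]
        new_root.parent_node = None
        tree.seed_node = new_root
    tree.seed_node.edge.length = None
    seen: set[str] = set()
    dupes: set[str] = set()
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label if leaf.taxon else None
        if not label:
            raise TreeError("tree contains an unlabeled tip")
        if label in seen:
            dupes.add(label)
        seen.add(label)
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        if node.edge.length is None:
            where = node.taxon.label if node.taxon else "an internal node"
            raise TreeError(f"missing branch length on the edge above {where}")
        if node.edge.length < 0:
            where = node.taxon.label if node.taxon else "an internal node"
            raise TreeError(f"negative branch length on the edge above {where}")
    return tree


def _get_tree(**kwargs) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(schema="newick", **kwargs)
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise TreeError(f"duplicate tip labels: {exc.message}") from exc


def parse_newick(newick: str) -> dendropy.Tree:
    """Parse a single rooted Newick string into a validated tree."""
    return _validate(_get_tree(data=newick))


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a single Newick tree from *path*.

    Underscores in unquoted labels become spaces (Newick convention).
    Raises :class:`TreeError` on missing branch lengths or duplicate tips.
    """
    return _validate(_get_tree(path=str(path)))


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True)


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    """Write *tree* as Newick; spaces in labels are emitted as underscores."""
    Path(path).write_text(tree_to_newick(tree))


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    """Root-to-tip path length for every tip, keyed by tip label."""
    depth: dict[dendropy.Node, float] = {tree.seed_node: 0.0}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        depth[node] = depth[node.parent_node] + (node.edge.length or 0.0)
        if node.is_leaf():
            out[node.taxon.label] = depth[node]
    if tree.seed_node.is_leaf():
        out[tree.seed_node.taxon.label] = 0.0
    return out


def tree_height(tree: dendropy.Tree) -> float:
    """Mean root-to-tip depth (equals the common depth on ultrametric trees)."""
    depths = tip_depths(tree)
    return sum(depths.values()) / len(depths)


def check_ultrametric(tree: dendropy.Tree) -> float:
    """Maximum relative deviation of tip depths from their mean.

    Returns ``max_t |depth(t) - mean| / mean``; 0 for a perfectly
    ultrametric tree. The caller compares the result against a tolerance
    (``DEFAULT_ULTRAMETRIC_RTOL`` by default elsewhere in the package).
    """
    depths = list(tip_depths(tree).values())
    if len(depths) < 2:
        return 0.0
    mean = sum(depths) / len(depths)
    if mean == 0:
        return 0.0
    return max(abs(d - mean) for d in depths) / mean


def calibrate_root_depth(
    tree: dendropy.Tree,
    depth: float = 100.0,
    rel_tol: float = DEFAULT_ULTRAMETRIC_RTOL,
) -> dendropy.Tree:
    """Rescale all branch lengths so the root-to-tip height equals *depth*.

    The tree must already be ultrametric within *rel_tol*; rankings of all
    downstream indices are invariant to this rescaling, so the target depth
    is an arbitrary relative unit (100 by convention here).
    """
    dev = check_ultrametric(tree)
    if dev > rel_tol:
        raise TreeError(
            f"tree is not ultrametric (relative deviation {dev:.3g} > {rel_tol:g})"
        )
    height = tree_height(tree)
    if height <= 0:
        raise TreeError("cannot calibrate a zero-height tree")
    factor = depth / height
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= factor
    return tree


def prune_tips(tree: dendropy.Tree, labels: set[str] | list[str]) -> dendropy.Tree:
    """Remove the named tips, suppressing the unifurcations this creates.

    Branch lengths across suppressed nodes are summed, so pairwise path
    lengths among surviving tips are unchanged.
    """
    labels = set(labels)
    if not labels:
        return tree
    present = set(tip_labels(tree))
    unknown = labels - present
    if unknown:
        raise TreeError(f"cannot prune unknown tips: {sorted(unknown)}")
    if len(present - labels) < 2:
        raise TreeError("pruning would leave fewer than 2 tips")
    tree.prune_taxa_with_labels(list(labels))
    tree.seed_node.edge.length = None
    return tree


def total_branch_length(tree: dendropy.Tree) -> float:
    """Sum of all branch lengths (root edge excluded)."""
    return sum(
        node.edge.length or 0.0
        for node in tree.preorder_node_iter()
        if node is not tree.seed_node
    )
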