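"""Occurrence gridding, range-weighted trees, and the RED index.

A species' range is measured as the number of cells of a regular
longitude/latitude grid (0.5 x 0.5 degrees by default) in which it occurs.
The range-weighted tree divides every branch length by the number of grid
cells occupied by the union of the occurrences of the species descending
from that branch, so branches subtending narrowly distributed lineages keep
(most of) their length while widespread lineages are shortened.

RED (Relative Evolutionary Distinctness) is fair-proportion ED computed on
the range-weighted tree. It requires no threat assessments, only
occurrences, and serves as an EDGE surrogate when red-list categories are
missing for many species.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import floor
from pathlib import Path

import dendropy
import pandas as pd

from .metrics import _score_table, fair_proportion_ed
from .tree import TreeError

__all__ = [
    "OccurrenceGrid",
    "assign_grid_cells",
    "read_occurrences",
    "branch_ranges",
    "range_weight_tree",
    "red_scores",
]

Cell = tuple[int, int]


@dataclass(frozen=True)
class OccurrenceGrid:
    """Per-species sets of occupied grid cells at a fixed cell size.

    Cells are half-open squares ``[i*size, (i+1)*size) x [j*size,
    (j+1)*size)`` indexed by ``(i, j) = (floor(lon/size), floor(lat/size))``;
    a point on a cell boundary belongs to the higher-index cell.
    """

    cell_size: float
    cells: dict[str, frozenset[Cell]]

    def range_size(self, species: str) -> int:
        return len(self.cells[species])

    def species(self) -> list[str]:
        return sorted(self.cells)

    def __contains__(self, species: str) -> bool:
        return species in self.cells


def assign_grid_cells(
    points: pd.DataFrame, cell_size: float = 0.5
) -> OccurrenceGrid:
    """Grid per-species point records (columns ``species, lon, lat``).

    Coordinates must be decimal degrees with lon in [-180, 180] and lat in
    [-90, 90]; out-of-range records are a hard error naming the row.
    Duplicate cells per species are deduplicated.
    """
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    cells: dict[str, set[Cell]] = {}
    for row_no, (sp, lon, lat) in enumerate(
        zip(points["species"], points["lon"], points["lat"]), start=1
    ):
        if not (-180.0 <= lon <= 180.0 and -90.0 <= lat <= 90.0):
            raise ValueError(
                f"record {row_no}: coordinates ({lon}, {lat}) outside "
                "lon [-180,180] / lat [-90,90]"
            )
        cells.setdefault(str(sp), set()).add(
            (floor(lon / cell_size), floor(lat / cell_size))
        )
    return OccurrenceGrid(cell_size, {s: frozenset(c) for s, c in cells.items()})


def read_occurrences(path: str | Path, cell_size: float = 0.5) -> OccurrenceGrid:
    """Read occurrences from CSV in either of two dialects, auto-detected
    by header: point records ``species,lon,lat`` or precomputed presences
    ``species,cell_i,cell_j``. Species names have underscores normalized
    to spaces."""
    df = pd.read_csv(path)
    cols = set(df.columns)
    df["species"] = df["species"].str.replace("_", " ").str.strip()
    if {"lon", "lat"} <= cols:
        return assign_grid_cells(df, cell_size)
    if {"cell_i", "cell_j"} <= cols:
        cells: dict[str, set[Cell]] = {}
        for sp, i, j in zip(df["species"], df["cell_i"], df["cell_j"]):
            cells.setdefault(sp, set()).add((int(i), int(j)))
        return OccurrenceGrid(cell_size, {s: frozenset(c) for s, c in cells.items()})
    raise ValueError(
        "occurrence CSV must have columns species,lon,lat or species,cell_i,cell_j"
    )


def branch_ranges(
    tree: dendropy.Tree,
    grid: OccurrenceGrid,
    assume_range_one: bool = False,
) -> dict[dendropy.Node, int]:
    """Range (number of occupied grid cells) of the species set descending
    from each edge, keyed by the edge's child node.

    The range of an edge is the cardinality of the union of the cell sets
    of its descendant tips, hence >= 1. Tips absent from the grid are an
    error unless *assume_range_one* grants them a single private cell.
    """
    missing = [
        leaf.taxon.label
        for leaf in tree.leaf_node_iter()
        if leaf.taxon.label not in grid
    ]
    if missing and not assume_range_one:
        raise TreeError(f"tips without occurrence data: {sorted(missing)}")
    fallback = {sp: frozenset({("__private__", k)}) for k, sp in enumerate(missing)}
    union: dict[dendropy.Node, frozenset] = {}
    ranges: dict[dendropy.Node, int] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            union[node] = fallback.get(label) or grid.cells[label]
        else:
            union[node] = frozenset().union(*(union[c] for c in node.child_nodes()))
        ranges[node] = len(union[node])
    return ranges


def range_weight_tree(
    tree: dendropy.Tree,
    grid: OccurrenceGrid,
    assume_range_one: bool = False,
) -> dendropy.Tree:
    """Copy of *tree* with every branch length divided by its range.

    Topology is unchanged; every weighted length is <= the original since
    ranges are >= 1, with equality exactly when all descendants of the
    branch share a single cell.
    """
    out = tree.clone(depth=1)
    ranges = branch_ranges(out, grid, assume_range_one=assume_range_one)
    for node in out.preorder_node_iter():
        if node is not out.seed_node and node.edge.length is not None:
            node.edge.length = node.edge.length / ranges[node]
    return out


def red_scores(
    replicates: list[dendropy.Tree],
    grid: OccurrenceGrid,
    assume_range_one: bool = False,
) -> pd.DataFrame:
    """Per-species RED across replicate trees, with a leading median column.

    RED is fair-proportion ED on the range-weighted tree; it is computed
    for every tip, evaluated or not.
    """
    if not replicates:
        raise ValueError("no replicate trees supplied")
    cols = [
        fair_proportion_ed(range_weight_tree(t, grid, assume_range_one))
        for t in replicates
    ]
    table = _score_table(cols, "RED")
    return table
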