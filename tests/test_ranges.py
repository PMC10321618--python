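"""Occurrence gridding, branch ranges, range-weighted trees, and RED."""

import numpy as np
import pandas as pd
import pytest

from red_metrics import (
    OccurrenceGrid,
    TreeError,
    assign_grid_cells,
    branch_ranges,
    fair_proportion_ed,
    parse_newick,
    range_weight_tree,
    red_scores,
    total_branch_length,
)
from red_metrics.ranges import read_occurrences

from conftest import random_tree


def points(*rows):
    return pd.DataFrame(rows, columns=["species", "lon", "lat"])


class TestGridAssignment:
    def test_floor_convention(self):
        grid = assign_grid_cells(points(("S s", -71.2, -33.6)), 0.5)
        assert grid.cells["S s"] == {(-143, -68)}

    def test_boundary_point_goes_to_upper_cell(self):
        grid = assign_grid_cells(points(("S s", -71.0, -33.5)), 0.5)
        assert grid.cells["S s"] == {(-142, -67)}

    def test_two_points_one_cell_deduplicated(self):
        grid = assign_grid_cells(
            points(("S s", 10.1, 20.1), ("S s", 10.3, 20.4)), 0.5
        )
        assert grid.range_size("S s") == 1

    def test_out_of_range_coordinates_error_names_record(self):
        with pytest.raises(ValueError, match="record 2"):
            assign_grid_cells(points(("A a", 0, 0), ("B b", 200.0, 0)), 0.5)

    def test_presence_dialect_autodetected(self, tmp_path):
        path = tmp_path / "occ.csv"
        path.write_text("species,cell_i,cell_j\nA_a,0,1\nA_a,0,2\nB_b,5,5\n")
        grid = read_occurrences(path)
        assert grid.cells["A a"] == {(0, 1), (0, 2)}
        assert grid.range_size("B b") == 1


class TestBranchRanges:
    def test_cherry_union(self):
        t = parse_newick("((A_a:1,B_b:1)ab:1,C_c:2);")
        grid = OccurrenceGrid(
            0.5,
            {
                "A a": frozenset({(0, 0), (0, 1)}),
                "B b": frozenset({(0, 1), (0, 2)}),
                "C c": frozenset({(9, 9)}),
            },
        )
        ranges = branch_ranges(t, grid)
        by_tips = {
            frozenset(l.taxon.label for l in n.leaf_iter()): r
            for n, r in ranges.items()
        }
        assert by_tips[frozenset({"A a", "B b"})] == 3
        assert by_tips[frozenset({"A a"})] == 2

    def test_missing_tip_is_error_unless_fallback(self):
        t = parse_newick("(A_a:1,B_b:1);")
        grid = OccurrenceGrid(0.5, {"A a": frozenset({(0, 0)})})
        with pytest.raises(TreeError, match="B b"):
            branch_ranges(t, grid)
        ranges = branch_ranges(t, grid, assume_range_one=True)
        tips = {n.taxon.label: r for n, r in ranges.items() if n.is_leaf()}
        assert tips["B b"] == 1

    def test_matches_brute_force_descendant_union(self, rng):
        for _ in range(10):
            t = random_tree(rng, 12)
            labels = [l.taxon.label for l in t.leaf_node_iter()]
            cells = {
                lab: frozenset(
                    (int(c), 0) for c in rng.choice(30, size=rng.integers(1, 6))
                )
                for lab in labels
            }
            grid = OccurrenceGrid(0.5, cells)
            got = branch_ranges(t, grid)
            for node, r in got.items():
                union = set()
                for leaf in node.leaf_iter():
                    union |= cells[leaf.taxon.label]
                assert r == len(union)


class TestRangeWeighting:
    def test_stated_division(self):
        t = parse_newick("((A_a:1,B_b:1):2,C_c:2);")
        grid = OccurrenceGrid(
            0.5,
            {
                "A a": frozenset({(0, 0)}),
                "B b": frozenset({(1, 0), (2, 0), (3, 0)}),
                "C c": frozenset({(9, 9)}),
            },
        )
        wt = range_weight_tree(t, grid)
        lengths = {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.edge.length
            for n in wt.preorder_node_iter()
            if n is not wt.seed_node
        }
        assert lengths[frozenset({"A a", "B b"})] == pytest.approx(2 / 4)
        assert lengths[frozenset({"B b"})] == pytest.approx(1 / 3)

    def test_shared_single_cell_is_identity(self, rng):
        t = random_tree(rng, 8)
        cell = frozenset({(3, 3)})
        grid = OccurrenceGrid(0.5, {l.taxon.label: cell for l in t.leaf_node_iter()})
        wt = range_weight_tree(t, grid)
        assert total_branch_length(wt) == pytest.approx(total_branch_length(t))

    def test_weighted_lengths_never_exceed_original(self, rng):
        t = random_tree(rng, 10)
        labels = [l.taxon.label for l in t.leaf_node_iter()]
        grid = OccurrenceGrid(
            0.5,
            {
                lab: frozenset((int(c), 0) for c in rng.choice(20, size=3))
                for lab in labels
            },
        )
        wt = range_weight_tree(t, grid)
        orig = {
            frozenset(l.taxon.label for l in n.leaf_iter()): n.edge.length
            for n in t.preorder_node_iter()
            if n is not t.seed_node
        }
        for n in wt.preorder_node_iter():
            if n is wt.seed_node:
                continue
            key = frozenset(l.taxon.label for l in n.leaf_iter())
            assert n.edge.length <= orig[key] + 1e-12


class TestRed:
    grid = OccurrenceGrid(
        0.5,
        {
            "A a": frozenset({(0, 0), (0, 1)}),
            "B b": frozenset({(1, 0)}),
            "C c": frozenset({(2, 0), (2, 1), (2, 2), (2, 3)}),
        },
    )

    def test_hand_computed_example(self, three_tip):
        red = red_scores([three_tip], self.grid)
        assert red["median"].to_dict() == pytest.approx(
            {"A a": 2 / 3, "B b": 7 / 6, "C c": 0.5}
        )

    def test_red_sum_is_weighted_tree_length(self, three_tip):
        wt = range_weight_tree(three_tip, self.grid)
        red = red_scores([three_tip], self.grid)
        assert red["median"].sum() == pytest.approx(total_branch_length(wt))

    def test_red_at_most_ed(self, three_tip):
        red = red_scores([three_tip], self.grid)["median"]
        ed = fair_proportion_ed(three_tip)
        assert (red <= ed + 1e-12).all()

    def test_shrinking_a_range_never_decreases_own_red(self, three_tip):
        smaller = OccurrenceGrid(
            0.5, {**self.grid.cells, "C c": frozenset({(2, 0), (2, 1)})}
        )
        before = red_scores([three_tip], self.grid)["median"]
        after = red_scores([three_tip], smaller)["median"]
        assert after["C c"] >= before["C c"] - 1e-12

    def test_invariant_to_cell_relabeling(self, three_tip):
        relabeled = OccurrenceGrid(
            0.5,
            {
                sp: frozenset((i + 100, j - 50) for i, j in cells)
                for sp, cells in self.grid.cells.items()
            },
        )
        a = red_scores([three_tip], self.grid)["median"]
        b = red_scores([three_tip], relabeled)["median"]
        assert a.to_dict() == pytest.approx(b.to_dict())
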