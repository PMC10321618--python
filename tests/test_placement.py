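"""Midpoint-sister grafting and random within-genus imputation."""

import numpy as np
import pytest

from red_metrics import (
    PlacementDirective,
    PlacementPlan,
    TreeError,
    add_species_to_genus_random,
    check_ultrametric,
    fair_proportion_ed,
    generate_replicates,
    parse_newick,
    place_midpoint_sister,
    tip_labels,
    tree_height,
)
from red_metrics.placement import read_placement_plan
from red_metrics.tree import tip_depths, tree_to_newick


class TestMidpointSister:
    def test_terminal_branch_bisected(self):
        t = parse_newick("(A_a:2,B_b:2);")
        place_midpoint_sister(t, "X x", "A a")
        depths = tip_depths(t)
        assert depths == pytest.approx({"A a": 2, "B b": 2, "X x": 2})
        # attachment node sits at depth 1 = midpoint of the length-2 branch
        assert check_ultrametric(t) == 0.0
        ed = fair_proportion_ed(t)
        assert ed["A a"] == pytest.approx(1 + 0.5)  # 1 + 1/2 shared

    def test_clade_target_uses_genus_mrca(self):
        # X becomes sister to genus Aim (two tips), on the clade's stem branch
        t = parse_newick("((Aim_a:1,Aim_b:1):2,Out_o:3);")
        place_midpoint_sister(t, "Iva x", "Aim")
        assert sorted(tip_labels(t)) == ["Aim a", "Aim b", "Iva x", "Out o"]
        assert check_ultrametric(t) < 1e-12
        # new tip attaches at height 2 (midpoint of stem from 1 to 3)
        assert tip_depths(t)["Iva x"] == pytest.approx(3.0)

    def test_zero_length_target_branch_is_error(self):
        t = parse_newick("((A_a:0,B_b:0):2,C_c:2);")
        with pytest.raises(TreeError, match="zero length"):
            place_midpoint_sister(t, "X x", "A a")

    def test_height_unchanged(self):
        t = parse_newick("((A_a:1,B_b:1):1,C_c:2);")
        h = tree_height(t)
        place_midpoint_sister(t, "X x", "B b")
        assert tree_height(t) == pytest.approx(h)


class TestRandomInGenus:
    def test_single_congener_forces_cherry(self):
        for seed in range(5):
            t = parse_newick("((Aa_x:1,Ab_y:1):1,Ac_z:2);")
            add_species_to_genus_random(
                t, "Ac w", "Ac", np.random.default_rng(seed)
            )
            assert check_ultrametric(t) < 1e-12
            # forced topology: the two Ac species form a cherry
            leaf = next(
                l for l in t.leaf_node_iter() if l.taxon.label == "Ac w"
            )
            sibs = {n.taxon.label for n in leaf.parent_node.leaf_iter()}
            assert sibs == {"Ac z", "Ac w"}

    def test_same_seed_same_tree(self):
        trees = []
        for _ in range(2):
            t = parse_newick("(((Aa_x:1,Aa_y:1):1,Aa_z:2):1,Bb_q:3);")
            add_species_to_genus_random(t, "Aa w", "Aa", np.random.default_rng(7))
            trees.append(tree_to_newick(t))
        assert trees[0] == trees[1]

    def test_absent_genus_is_error(self):
        t = parse_newick("(A_a:1,B_b:1);")
        with pytest.raises(TreeError, match="absent"):
            add_species_to_genus_random(t, "Z z", "Z", np.random.default_rng(0))

    def test_edge_choice_uniform_over_eligible_edges(self):
        """Attachment edges are chosen uniformly per edge, not by length.

        Genus Aa clade: tips x (terminal edge 1), y (terminal edge 1), and
        the clade stem of length 2 — three eligible edges; each should be
        hit ~1/3 of the time despite unequal lengths.
        """
        newick = "((Aa_x:1,Aa_y:1):2,Bb_q:3);"
        counts = {"x": 0, "y": 0, "stem": 0}
        rng = np.random.default_rng(123)
        n = 3000
        for _ in range(n):
            t = parse_newick(newick)
            add_species_to_genus_random(t, "Aa w", "Aa", rng)
            new = next(l for l in t.leaf_node_iter() if l.taxon.label == "Aa w")
            sibs = {x.taxon.label for x in new.parent_node.leaf_iter()} - {"Aa w"}
            if sibs == {"Aa x"}:
                counts["x"] += 1
            elif sibs == {"Aa y"}:
                counts["y"] += 1
            else:
                counts["stem"] += 1
        for key, c in counts.items():
            # binomial(3000, 1/3): 5 sigma ~ 0.043
            assert abs(c / n - 1 / 3) < 0.05, (key, counts)


class TestReplicates:
    backbone = "(((Aa_x:1,Aa_y:1):1,Ab_z:2):1,Bb_q:3);"

    def plan(self):
        return PlacementPlan(
            [
                PlacementDirective("Aa w", "random_in_genus", "Aa"),
                PlacementDirective("Bb r", "random_in_genus", "Bb"),
            ]
        )

    def test_empty_plan_identity(self):
        t = parse_newick(self.backbone)
        reps = generate_replicates(t, PlacementPlan(), n=1, seed=0)
        assert tree_to_newick(reps[0]) == tree_to_newick(t)

    def test_all_replicates_have_full_tip_set(self):
        t = parse_newick(self.backbone)
        reps = generate_replicates(t, self.plan(), n=20, seed=5)
        want = {"Aa x", "Aa y", "Ab z", "Bb q", "Aa w", "Bb r"}
        for r in reps:
            assert set(tip_labels(r)) == want
            assert check_ultrametric(r) < 1e-12
            assert tree_height(r) == pytest.approx(3.0)

    def test_replicates_deterministic_in_master_seed(self):
        t = parse_newick(self.backbone)
        a = generate_replicates(t, self.plan(), n=4, seed=11)
        b = generate_replicates(t, self.plan(), n=4, seed=11)
        assert [tree_to_newick(x) for x in a] == [tree_to_newick(y) for y in b]
        c = generate_replicates(t, self.plan(), n=4, seed=12)
        assert [tree_to_newick(x) for x in a] != [tree_to_newick(y) for y in c]

    def test_backbone_species_ed_constant_across_replicates(self):
        t = parse_newick(self.backbone)
        # species in genera untouched by the plan keep a constant ED
        reps2 = generate_replicates(
            t,
            PlacementPlan([PlacementDirective("Aa w", "random_in_genus", "Aa")]),
            n=10,
            seed=3,
        )
        eds2 = {fair_proportion_ed(r)["Bb q"] for r in reps2}
        assert len(eds2) == 1

    def test_plan_validation_rejects_existing_species(self):
        t = parse_newick(self.backbone)
        bad = PlacementPlan([PlacementDirective("Aa x", "random_in_genus", "Aa")])
        with pytest.raises(TreeError, match="already in tree"):
            generate_replicates(t, bad, n=1, seed=0)


def test_plan_csv_round_trip(tmp_path):
    path = tmp_path / "plan.csv"
    path.write_text(
        "species,mode,target\n"
        "Ivania_juncalensis,midpoint_sister,Aimara\n"
        "Calceolaria_nana,random_in_genus,Calceolaria\n"
    )
    plan = read_placement_plan(path)
    assert len(plan) == 2
    d = plan.directives[0]
    assert d.species == "Ivania juncalensis" and d.target == "Aimara"
    assert plan.directives[1].mode == "random_in_genus"
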