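"""Shared fixtures: hand-built trees and random tree generators."""

from __future__ import annotations

import numpy as np
import pytest

import dendropy
from red_metrics import parse_newick
from red_metrics.simulate import _yule


@pytest.fixture
def cherry():
    return parse_newick("(A_a:1,B_b:1);")


@pytest.fixture
def three_tip():
    # ((A a:1, B b:1):1, C c:2) — ultrametric, depth 2
    return parse_newick("((A_a:1,B_b:1):1,C_c:2);")


def random_ultrametric(rng: np.random.Generator, n_tips: int) -> dendropy.Tree:
    """Random ultrametric tree via the package's Yule sampler."""
    return _yule(n_tips, 1.0, rng)


def random_tree(rng: np.random.Generator, n_tips: int) -> dendropy.Tree:
    """Random rooted tree with arbitrary (non-ultrametric) branch lengths
    and occasional polytomies, built by repeated random joins."""
    tree = dendropy.Tree()
    tree.is_rooted = True
    nodes = []
    for i in range(n_tips):
        node = dendropy.Node(edge_length=float(rng.uniform(0.1, 3.0)))
        node.taxon = tree.taxon_namespace.require_taxon(label=f"G{i} sp{i}")
        nodes.append(node)
    while len(nodes) > 1:
        k = min(len(nodes), int(rng.choice([2, 2, 2, 3])))  # occasional polytomy
        picks = [nodes.pop(int(rng.integers(len(nodes)))) for _ in range(k)]
        parent = dendropy.Node(edge_length=float(rng.uniform(0.1, 3.0)))
        for p in picks:
            parent.add_child(p)
        nodes.append(parent)
    for child in nodes[0].child_nodes():
        tree.seed_node.add_child(child)
    tree.seed_node.edge.length = None
    return tree


@pytest.fixture
def rng():
    return np.random.default_rng(20230705)
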