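"""Shared helpers: random additive trees, unrooted RF distance, fixtures."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare

from pandiverge import DistanceMatrix, SimulationConfig, simulate_tree


def rf_unrooted(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> int:
    """Robinson–Foulds symmetric difference with both trees unrooted."""
    tns = dendropy.TaxonNamespace()
    trees = []
    for t in (tree_a, tree_b):
        c = dendropy.Tree.get(data=t.as_string(schema="newick"),
                              schema="newick", taxon_namespace=tns)
        c.is_rooted = False
        c.collapse_basal_bifurcation()
        c.encode_bipartitions()
        trees.append(c)
    return treecompare.symmetric_difference(*trees)


def random_tree_with_lengths(n_leaves: int, rng: np.random.Generator,
                             min_len: float = 0.1,
                             max_len: float = 1.0) -> dendropy.Tree:
    """Random binary tree with uniform branch lengths (for additivity tests)."""
    cfg = SimulationConfig(n_genomes=max(n_leaves, 3), seed=int(rng.integers(2**31)))
    tree = simulate_tree(cfg)
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None:
            edge.length = float(rng.uniform(min_len, max_len))
    return tree


def additive_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic (path-length) distance matrix of a tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = pdm.distance(taxa[i], taxa[j])
    return DistanceMatrix(labels, values)


def patristic_lookup(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1:]:
            d = pdm.distance(a, b)
            out[(a.label, b.label)] = d
            out[(b.label, a.label)] = d
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
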