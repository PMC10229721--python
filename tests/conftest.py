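import numpy as np
import pandas as pd
import pytest

from phylofauna.phylo import DistanceMatrix, parse_newick


@pytest.fixture
def three_tip_tree():
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def triangle_dmat():
    """d(A,B)=2, d(A,C)=4, d(B,C)=6."""
    return DistanceMatrix(
        ("A", "B", "C"),
        np.array([[0.0, 2.0, 4.0], [2.0, 0.0, 6.0], [4.0, 6.0, 0.0]]),
    )


def random_tree_newick(n_tips, rng, prefix="t"):
    """Random binary tree via recursive splitting; branch lengths U(0.1, 2)."""

    def build(labels):
        if len(labels) == 1:
            return f"{labels[0]}:{rng.uniform(0.1, 2.0):.6f}"
        k = int(rng.integers(1, len(labels)))
        idx = rng.permutation(len(labels))
        left = [labels[i] for i in idx[:k]]
        right = [labels[i] for i in idx[k:]]
        return f"({build(left)},{build(right)}):{rng.uniform(0.1, 2.0):.6f}"

    labels = [f"{prefix}{i}" for i in range(n_tips)]
    k = int(rng.integers(1, n_tips))
    return f"({build(labels[:k])},{build(labels[k:])});"


def brute_force_patristic(tree):
    """Independent path-sum oracle: shortest paths on the tree graph."""
    import networkx as nx

    g = nx.Graph()
    for edge in tree.tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length)
    tips = {leaf.taxon.label: id(leaf) for leaf in tree.tree.leaf_node_iter()}
    labels = sorted(tips)
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = nx.shortest_path_length(g, tips[labels[i]], tips[labels[j]], weight="weight")
            out[i, j] = out[j, i] = d
    return labels, out


def random_abundances(n, rng):
    p = rng.dirichlet(np.ones(n))
    return p


@pytest.fixture
def fauna_table():
    return pd.DataFrame(
        [
            ("s1", "Lumbricus1", "earthworm", "epigeic", 5),
            ("s1", "Aporrectodea1", "earthworm", "endogeic", 3),
            ("s1", "Coll_a", "springtail", "hemiedaphic", 3),
            ("s1", "Coll_b", "springtail", "hemiedaphic", 4),
            ("s1", "Coll_c", "springtail", "euedaphic", 2),
            ("s1", "Mite_a", "mite", "actinedid", 10),
            ("s1", "Mite_b", "mite", "gamasid", 6),
            ("s1", "Nem_ba", "nematode", "Ba2", 100),
            ("s1", "Nem_ca", "nematode", "Ca3", 50),
            ("s2", "Lumbricus1", "earthworm", "epigeic", 2),
            ("s2", "Coll_a", "springtail", "euedaphic", 7),
            ("s2", "Nem_fu", "nematode", "Fu2", 40),
            ("s2", "Nem_om", "nematode", "Om4", 8),
            ("s2", "Nem_pl", "nematode", "Pl2", 30),
        ],
        columns=["site", "taxon", "major_group", "subgroup", "count"],
    )
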