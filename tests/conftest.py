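"""Shared fixtures and tree-building helpers."""

from __future__ import annotations

import numpy as np
import pytest

from chronosite import SimConfig, parse_newick, simulate_tree
from chronosite.tree import SpeciesTree


def caterpillar_newick(n: int) -> str:
    """Fully unbalanced topology over taxa T1..Tn (no branch lengths)."""
    s = "(T1,T2)"
    for i in range(3, n + 1):
        s = f"({s},T{i})"
    return s + ";"


def balanced_newick(n: int) -> str:
    """Fully balanced topology; n must be a power of two."""
    leaves = [f"T{i}" for i in range(1, n + 1)]
    while len(leaves) > 1:
        leaves = [
            f"({leaves[i]},{leaves[i + 1]})" for i in range(0, len(leaves), 2)
        ]
    return leaves[0] + ";"


def random_bds_tree(n_taxa: int, seed: int) -> SpeciesTree:
    return simulate_tree(SimConfig(n_taxa=n_taxa, seed=seed))


def set_clade_age(tree: SpeciesTree, labels: set[str], age: float) -> int:
    nid = tree.mrca(labels)
    tree.nodes[nid].age = age
    return nid


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture
def three_taxon_tree():
    return parse_newick("((A,B),C);")
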