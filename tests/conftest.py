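"""Shared fixtures and simulation helpers for the test suite.

The CTMC simulator here walks trees node by node and samples states
directly from transition matrices; it is deliberately separate from the
package's own bulk generator so likelihood-recovery tests do not validate
the engine against itself.
"""

from __future__ import annotations

import numpy as np
import pytest

from radsignal import phylo_core as pc
from radsignal.likelihood import SubstitutionModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


def simulate_on_tree(tree, n_sites: int, model: SubstitutionModel,
                     rng: np.random.Generator) -> pc.Alignment:
    """Plain root-to-tips CTMC simulation of ``n_sites`` iid characters."""
    k = model.n_states
    pi = model.equilibrium_frequencies
    seqs = {id(tree.seed_node): rng.choice(k, size=n_sites, p=pi)}
    for nd in tree.preorder_node_iter():
        if nd is tree.seed_node:
            continue
        P = model.transition_matrices(np.array([nd.edge.length or 0.0]))[0]
        rows = P[seqs[id(nd.parent_node)]]
        cum = np.cumsum(rows, axis=1)
        u = rng.random((n_sites, 1))
        seqs[id(nd)] = (u > cum[:, :-1]).sum(axis=1)
    symbols = np.array(list(model.states))
    return pc.Alignment.from_dict(
        {lf.taxon.label: "".join(symbols[seqs[id(lf)]])
         for lf in tree.leaf_node_iter()},
        alphabet=model.states)


def random_binary_tree(labels, rng: np.random.Generator,
                       with_lengths: bool = True):
    """Random rooted binary topology by random pair joins; exponential
    branch lengths when requested."""
    parts = [f"{lab}" for lab in labels]
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        a, b = parts[i], parts[j]
        if with_lengths:
            la, lb = rng.exponential(0.1, size=2) + 0.01
            merged = f"({a}:{la:.6f},{b}:{lb:.6f})"
        else:
            merged = f"({a},{b})"
        parts[j:j + 1] = []
        parts[i] = merged
    return pc.parse_tree(parts[0] + ";")


@pytest.fixture
def quartet_tree():
    return pc.parse_tree("((A,B),(C,D));")
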