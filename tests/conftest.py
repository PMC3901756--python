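"""Shared fixtures and independent oracles for the test suite."""

from itertools import product

import numpy as np
import pytest

import phyloinform as pf
from phyloinform.substmodel import jc_prob

#: single fixed seed for every stochastic check in the suite
SUITE_SEED = 7


@pytest.fixture(scope="session")
def bench_bundle():
    """The eight-fragment benchmark dataset (40 tips, 110 Ma, 6095 bp)."""
    return pf.aciliini_fixture(SUITE_SEED)


@pytest.fixture(scope="session")
def bench_rates(bench_bundle):
    """Per-site ML rates estimated on the benchmark dataset."""
    b = bench_bundle
    return pf.estimate_all_rates(b.matrix, b.tree, b.scheme)


@pytest.fixture
def three_tip_tree():
    return pf.parse_newick("((A:2,B:2):3,C:5);")


def brute_force_loglik(tree, col_codes, lam: float) -> float:
    """Independent pruning oracle: exhaustive sum over every ancestral
    state assignment (tractable for small trees only)."""
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    tips = tree.tip_ids
    total = 0.0
    for assign in product(range(4), repeat=len(internal)):
        state = dict(zip(internal, assign))
        p = 0.25  # uniform root prior
        for node in internal:
            if tree.parent[node] != -1:
                P = jc_prob(lam * tree.blen[node])
                p *= P[state[tree.parent[node]], state[node]]
        for row, tip in enumerate(tips):
            c = col_codes[row]
            if c == 4:  # missing: sums to 1 over states
                continue
            P = jc_prob(lam * tree.blen[tip])
            p *= P[state[tree.parent[tip]], c]
        total += p
    return float(np.log(total))
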