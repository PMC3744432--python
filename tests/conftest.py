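"""Shared fixtures and independent brute-force oracles.

The oracles enumerate ancestral states / HMM paths directly and never call
the dynamic programs they are used to check.
"""

from itertools import product

import numpy as np
import pytest

import phylobias as pb


@pytest.fixture(scope="session")
def tree():
    return pb.PhyloTree.default()


@pytest.fixture(scope="session")
def neutral(tree):
    return pb.default_neutral_model()


@pytest.fixture(scope="session")
def state_models(neutral):
    return pb.build_state_models(neutral, rho=0.31, B=3.0)


def brute_force_column_loglik(model, leaf_codes):
    """Sum over all internal-node assignments (no pruning)."""
    tree = model.tree
    internals = tree.postorder_internal
    total = 0.0
    for assign in product(range(4), repeat=len(internals)):
        state = dict(zip(internals, assign))
        p = model.pi[state[tree.root]]
        for node in range(tree.n_nodes - 1):
            par_state = state[tree.parent[node]]
            if node < tree.n_leaves:
                x = leaf_codes[node]
                p *= 1.0 if x >= 4 else model.P[node][par_state, x]
            else:
                p *= model.P[node][par_state, state[node]]
        total += p
    return np.log(total)


def brute_force_hmm(init, P, em):
    """Posteriors, log-likelihood and best path by full path enumeration."""
    L, S = em.shape
    post = np.zeros((L, S))
    total = 0.0
    best_p, best_path = -1.0, None
    for path in product(range(S), repeat=L):
        p = init[path[0]] * em[0, path[0]]
        for t in range(1, L):
            p *= P[path[t - 1], path[t]] * em[t, path[t]]
        total += p
        for t, s in enumerate(path):
            post[t, s] += p
        if p > best_p:
            best_p, best_path = p, path
    return post / total, np.log(total), np.array(best_path)


@pytest.fixture
def toy_hmm():
    """A length-5 toy block with exaggerated parameters for enumeration."""
    params = pb.HMMParams(mu=0.1, nu=0.2, alpha=0.15, beta=0.05)
    rng = np.random.default_rng(42)
    logem = np.log(rng.dirichlet(np.ones(4), size=5))
    return params, logem


def make_block(rows, target="human", **kw):
    """Build an AlignmentBlock from a dict of aligned strings."""
    return pb.AlignmentBlock.from_strings(rows, target=target, **kw)


SPECIES = ["human", "chimpanzee", "orangutan", "rhesus"]
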