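import itertools

import numpy as np
import pytest

import phylosample as ps


@pytest.fixture(scope="session")
def t4():
    return ps.fixture_tree()


@pytest.fixture(scope="session")
def ead4(t4):
    return ps.compute_ead(t4)


@pytest.fixture(scope="session")
def yule100():
    return ps.yule_tree(100, seed=3)


def enumerate_subset_pds(tree):
    """All 2^N subset PDs and subset sizes, computed from first principles:
    an edge counts iff its descendant tip set intersects the subset (via
    the descendant matrix), independent of the library's path-walking
    routine."""
    desc = tree.descendant_matrix()  # (nodes, tips) booleans
    n = tree.tips.size
    masks = np.array(list(itertools.product([False, True], repeat=n)))
    present = (masks.astype(float) @ desc.T.astype(float)) > 0.5
    pds = present @ tree.lengths
    return pds, masks.sum(axis=1)


def exhaustive_binomial_moments(tree, p, enum=None):
    """Independent oracle: mean and variance of rooted PD under binomial
    sampling by enumerating all 2^N tip subsets."""
    pds, sizes = enumerate_subset_pds(tree) if enum is None else enum
    n = tree.tips.size
    probs = p ** sizes * (1 - p) ** (n - sizes)
    mean = float(np.dot(probs, pds))
    var = float(np.dot(probs, (pds - mean) ** 2))
    return mean, var
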