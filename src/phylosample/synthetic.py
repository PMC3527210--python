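"""Synthetic metacommunity trees for tests, theory curves and simulation.

Three generators:

* :func:`fixture_tree` — a fixed four-tip tree used throughout the test
  suite and documentation; it contains an internal edge of length 2 with
  exactly two descendant tips, the pedagogical case for reading off the
  edge-length abundance distribution.
* :func:`yule_tree` — pure-birth (Yule) topology with i.i.d. exponential
  branch lengths; the neutral tree generator for property tests.
* :func:`powerlaw_tree` — a random-merge topology whose branch lengths are
  rescaled per abundance class so the tree's EAD is *exactly*
  ``scale * n**-alpha`` on every occupied class; realizes the power-law
  metacommunity as a concrete tree when per-edge quantities (e.g. the PD
  variance) are needed.
"""

from __future__ import annotations

import numpy as np

from .tree import RootedTree

__all__ = ["fixture_tree", "yule_tree", "powerlaw_tree", "FIXTURE_NEWICK"]

FIXTURE_NEWICK = "((A:1.0,B:2.0):2.0,(C:1.0,D:1.0):1.0);"


def fixture_tree() -> RootedTree:
    """The four-tip fixture tree ((A:1,B:2):2,(C:1,D:1):1).

    Total branch length 8; EAD {1: 5, 2: 3, 4: 0} (the root edge has
    length 0 and belongs to class N=4).
    """
    return RootedTree.from_newick(FIXTURE_NEWICK)


def yule_tree(n_tips: int, seed: int, length_scale: float = 1.0) -> RootedTree:
    """Pure-birth tree: split a uniformly chosen extant lineage until
    ``n_tips`` tips exist; every branch length is exponential with mean
    ``length_scale``.  Deterministic given ``seed``.
    """
    if n_tips < 2:
        raise ValueError("yule_tree requires n_tips >= 2")
    if length_scale <= 0:
        raise ValueError("length_scale must be > 0")
    rng = np.random.default_rng(seed)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    # node 0 is the root with children 1, 2
    parent[1] = parent[2] = 0
    leaves = [1, 2]
    nxt = 3
    while len(leaves) < n_tips:
        k = int(rng.integers(len(leaves)))
        nd = leaves.pop(k)
        parent[nxt] = nd
        parent[nxt + 1] = nd
        leaves.extend([nxt, nxt + 1])
        nxt += 2
    lengths = rng.exponential(length_scale, size=n_nodes)
    lengths[0] = 0.0
    labels = {nd: f"t{i + 1}" for i, nd in enumerate(sorted(leaves))}
    return RootedTree(parent, lengths, labels)


def powerlaw_tree(n_tips: int, exponent: float, seed: int,
                  scale: float = 1.0) -> RootedTree:
    """Random topology with an exactly power-law EAD.

    Topology comes from uniformly random pairwise merges (a coalescent-style
    merge order); then every edge in abundance class n gets length
    ``scale * n**-exponent / (number of class-n edges)``, so
    L(n) = scale * n**-exponent exactly on occupied classes.  Classes with
    no edge are simply absent from the EAD.
    """
    if n_tips < 4:
        raise ValueError("powerlaw_tree requires n_tips >= 4")
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rng = np.random.default_rng(seed)
    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    active = list(range(n_tips))
    nxt = n_tips
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent[a] = parent[b] = nxt
        for x in sorted((int(i), int(j)), reverse=True):
            active.pop(x)
        active.append(nxt)
        nxt += 1
    root = active[0]
    # reindex so the arrays are parent-consistent (root already last)
    labels = {i: f"t{i + 1}" for i in range(n_tips)}
    tmp = RootedTree(parent, np.zeros(n_nodes), labels)
    counts: dict[int, int] = {}
    for i in range(n_nodes):
        n = int(tmp.n_desc[i])
        counts[n] = counts.get(n, 0) + 1
    lengths = np.array([
        scale * float(tmp.n_desc[i]) ** (-exponent) / counts[int(tmp.n_desc[i])]
        for i in range(n_nodes)
    ])
    assert root == n_nodes - 1
    return RootedTree(parent, lengths, labels)
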