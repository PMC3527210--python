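"""Rooted phylogenetic trees with branch lengths and descendant-tip counts.

The metacommunity is represented as a rooted tree whose tips are individual
sampled organisms (e.g. one 16S read each).  Every node carries the length of
the edge *above* it (the root's edge defaults to length 0), and ``n_desc``,
the number of tips at or below it — the quantity that indexes the edge-length
abundance distribution.

Phylogenetic diversity here uses the *rooted* convention: the PD of a tip set
is the total length of every edge having at least one member of the set among
its descendants, i.e. the induced subtree is connected all the way to the
root.  This is the convention under which the closed-form sampling
expectations hold edge by edge; software using the MRCA-spanning (unrooted)
convention will report smaller PD for nested samples.
"""

from __future__ import annotations

import io as _io
import warnings
from collections.abc import Iterable, Mapping

import dendropy
import numpy as np

from .errors import NewickParseError, TreeValidationError, UnknownTipError

__all__ = ["RootedTree", "parse_newick", "write_newick", "total_branch_length", "induced_pd"]


class RootedTree:
    """A validated rooted tree stored as flat parent/length arrays.

    Parameters
    ----------
    parent : sequence of int
        ``parent[i]`` is the parent index of node ``i``; exactly one node
        (the root) has parent ``-1``.
    lengths : sequence of float
        Length of the edge above each node; all non-negative.
    tip_labels : mapping int -> str
        Unique non-empty labels for tip nodes (nodes without children).
    tip_weights : mapping str -> int, optional
        Integer multiplicity per tip label; a weight of ``w`` makes the tip
        count as ``w`` identical individuals in ``n_desc``.  Default 1.
    """

    def __init__(self, parent, lengths, tip_labels: Mapping[int, str],
                 tip_weights: Mapping[str, int] | None = None):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=np.float64)
        self.tip_labels = dict(tip_labels)
        self._validate_shape()

        n = self.parent.size
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise TreeValidationError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]

        self.tips = np.array([i for i in range(n) if not self.children[i]], dtype=np.int64)
        self._validate_labels()
        self.label_to_node = {lab: i for i, lab in self.tip_labels.items()}

        self._traverse()  # sets postorder, preorder, tin, tout; checks connectivity
        self._count_descendants(tip_weights)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, text: str, tip_weights: Mapping[str, int] | None = None) -> "RootedTree":
        """Parse a newick string into a validated :class:`RootedTree`."""
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick",
                suppress_internal_node_taxa=True,
                preserve_underscores=True,
            )
        except Exception as exc:  # dendropy raises several error classes
            msg = str(exc)
            if "Duplicate taxon labels" in msg:
                raise TreeValidationError(f"duplicate tip label(s): {msg}") from exc
            pos = ""
            line = getattr(exc, "line_num", None)
            col = getattr(exc, "col_num", None)
            if line is not None:
                pos = f" (line {line}, column {col})"
            raise NewickParseError(f"malformed newick{pos}: {exc}") from exc

        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        labels: dict[int, str] = {}
        missing = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
            if nd.edge.length is None:
                if nd.parent_node is not None:
                    missing += 1
            else:
                lengths[i] = float(nd.edge.length)
            if nd.is_leaf():
                labels[i] = "" if nd.taxon is None else str(nd.taxon.label)
        if missing:
            warnings.warn(
                f"{missing} edge(s) had no branch length in the newick input; "
                "defaulting to 0", stacklevel=2)
        return cls(parent, lengths, labels, tip_weights=tip_weights)

    # -- validation --------------------------------------------------------

    def _validate_shape(self) -> None:
        if self.parent.size != self.lengths.size:
            raise TreeValidationError("parent and lengths must have equal size")
        if self.parent.size == 0:
            raise TreeValidationError("empty tree")
        if np.any(self.lengths < 0):
            bad = np.flatnonzero(self.lengths < 0)
            raise TreeValidationError(f"negative branch length at node(s) {bad.tolist()}")

    def _validate_labels(self) -> None:
        if set(self.tip_labels) != set(self.tips.tolist()):
            raise TreeValidationError("tip_labels must label exactly the leaf nodes")
        labels = list(self.tip_labels.values())
        if any(not lab for lab in labels):
            raise TreeValidationError("empty tip label")
        if len(set(labels)) != len(labels):
            seen, dups = set(), set()
            for lab in labels:
                (dups if lab in seen else seen).add(lab)
            raise TreeValidationError(f"duplicate tip label(s): {sorted(dups)}")

    def _traverse(self) -> None:
        n = self.parent.size
        order = np.empty(n, dtype=np.int64)
        tin = np.empty(n, dtype=np.int64)
        tout = np.empty(n, dtype=np.int64)
        clock = 0
        k = n
        stack = [self.root]
        seen = 0
        while stack:
            nd = stack.pop()
            tin[nd] = clock
            clock += 1
            k -= 1
            order[k] = nd
            seen += 1
            stack.extend(self.children[nd])
        if seen != n:
            raise TreeValidationError("tree is not connected (unreachable nodes)")
        # reversed preorder: every node appears before its ancestors
        self.preorder = order[::-1].copy()
        self.postorder = order.copy()
        # exit times for ancestor tests
        for nd in self.postorder:
            if self.children[nd]:
                tout[nd] = max(tout[c] for c in self.children[nd])
            else:
                tout[nd] = tin[nd]
        self.tin, self.tout = tin, tout

    def _count_descendants(self, tip_weights: Mapping[str, int] | None) -> None:
        n = self.parent.size
        nd = np.zeros(n, dtype=np.int64)
        for i in self.tips:
            w = 1
            if tip_weights is not None:
                w = int(tip_weights.get(self.tip_labels[int(i)], 1))
                if w < 1:
                    raise TreeValidationError("tip weights must be positive integers")
            nd[i] = w
        for i in self.postorder:
            for c in self.children[i]:
                nd[i] += nd[c]
        self.n_desc = nd

    # -- basic queries -----------------------------------------------------

    @property
    def n_tips(self) -> int:
        """Total tip count N (weighted if tip weights were supplied)."""
        return int(self.n_desc[self.root])

    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    def total_branch_length(self) -> float:
        """Sum of all edge lengths, including the root edge."""
        return float(self.lengths.sum())

    def tip_nodes(self, labels: Iterable[str]) -> np.ndarray:
        """Map tip labels to node indices, raising on unknown labels."""
        labels = list(labels)
        unknown = [lab for lab in labels if lab not in self.label_to_node]
        if unknown:
            raise UnknownTipError(unknown)
        return np.array([self.label_to_node[lab] for lab in labels], dtype=np.int64)

    def edge_presence(self, labels: Iterable[str]) -> np.ndarray:
        """Boolean per node: does the edge above it lie on a path from any
        of the given tips to the root?"""
        present = np.zeros(self.n_nodes, dtype=bool)
        for i in self.tip_nodes(labels):
            j = int(i)
            while j >= 0 and not present[j]:
                present[j] = True
                j = int(self.parent[j])
        return present

    def induced_pd(self, labels: Iterable[str]) -> float:
        """Rooted phylogenetic diversity of a tip set.

        Sum of the lengths of every edge with at least one of the given tips
        among its descendants; the empty set has PD 0.
        """
        labels = list(labels)
        if not labels:
            return 0.0
        return float(self.lengths[self.edge_presence(labels)].sum())

    def descendant_matrix(self) -> np.ndarray:
        """Boolean (n_nodes, n_tips) matrix: node i has tip j below it.

        Column order follows ``self.tips``.
        """
        n = self.n_nodes
        tip_col = {int(t): j for j, t in enumerate(self.tips)}
        mat = np.zeros((n, len(self.tips)), dtype=bool)
        for i in self.postorder:
            if not self.children[i]:
                mat[i, tip_col[int(i)]] = True
            else:
                for c in self.children[i]:
                    mat[i] |= mat[c]
        return mat

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        """Serialize to a newick string (branch lengths as decimals)."""
        out = _io.StringIO()

        def fmt(x: float) -> str:
            return repr(float(x))

        # iterative writer to cope with deep trees
        stack: list[tuple[int, int]] = [(self.root, 0)]
        while stack:
            nd, state = stack.pop()
            if state == 2:  # comma between siblings
                out.write(",")
                continue
            kids = self.children[nd]
            if not kids:
                out.write(self.tip_labels[nd])
                out.write(f":{fmt(self.lengths[nd])}")
                continue
            if state == 0:
                out.write("(")
                stack.append((nd, 1))
                for j, c in enumerate(reversed(kids)):
                    stack.append((c, 0))
                    if j != len(kids) - 1:
                        stack.append((-1, 2))  # comma marker
            elif state == 1:
                out.write(")")
                if nd != self.root or self.lengths[nd] != 0.0:
                    out.write(f":{fmt(self.lengths[nd])}")
        out.write(";")
        return out.getvalue()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"<RootedTree N={self.n_tips} nodes={self.n_nodes} "
                f"length={self.total_branch_length():.6g}>")


def parse_newick(text: str, tip_weights: Mapping[str, int] | None = None) -> RootedTree:
    """Parse a newick string; see :meth:`RootedTree.from_newick`."""
    return RootedTree.from_newick(text, tip_weights=tip_weights)


def write_newick(tree: RootedTree) -> str:
    return tree.to_newick()


def total_branch_length(tree: RootedTree) -> float:
    return tree.total_branch_length()


def induced_pd(tree: RootedTree, tips: Iterable[str]) -> float:
    return tree.induced_pd(tips)
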