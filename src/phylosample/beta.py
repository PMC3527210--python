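"""Expected and observed phylogenetic beta diversity (UniFrac).

For two independent samples A and B from the same metacommunity, an edge
with n descendant tips is present in both with probability P_A(n)*P_B(n)
and in at least one with probability 1 - (1-P_A(n))(1-P_B(n)), so the
expected shared and union branch lengths are EAD-weighted sums of those
probabilities.  The expected (unweighted) UniFrac distance is taken as the
ratio of expectations, 1 - E[shared]/E[union] — the quantity plotted when
expected shared and total branch length are computed analytically.  The
Monte-Carlo module also reports the mean of per-replicate UniFrac so the
bias of the ratio-of-expectations convention is measurable.

Because expected UniFrac between two *random* samples depends on their
sizes — and grows as the sizes become more unequal — observed UniFrac
distances between differently-sized communities can be normalized by the
expected value for random samples of the same two sizes
(:func:`normalize_unifrac`); values below 1 mean the communities are more
similar than random same-sized samples.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections.abc import Iterable

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .ead import EAD
from .errors import PhylosampleError, UndefinedDistanceError
from .sampling import SamplingScheme, presence_probability
from .tree import RootedTree

__all__ = [
    "BetaPrediction", "expected_shared", "expected_union", "expected_unifrac",
    "observed_unifrac", "normalize_unifrac", "predict_beta",
    "Dendrogram", "cluster_distances",
]


@dataclass(frozen=True)
class BetaPrediction:
    """Expected shared/union branch length and UniFrac for a scheme pair."""

    expected_shared: float
    expected_union: float
    expected_unifrac: float


def expected_shared(ead: EAD, scheme_a: SamplingScheme,
                    scheme_b: SamplingScheme) -> float:
    """E[shared branch length] = sum_n L(n) * P_A(n) * P_B(n)."""
    ns = ead.classes
    pa = np.asarray(presence_probability(scheme_a, ns))
    pb = np.asarray(presence_probability(scheme_b, ns))
    return float(np.dot(ead.lengths, pa * pb))


def expected_union(ead: EAD, scheme_a: SamplingScheme,
                   scheme_b: SamplingScheme) -> float:
    """E[union branch length] = sum_n L(n) * (1 - (1-P_A(n))(1-P_B(n)))."""
    ns = ead.classes
    pa = np.asarray(presence_probability(scheme_a, ns))
    pb = np.asarray(presence_probability(scheme_b, ns))
    return float(np.dot(ead.lengths, 1.0 - (1.0 - pa) * (1.0 - pb)))


def expected_unifrac(ead: EAD, scheme_a: SamplingScheme,
                     scheme_b: SamplingScheme) -> float:
    """Expected UniFrac as a ratio of expectations:
    1 - E[shared]/E[union]."""
    union = expected_union(ead, scheme_a, scheme_b)
    if union <= 0.0:
        raise UndefinedDistanceError(
            "expected union branch length is 0; UniFrac undefined")
    return 1.0 - expected_shared(ead, scheme_a, scheme_b) / union


def predict_beta(ead: EAD, scheme_a: SamplingScheme,
                 scheme_b: SamplingScheme) -> BetaPrediction:
    shared = expected_shared(ead, scheme_a, scheme_b)
    union = expected_union(ead, scheme_a, scheme_b)
    if union <= 0.0:
        raise UndefinedDistanceError(
            "expected union branch length is 0; UniFrac undefined")
    return BetaPrediction(shared, union, 1.0 - shared / union)


def observed_unifrac(tree: RootedTree, tips_a: Iterable[str],
                     tips_b: Iterable[str]) -> float:
    """Unweighted UniFrac between two explicit tip sets.

    An edge belongs to a sample when at least one of the sample's tips is
    among its descendants (rooted convention); UniFrac is the fraction of
    the union branch length not shared by both samples.
    """
    tips_a, tips_b = list(tips_a), list(tips_b)
    if not tips_a or not tips_b:
        raise PhylosampleError("both tip sets must be non-empty")
    in_a = tree.edge_presence(tips_a)
    in_b = tree.edge_presence(tips_b)
    union = float(tree.lengths[in_a | in_b].sum())
    if union <= 0.0:
        raise UndefinedDistanceError("union branch length is 0; UniFrac undefined")
    shared = float(tree.lengths[in_a & in_b].sum())
    return (union - shared) / union


def normalize_unifrac(observed: float, expected: float) -> float:
    """Observed UniFrac divided by the expectation for random samples of the
    same sizes; < 1 means more similar than random."""
    if expected <= 0.0:
        raise UndefinedDistanceError("expected UniFrac is 0; normalization undefined")
    return observed / expected


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage dendrogram over labeled distances."""

    labels: list[str]
    linkage: np.ndarray  # scipy linkage matrix in self.labels order

    def to_newick(self) -> str:
        """Newick with ultrametric branch lengths derived from merge heights."""
        n = len(self.labels)
        text = {i: self.labels[i] for i in range(n)}
        height = {i: 0.0 for i in range(n)}
        for k, (i, j, h, _) in enumerate(self.linkage):
            i, j = int(i), int(j)
            li = h - height[i]
            lj = h - height[j]
            node = n + k
            text[node] = f"({text[i]}:{li:g},{text[j]}:{lj:g})"
            height[node] = float(h)
        return text[n + len(self.linkage) - 1] + ";"


def cluster_distances(matrix, labels: list[str] | None = None) -> Dendrogram:
    """Average-linkage agglomerative clustering of a symmetric distance
    matrix.

    Accepts a pandas DataFrame (labels from its index) or an array plus a
    label list.  Labels are sorted lexicographically before clustering so
    tie-breaking is deterministic: among equidistant merges, the
    lexicographically smallest pair merges first.
    """
    import pandas as pd

    if isinstance(matrix, pd.DataFrame):
        labels = list(matrix.index)
        mat = matrix.to_numpy(dtype=float)
    else:
        mat = np.asarray(matrix, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(mat.shape[0])]
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise PhylosampleError("distance matrix must be square")
    if np.any(~np.isfinite(mat)):
        raise PhylosampleError("distance matrix contains NaN/inf")
    if not np.allclose(mat, mat.T, atol=1e-12):
        raise PhylosampleError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(mat)) > 1e-12):
        raise PhylosampleError("distance matrix diagonal must be zero")

    order = np.argsort(np.asarray(labels, dtype=object))
    sorted_labels = [labels[i] for i in order]
    mat = mat[np.ix_(order, order)]
    if len(sorted_labels) < 2:
        raise PhylosampleError("need at least two labels to cluster")
    condensed = squareform(mat, checks=False)
    link = hierarchy.linkage(condensed, method="average")
    return Dendrogram(labels=sorted_labels, linkage=link)
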