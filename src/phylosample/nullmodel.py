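"""Null-model classification of local communities and theory curves.

An observed local community (a tip set from the metacommunity tree) is
compared against the random-sampling null: the scheme's intensity is fitted
so the expected number of distinct tips matches the observed tip count
(moment matching — the only quantity both observable and analytic in every
family), then the observed PD is placed against the closed-form expectation
and its confidence band.  PD below the band is phylogenetically *clustered*
(the classic signature of environmental filtering), above it *overdispersed*
(associated with competitive exclusion), inside it consistent with random
assembly.

Two surfaces are provided: the plain function :func:`classify_sample` /
:func:`pd_curve`, and the model-object pair :class:`PDNullModel` /
:class:`PDNullModelResults` (``fit()`` then ``summary()``) for batch
analysis of a sample-membership table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections.abc import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .ead import EAD, compute_ead
from .errors import SchemeDomainError
from .sampling import expected_pd, expected_tips, solve_intensity, variance_pd
from .tree import RootedTree

__all__ = ["NullModelResult", "classify_sample", "pd_curve", "theory_curve",
           "PDNullModel", "PDNullModelResults"]

RESULT_COLUMNS = ["sample_id", "observed_tips", "observed_pd", "fitted_intensity",
                  "expected_pd", "sd_pd", "z_score", "ci_low", "ci_high", "label"]


@dataclass(frozen=True)
class NullModelResult:
    """Observed vs expected PD for one local community, with a label."""

    sample_id: str
    observed_tips: int
    observed_pd: float
    fitted_intensity: float
    expected_pd: float
    sd_pd: float
    z_score: float
    ci_low: float
    ci_high: float
    label: str  # clustered | random | overdispersed


def _critical_value(alpha_level: float, ci_method: str) -> float:
    if not (0.0 < alpha_level < 1.0):
        raise ValueError(f"alpha_level must be in (0, 1), got {alpha_level}")
    if ci_method == "normal":
        return float(stats.norm.ppf(1.0 - alpha_level / 2.0))
    if ci_method == "chebyshev":
        # two-sided Chebyshev bound: P(|Z| > k) <= 1/k^2 = alpha
        return float(1.0 / np.sqrt(alpha_level))
    raise ValueError(f"unknown ci_method {ci_method!r}")


def classify_sample(tree: RootedTree, tips: Iterable[str], family: str = "binomial",
                    eps: float | None = None, alpha_level: float = 0.05,
                    ci_method: str = "normal", sample_id: str = "",
                    ead: EAD | None = None) -> NullModelResult:
    """Classify one local community against the random-sampling null.

    The intensity is solved so the null's expected distinct-tip count equals
    the observed tip count; the confidence band is expectation +/- critical
    value * sd (normal approximation by default; ``ci_method='chebyshev'``
    gives a distribution-free conservative band).  ``ead`` may be passed to
    avoid recomputing it for many samples on the same metacommunity.
    """
    tips = set(tips)
    observed_tips = len(tips)
    observed_pd = tree.induced_pd(tips)
    if ead is None:
        ead = compute_ead(tree)
    scheme = solve_intensity(family, tree.n_tips, observed_tips, eps=eps)
    exp_pd = expected_pd(ead, scheme)
    sd = float(np.sqrt(variance_pd(tree, scheme)))
    crit = _critical_value(alpha_level, ci_method)
    if sd > 0:
        z = (observed_pd - exp_pd) / sd
    elif observed_pd == exp_pd:
        z = 0.0
    else:
        warnings.warn(
            f"sample {sample_id!r}: null sd is 0 but observed != expected; "
            "labeling by sign of the deviation", stacklevel=2)
        z = np.inf if observed_pd > exp_pd else -np.inf
    ci_low = exp_pd - crit * sd
    ci_high = exp_pd + crit * sd
    if observed_pd < ci_low:
        label = "clustered"
    elif observed_pd > ci_high:
        label = "overdispersed"
    else:
        label = "random"
    return NullModelResult(
        sample_id=sample_id, observed_tips=observed_tips,
        observed_pd=observed_pd, fitted_intensity=scheme.p,
        expected_pd=exp_pd, sd_pd=sd, z_score=float(z),
        ci_low=ci_low, ci_high=ci_high, label=label)


def pd_curve(tree: RootedTree, family: str = "binomial", eps: float | None = None,
             grid: Iterable[float] = (), alpha_level: float = 0.05,
             ci_method: str = "normal", ead: EAD | None = None) -> pd.DataFrame:
    """Expected PD and its confidence band along a grid of target tip counts.

    One row per grid value: the intensity matching that expected tip count,
    the closed-form expected PD, and the band expectation +/- critical
    value * sd.  Grid values must lie in (0, N].  The variance needs the
    full tree (per-edge lengths), which is why this takes a tree rather
    than a bare EAD; for pure-EAD theory curves without a band use
    :func:`theory_curve`.
    """
    if ead is None:
        ead = compute_ead(tree)
    crit = _critical_value(alpha_level, ci_method)
    rows = []
    for target in grid:
        if not (0.0 < target <= tree.n_tips):
            raise SchemeDomainError(
                f"grid value {target} outside (0, N={tree.n_tips}]")
        scheme = solve_intensity(family, tree.n_tips, target, eps=eps)
        e = expected_pd(ead, scheme)
        sd = float(np.sqrt(variance_pd(tree, scheme)))
        rows.append((expected_tips(scheme, tree.n_tips), e,
                     e - crit * sd, e + crit * sd))
    return pd.DataFrame(rows, columns=["expected_tips", "expected_pd",
                                       "ci_low", "ci_high"])


def theory_curve(ead: EAD, family: str = "binomial", eps: float | None = None,
                 grid: Iterable[float] = ()) -> pd.DataFrame:
    """Expected PD vs expected tips for a bare EAD (no confidence band)."""
    rows = []
    n = ead.n_tips
    for target in grid:
        if not (0.0 < target <= n):
            raise SchemeDomainError(f"grid value {target} outside (0, N={n}]")
        scheme = solve_intensity(family, n, target, eps=eps)
        rows.append((expected_tips(scheme, n), expected_pd(ead, scheme)))
    return pd.DataFrame(rows, columns=["expected_tips", "expected_pd"])


class PDNullModel:
    """Null-model analysis of many local communities on one metacommunity.

    Parameters
    ----------
    tree : RootedTree
        The metacommunity tree (the regional pool).
    communities : mapping sample_id -> iterable of tip labels
        The observed local communities.
    family, eps : scheme family and clustering parameter of the null.
    """

    def __init__(self, tree: RootedTree, communities: Mapping[str, Iterable[str]],
                 family: str = "binomial", eps: float | None = None):
        self.tree = tree
        self.communities = {k: set(v) for k, v in communities.items()}
        self.family = family
        self.eps = eps
        self.ead = compute_ead(tree)

    @classmethod
    def from_membership(cls, tree: RootedTree, table: pd.DataFrame,
                        family: str = "binomial", eps: float | None = None
                        ) -> "PDNullModel":
        """Build from a long-format membership table with columns
        ``sample`` and ``tip``."""
        groups = {str(s): set(g["tip"]) for s, g in table.groupby("sample")}
        return cls(tree, groups, family=family, eps=eps)

    def fit(self, alpha_level: float = 0.05,
            ci_method: str = "normal") -> "PDNullModelResults":
        results = [
            classify_sample(self.tree, tips, family=self.family, eps=self.eps,
                            alpha_level=alpha_level, ci_method=ci_method,
                            sample_id=sid, ead=self.ead)
            for sid, tips in sorted(self.communities.items())
        ]
        return PDNullModelResults(self, results, alpha_level, ci_method)


class PDNullModelResults:
    """Fitted null-model classifications with a summary table."""

    def __init__(self, model: PDNullModel, results: list[NullModelResult],
                 alpha_level: float, ci_method: str):
        self.model = model
        self.results = results
        self.alpha_level = alpha_level
        self.ci_method = ci_method

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results],
                            columns=RESULT_COLUMNS)

    def label_counts(self) -> dict[str, int]:
        counts = {"clustered": 0, "random": 0, "overdispersed": 0}
        for r in self.results:
            counts[r.label] += 1
        return counts

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def summary(self) -> str:
        tree = self.model.tree
        counts = self.label_counts()
        head = [
            "Phylogenetic diversity null-model classification",
            "=" * 49,
            f"Metacommunity: N={tree.n_tips} tips, "
            f"total branch length {tree.total_branch_length():.6g}",
            f"Null: {self.model.family}"
            + (f" (eps={self.model.eps})" if self.model.eps is not None else "")
            + f", alpha={self.alpha_level}, CI={self.ci_method}",
            f"Samples: {len(self.results)} "
            f"(clustered {counts['clustered']}, random {counts['random']}, "
            f"overdispersed {counts['overdispersed']})",
            "",
        ]
        body = self.frame.to_string(
            index=False,
            float_format=lambda x: f"{x:.4g}",
        )
        return "\n".join(head) + body

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<PDNullModelResults: {self.label_counts()}>"
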