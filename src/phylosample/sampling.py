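"""Sampling schemes and closed-form expected phylogenetic diversity.

A local community is modeled as a random sample of individuals from the
metacommunity.  Three phenomenological schemes are supported, each defined
by the probability P(n) that a clade with n tips contributes at least one
sampled individual:

* ``binomial`` — every individual sampled independently with probability p
  (sampling without replacement): ``P(n) = 1 - (1-p)**n``.
* ``poisson`` — each individual's sampled count is Poisson with mean p
  (sampling with replacement): ``P(n) = 1 - exp(-p*n)``.
* ``negbinom`` — clustered/overdispersed sampling with departure parameter
  eps: ``P(n) = 1 - (1 + eps*p*n)**(-1/eps)``.  eps > 0 means clustered
  (nearby tips co-occur more than chance), eps < 0 overdispersed, and
  eps -> 0 recovers the Poisson scheme.  Generatively (for eps > 0) a
  single gamma factor g with mean 1 and variance eps multiplies every
  tip's Poisson intensity within one sample.

The central identity: expected rooted PD of the sample is

    E[PD] = sum_n L(n) * P(n)

where L(n) is the metacommunity's edge-length abundance distribution —
no randomization null is needed.  The variance of sampled PD is likewise
closed-form (see :func:`variance_pd`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ead import EAD
from .errors import SchemeDomainError
from .tree import RootedTree

__all__ = [
    "SamplingScheme", "PDPrediction",
    "presence_probability", "expected_pd", "expected_tips",
    "solve_intensity", "variance_pd", "predict",
]

FAMILIES = ("binomial", "poisson", "negbinom")


@dataclass(frozen=True)
class SamplingScheme:
    """A sampling-scheme family with its intensity and clustering parameter.

    ``p`` is the per-individual sampling probability (binomial) or the mean
    per-individual sampled count (poisson/negbinom).  ``eps`` is the
    dimensionless departure-from-random parameter, used only by negbinom.
    """

    family: str
    p: float
    eps: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise SchemeDomainError(
                f"unknown family {self.family!r}; expected one of {FAMILIES}")
        if self.family == "binomial":
            if not (0.0 <= self.p <= 1.0):
                raise SchemeDomainError(f"binomial requires 0 <= p <= 1, got {self.p}")
        else:
            if self.p < 0:
                raise SchemeDomainError(f"{self.family} requires p >= 0, got {self.p}")
        if self.family == "negbinom":
            if self.eps is None:
                raise SchemeDomainError("negbinom requires an eps parameter")
        elif self.eps is not None:
            raise SchemeDomainError(f"{self.family} does not take eps")

    @classmethod
    def from_string(cls, spec: str) -> "SamplingScheme":
        """Parse e.g. ``'binomial:p=0.5'`` or ``'negbinom:p=0.1,eps=0.5'``."""
        try:
            family, _, rest = spec.partition(":")
            kwargs = {}
            if rest:
                for item in rest.split(","):
                    key, _, val = item.partition("=")
                    kwargs[key.strip()] = float(val)
        except ValueError as exc:
            raise SchemeDomainError(f"cannot parse scheme spec {spec!r}") from exc
        if "p" not in kwargs:
            raise SchemeDomainError(f"scheme spec {spec!r} missing p=")
        p = kwargs.pop("p")
        eps = kwargs.pop("eps", None)
        if kwargs:
            raise SchemeDomainError(
                f"unknown key(s) {sorted(kwargs)} in scheme spec {spec!r}")
        return cls(family=family.strip(), p=p, eps=eps)

    def __str__(self) -> str:
        s = f"{self.family}:p={self.p!r}"
        if self.eps is not None:
            s += f",eps={self.eps!r}"
        return s


@dataclass(frozen=True)
class PDPrediction:
    """Closed-form moments of sampled PD for one scheme on one tree."""

    expected_pd: float
    variance_pd: float
    expected_tips: float


def presence_probability(scheme: SamplingScheme, n) -> float | np.ndarray:
    """P(n): probability that a clade with n metacommunity tips has at least
    one representative in the sample.

    Accepts a scalar or array of abundance classes; evaluated via
    log1p/expm1 so tiny probabilities and the eps -> 0 limit are exact to
    machine precision.
    """
    n_arr = np.asarray(n, dtype=np.float64)
    if np.any(n_arr < 1):
        raise SchemeDomainError("abundance class n must be >= 1")
    p = scheme.p
    if scheme.family == "binomial":
        if p == 1.0:
            out = np.ones_like(n_arr)
        else:
            out = -np.expm1(n_arr * np.log1p(-p))
    elif scheme.family == "poisson":
        out = -np.expm1(-p * n_arr)
    else:
        eps = scheme.eps
        if abs(eps) < 1e-150:  # below this eps*p*n underflows; Poisson limit
            out = -np.expm1(-p * n_arr)
        else:
            arg = eps * p * n_arr
            if np.any(1.0 + arg <= 0.0):
                bad = np.atleast_1d(n_arr)[np.atleast_1d(1.0 + arg) <= 0.0]
                raise SchemeDomainError(
                    "negbinom presence probability undefined: 1 + eps*p*n <= 0 "
                    f"for n = {np.unique(bad).astype(int).tolist()}")
            out = -np.expm1(-np.log1p(arg) / eps)
    return out if np.ndim(n) else float(out)


def _absence(scheme: SamplingScheme, n_arr: np.ndarray) -> np.ndarray:
    """Q(n) = 1 - P(n), evaluated in log space (no cancellation)."""
    p = scheme.p
    if scheme.family == "binomial":
        if p == 1.0:
            return np.zeros_like(n_arr, dtype=float)
        return np.exp(n_arr * np.log1p(-p))
    if scheme.family == "poisson" or abs(scheme.eps) < 1e-150:
        return np.exp(-p * n_arr)
    return np.exp(-np.log1p(scheme.eps * p * n_arr) / scheme.eps)


def expected_pd(ead: EAD, scheme: SamplingScheme) -> float:
    """Expected rooted PD of a sample: sum over abundance classes of
    L(n) * P(n)."""
    probs = presence_probability(scheme, ead.classes)
    return float(np.dot(ead.lengths, probs))


def expected_tips(scheme: SamplingScheme, n_tips: int) -> float:
    """Expected number of distinct tips in the sample.

    Each of the N pendant edges is present exactly when its own tip is
    sampled, so E[tips] = N * P(1).
    """
    if n_tips < 1:
        raise SchemeDomainError("n_tips must be >= 1")
    return n_tips * presence_probability(scheme, 1)


def solve_intensity(family: str, n_tips: int, target_tips: float,
                    eps: float | None = None) -> SamplingScheme:
    """Invert E[tips] = N * P(1) for the intensity p.

    P(1) is strictly monotone in p in every family, and each inverse has a
    closed form; the returned scheme reproduces ``target_tips`` to machine
    precision.  ``target_tips = N`` is attainable only under binomial
    sampling (p = 1); poisson/negbinom approach N asymptotically.
    """
    if not (0.0 <= target_tips <= n_tips):
        raise SchemeDomainError(
            f"target tip count {target_tips} outside [0, N={n_tips}]")
    frac = target_tips / n_tips
    if family == "binomial":
        return SamplingScheme("binomial", frac)
    if frac >= 1.0:
        raise SchemeDomainError(
            f"{family} sampling cannot reach E[tips] = N exactly")
    if family == "poisson":
        return SamplingScheme("poisson", -np.log1p(-frac))
    if family == "negbinom":
        if eps is None:
            raise SchemeDomainError("negbinom requires eps")
        if abs(eps) < 1e-150:  # Poisson limit (and avoids subnormal division)
            return SamplingScheme("negbinom", -np.log1p(-frac), eps)
        # (1 + eps*p)^(-1/eps) = 1 - frac  =>  p = ((1-frac)^(-eps) - 1)/eps
        p = np.expm1(-eps * np.log1p(-frac)) / eps
        if not np.isfinite(p) or p < 0:
            raise SchemeDomainError(
                f"target tip count {target_tips} unattainable for eps={eps}")
        return SamplingScheme("negbinom", float(p), eps)
    raise SchemeDomainError(f"unknown family {family!r}")


def variance_pd(tree: RootedTree, scheme: SamplingScheme) -> float:
    """Closed-form variance of sampled rooted PD.

    Writing I_e for the indicator that edge e appears in the sample and
    l_e for its length, PD = sum_e l_e I_e and

        Var(PD) = sum_e l_e^2 P_e (1 - P_e)
                + 2 sum_{a anc of d} l_a l_d P_d (1 - P_a)
                + 2 sum_{a, b disjoint} l_a l_b [Q(n_a + n_b) - Q(n_a) Q(n_b)]

    with Q(n) = 1 - P(n).  The ancestor term uses the fact that a
    descendant edge's presence implies its ancestor's; it is computed in
    O(edges) by a post-order accumulation.  The disjoint-pair term is the
    covariance induced by the shared gamma factor of negbinom sampling; it
    vanishes identically for binomial and poisson (Q is multiplicative in
    n) and is evaluated pairwise (O(edges^2)) only for negbinom.
    """
    lens = tree.lengths
    nd = tree.n_desc.astype(np.float64)
    P = np.asarray(presence_probability(scheme, nd))
    Q = _absence(scheme, nd)

    # P*(1-P) written as P*Q: Q comes straight from log space, no cancellation
    var = float(np.dot(lens * lens, P * Q))

    # ancestor-descendant covariances via subtree accumulation
    lp = lens * P
    sub = lp.copy()
    for i in tree.postorder:
        for c in tree.children[i]:
            sub[i] += sub[c]
    nested = float(np.dot(lens * Q, sub - lp))
    var += 2.0 * nested

    if scheme.family == "negbinom" and scheme.eps != 0.0:
        var += _disjoint_covariance(tree, scheme, lens, nd, Q)
    return max(var, 0.0)


def _disjoint_covariance(tree, scheme, lens, nd, Q) -> float:
    """2 * sum over unordered disjoint edge pairs of l_a l_b Cov(I_a, I_b)
    under the shared-gamma negbinom scheme."""
    live = np.flatnonzero(lens > 0)
    if live.size < 2:
        return 0.0
    tin = tree.tin[live]
    tout = tree.tout[live]
    anc = (tin[:, None] <= tin[None, :]) & (tout[None, :] <= tout[:, None])
    related = anc | anc.T  # includes the diagonal
    n_live = nd[live]
    q_pair = _absence(scheme, n_live[:, None] + n_live[None, :])
    cov = q_pair - Q[live][:, None] * Q[live][None, :]
    cov[related] = 0.0
    ll = lens[live]
    return float(ll @ cov @ ll)


def predict(tree: RootedTree, scheme: SamplingScheme,
            ead: EAD | None = None) -> PDPrediction:
    """Expected PD, its variance, and expected distinct tips for a scheme."""
    from .ead import compute_ead
    if ead is None:
        ead = compute_ead(tree)
    return PDPrediction(
        expected_pd=expected_pd(ead, scheme),
        variance_pd=variance_pd(tree, scheme),
        expected_tips=expected_tips(scheme, tree.n_tips),
    )
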