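"""Randomization oracle: brute-force sampling of tips from the tree.

This is the computational null that the closed-form expectations replace;
it is retained as a validation oracle and as a fallback for quantities
without closed forms.  Replicates are drawn in fixed-size chunks of 1024,
each chunk on its own counter-offset Philox stream, so results are
bit-reproducible for a given seed regardless of how many chunks run.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import UnsupportedSamplerError
from .sampling import SamplingScheme
from .tree import RootedTree

__all__ = ["MCSummary", "draw_sample", "mc_pd", "mc_beta"]

CHUNK = 1024


@dataclass(frozen=True)
class MCSummary:
    """Summary of a Monte-Carlo sampling experiment."""

    reps: int
    seed: int
    mean_pd: float
    sd_pd: float
    se_mean: float
    mean_tips: float
    mean_shared: float | None = None
    se_shared: float | None = None
    mean_union: float | None = None
    se_union: float | None = None
    mean_unifrac: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _chunk_rng(seed: int, chunk_index: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=seed, counter=chunk_index << 66))


def _inclusion(rng: np.random.Generator, scheme: SamplingScheme,
               rows: int, n_tips: int) -> np.ndarray:
    """Boolean (rows, n_tips) matrix of per-replicate tip presence."""
    if scheme.family == "binomial":
        return rng.random((rows, n_tips)) < scheme.p
    if scheme.family == "poisson":
        thr = -math.expm1(-scheme.p)
        return rng.random((rows, n_tips)) < thr
    eps = scheme.eps
    if eps is None or eps <= 0.0:
        raise UnsupportedSamplerError(
            "negbinom sampling requires eps > 0 (overdispersed eps < 0 has "
            "no shared-gamma generative form; use the analytic results)")
    g = rng.gamma(shape=1.0 / eps, scale=eps, size=rows)
    thr = -np.expm1(-g * scheme.p)
    return rng.random((rows, n_tips)) < thr[:, None]


def draw_sample(tree: RootedTree, scheme: SamplingScheme,
                rng: np.random.Generator) -> set[str]:
    """One random local community: the set of sampled tip labels."""
    incl = _inclusion(rng, scheme, 1, tree.tips.size)[0]
    return {tree.tip_labels[int(t)] for t, keep in zip(tree.tips, incl) if keep}


def _edge_presence_matrix(incl: np.ndarray, desc: np.ndarray) -> np.ndarray:
    """(reps, edges) edge-presence booleans from tip inclusions."""
    return (incl.astype(np.float64) @ desc.T.astype(np.float64)) > 0.5


def mc_pd(tree: RootedTree, scheme: SamplingScheme, reps: int,
          seed: int) -> MCSummary:
    """Monte-Carlo mean and SD of sampled rooted PD over ``reps`` draws."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    desc = tree.descendant_matrix()
    lens = tree.lengths
    pds = np.empty(reps)
    tips = np.empty(reps)
    done = 0
    chunk_index = 0
    while done < reps:
        rows = min(CHUNK, reps - done)
        rng = _chunk_rng(seed, chunk_index)
        incl = _inclusion(rng, scheme, rows, tree.tips.size)
        pres = _edge_presence_matrix(incl, desc)
        pds[done:done + rows] = pres @ lens
        tips[done:done + rows] = incl.sum(axis=1)
        done += rows
        chunk_index += 1
    sd = float(np.std(pds, ddof=1)) if reps > 1 else 0.0
    if reps == 1:
        warnings.warn("reps=1: standard error of the mean is undefined",
                      stacklevel=2)
        se = math.inf
    else:
        se = sd / math.sqrt(reps)
    return MCSummary(reps=reps, seed=seed, mean_pd=float(pds.mean()),
                     sd_pd=sd, se_mean=se, mean_tips=float(tips.mean()))


def mc_beta(tree: RootedTree, scheme_a: SamplingScheme,
            scheme_b: SamplingScheme, reps: int, seed: int) -> MCSummary:
    """Paired draws: Monte-Carlo shared/union branch length and UniFrac.

    Per replicate, independent samples A and B are drawn; shared and union
    branch lengths are recorded, along with per-replicate UniFrac (averaged
    over replicates with non-zero union — a diagnostic for the bias of the
    ratio-of-expectations convention used by the analytic predictions).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    desc = tree.descendant_matrix()
    lens = tree.lengths
    shared = np.empty(reps)
    union = np.empty(reps)
    pd_a = np.empty(reps)
    tips_a = np.empty(reps)
    done = 0
    chunk_index = 0
    while done < reps:
        rows = min(CHUNK, reps - done)
        rng = _chunk_rng(seed, chunk_index)
        incl_a = _inclusion(rng, scheme_a, rows, tree.tips.size)
        incl_b = _inclusion(rng, scheme_b, rows, tree.tips.size)
        pres_a = _edge_presence_matrix(incl_a, desc)
        pres_b = _edge_presence_matrix(incl_b, desc)
        shared[done:done + rows] = (pres_a & pres_b) @ lens
        union[done:done + rows] = (pres_a | pres_b) @ lens
        pd_a[done:done + rows] = pres_a @ lens
        tips_a[done:done + rows] = incl_a.sum(axis=1)
        done += rows
        chunk_index += 1
    ok = union > 0
    unifrac = float(np.mean((union[ok] - shared[ok]) / union[ok])) if ok.any() else math.nan
    sd = float(np.std(pd_a, ddof=1)) if reps > 1 else 0.0
    se = sd / math.sqrt(reps) if reps > 1 else math.inf
    if reps == 1:
        warnings.warn("reps=1: standard error of the mean is undefined",
                      stacklevel=2)

    def _se(x):
        return float(np.std(x, ddof=1) / math.sqrt(reps)) if reps > 1 else math.inf

    return MCSummary(
        reps=reps, seed=seed, mean_pd=float(pd_a.mean()), sd_pd=sd,
        se_mean=se, mean_tips=float(tips_a.mean()),
        mean_shared=float(shared.mean()), se_shared=_se(shared),
        mean_union=float(union.mean()), se_union=_se(union),
        mean_unifrac=unifrac,
    )
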