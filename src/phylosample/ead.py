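"""The Edge-length Abundance Distribution (EAD) and power-law summaries.

The EAD is the phylogenetic analogue of the species abundance distribution:
``L(n)`` is the total branch length summed over all edges of the
metacommunity tree that have exactly ``n`` descendant tips.  It is the only
feature of the tree that the closed-form sampling expectations depend on,
and empirically it is often close to a power law, ``L(n) ~ n**-alpha``.

Octave (Preston-style) binning groups abundance classes into half-open
base-2 bins ``[2**k, 2**(k+1))`` before plotting or fitting, exactly as
species abundance distributions are conventionally displayed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError
from .tree import RootedTree

__all__ = [
    "EAD", "BinnedEAD", "PowerLawFit",
    "compute_ead", "bin_ead", "fit_power_law", "power_law_ead",
]


@dataclass(frozen=True)
class EAD:
    """Map from abundance class ``n`` to total edge length ``L(n)``.

    ``entries`` keeps every class that has at least one edge, even when the
    summed length is 0 (zero-length edges are common in real trees).
    """

    entries: dict[int, float]
    n_tips: int

    def __post_init__(self):
        for n, length in self.entries.items():
            if not (1 <= n <= self.n_tips):
                raise ValueError(f"abundance class {n} outside [1, {self.n_tips}]")
            if length < 0:
                raise ValueError(f"negative edge length for class {n}")

    @property
    def classes(self) -> np.ndarray:
        return np.array(sorted(self.entries), dtype=np.int64)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([self.entries[n] for n in sorted(self.entries)])

    def total_length(self) -> float:
        return float(sum(self.entries.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.classes, "edge_length": self.lengths})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "EAD":
        df = pd.read_csv(path, sep="\t")
        entries = dict(zip(df["n"].astype(int), df["edge_length"].astype(float)))
        return cls(entries=entries, n_tips=max(entries))


@dataclass(frozen=True)
class BinnedEAD:
    """Octave-binned EAD: bin k covers classes in [2**k, 2**(k+1)).

    ``n_classes`` counts, per bin, the abundance classes with positive mass
    actually present in the source EAD; it is the denominator for the
    per-class density used in power-law fitting (for a fully occupied
    support this equals the covered bin width).
    """

    bins: list[tuple[int, int, float]]  # (lower, upper, mass)
    n_classes: list[int] = field(default_factory=list)
    base: int = 2

    def total_mass(self) -> float:
        return float(sum(b[2] for b in self.bins))

    def to_frame(self) -> pd.DataFrame:
        lo, hi, mass = zip(*self.bins)
        return pd.DataFrame({"bin_lower": lo, "bin_upper": hi, "mass": mass})

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of log2 binned edge-length density against log2 abundance."""

    exponent: float   # alpha in L(n) ~ n**-alpha
    intercept: float  # log2-scale offset
    r_squared: float

    def __post_init__(self):
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared outside [0, 1]")


def compute_ead(tree: RootedTree) -> EAD:
    """Edge-length abundance distribution of a metacommunity tree.

    Sums the branch length of every edge (including the root edge) into the
    abundance class given by its descendant-tip count; conserves total
    branch length exactly.
    """
    entries: dict[int, float] = {}
    for i in range(tree.n_nodes):
        n = int(tree.n_desc[i])
        entries[n] = entries.get(n, 0.0) + float(tree.lengths[i])
    return EAD(entries=entries, n_tips=tree.n_tips)


def bin_ead(ead: EAD) -> BinnedEAD:
    """Group an EAD into Preston octaves [2**k, 2**(k+1)), k = 0, 1, ...

    Bins run from class 1 up to the octave containing N, so their union
    covers [1, N]; total mass is conserved.
    """
    if not ead.entries:
        raise InsufficientDataError("empty EAD")
    kmax = int(np.floor(np.log2(ead.n_tips)))
    bins = []
    counts = []
    for k in range(kmax + 1):
        lo, hi = 2 ** k, 2 ** (k + 1)
        mass = 0.0
        cnt = 0
        for n, length in ead.entries.items():
            if lo <= n < hi:
                mass += length
                if length > 0:
                    cnt += 1
        bins.append((lo, hi, mass))
        counts.append(cnt)
    return BinnedEAD(bins=bins, n_classes=counts)


def fit_power_law(binned: BinnedEAD, normalize: str = "classes",
                  abscissa: str = "lower") -> PowerLawFit:
    """Estimate the power-law exponent alpha of L(n) ~ n**-alpha by OLS on
    log2-transformed octave bins.

    Parameters
    ----------
    normalize : {"classes", "width", "none"}
        What to divide each bin mass by before taking logs: the number of
        occupied abundance classes in the bin (default; estimates the mean
        per-class edge length, so sparsely occupied high-abundance octaves
        are not biased low), the covered bin width, or nothing.
    abscissa : {"lower", "midpoint"}
        x-coordinate of a bin: log2 of its lower edge, or log2 of the
        geometric midpoint sqrt(lower*upper).

    Bins with zero mass are dropped; at least 3 positive bins are required.
    """
    if normalize not in ("classes", "width", "none"):
        raise ValueError(f"unknown normalization {normalize!r}")
    if abscissa not in ("lower", "midpoint"):
        raise ValueError(f"unknown abscissa {abscissa!r}")
    xs, ys = [], []
    for (lo, hi, mass), cnt in zip(binned.bins, binned.n_classes):
        if mass <= 0:
            continue
        if normalize == "classes":
            y = mass / cnt
        elif normalize == "width":
            y = mass / (hi - lo)
        else:
            y = mass
        x = np.log2(lo) if abscissa == "lower" else 0.5 * (np.log2(lo) + np.log2(hi))
        xs.append(x)
        ys.append(np.log2(y))
    if len(xs) < 3:
        raise InsufficientDataError(
            f"power-law fit needs >=3 positive octave bins, got {len(xs)}")
    res = stats.linregress(xs, ys)
    r2 = float(res.rvalue) ** 2
    if np.isnan(r2):  # constant y: the line fits exactly
        r2 = 1.0
    return PowerLawFit(exponent=-float(res.slope), intercept=float(res.intercept),
                       r_squared=r2)


def power_law_ead(exponent: float, n_max: int, scale: float = 1.0) -> EAD:
    """Exact theoretical EAD with L(n) = scale * n**-exponent, n = 1..n_max.

    Used for theory curves of expected PD and UniFrac against sample size;
    ``exponent`` may be 0 (flat) but not negative, and ``n_max >= 2``.
    """
    if n_max < 2:
        raise ValueError("n_max must be >= 2")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    ns = np.arange(1, n_max + 1)
    vals = scale * ns.astype(float) ** (-exponent)
    return EAD(entries=dict(zip(ns.tolist(), vals.tolist())), n_tips=int(n_max))
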