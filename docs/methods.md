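# Methods

## Model

A metacommunity is a rooted phylogenetic tree with non-negative branch
lengths whose tips are individual organisms (in microbiome applications,
individual 16S reads); multifurcations and zero-length edges are accepted
as-is, since both are routine in large inferred trees. A local community is
modeled as a random subset of tips produced by a *sampling scheme*, and all
alpha- and beta-diversity expectations follow from two ingredients:

1. the **edge-length abundance distribution (EAD)** `L(n)` — total branch
   length over edges with exactly `n` descendant tips — which is the only
   property of the tree the expectations use; and
2. the scheme's **presence probability** `P(n)` — the chance that a clade
   of `n` tips contributes at least one sampled individual.

Expected rooted PD is `Σ_n L(n)·P(n)`; expected shared and union branch
length for two independent samples are `Σ_n L(n)·P_A·P_B` and
`Σ_n L(n)·(1−(1−P_A)(1−P_B))`.

### The rooted PD convention

`induced_pd` counts every edge with at least one sampled descendant, which
connects the sample's subtree to the root. This convention is forced by the
edge-by-edge expectation above: an edge is present in the sample exactly
when its clade is hit, for *all* edges on the root path included. Software
using the MRCA-spanning (unrooted) convention reports smaller PD for
samples confined to a subclade; comparisons across tools must account for
this. The root edge itself is modeled as an edge of length 0 (unless the
newick supplies one) in abundance class N, so it never changes totals but
keeps the bookkeeping uniform.

### Sampling schemes

* binomial: `P(n) = 1 − (1−p)^n`, `0 ≤ p ≤ 1` (without replacement).
* poisson: `P(n) = 1 − e^(−pn)`, `p ≥ 0` mean count per individual (with
  replacement).
* negative binomial: `P(n) = 1 − (1 + εpn)^(−1/ε)`. The generative story
  (used by the Monte-Carlo sampler and the variance) is a single
  community-wide gamma factor `g` with mean 1 and variance ε multiplying
  every tip's Poisson intensity `p`; conditional on `g` tips are
  independent. ε > 0 is clustered sampling, ε → 0 recovers Poisson, and
  ε < 0 (overdispersed) is admitted analytically on the domain
  `1 + εpn > 0` but has no shared-gamma sampler — a documented limitation.

Two consequences worth knowing:

* At matched *expected distinct tips*, binomial and Poisson are identical:
  both have `1 − P(n) = (1 − P(1))^n`. They differ only when compared at
  equal intensity `p` (equal sampling *effort*), where Poisson's
  with-replacement repeats waste effort once `p` is large.
* At matched expected tips, clustered sampling (ε > 0) has
  `−log(1−P(n))` concave in `n` with equality at `n = 1`, hence
  `P(n) ≤ P_poisson(n)` for all `n ≥ 1`: clustered samples carry less
  expected PD at the same size, which is what makes the scheme a model of
  phylogenetic clustering.

All probabilities are evaluated through `log1p`/`expm1`, so `p → 0`,
`p → 1` and `ε → 0` are exact to machine precision; |ε| below 1e−150 (where
`εpn` would underflow) falls back to the exact Poisson limit.

### Variance of sampled PD

With `I_e` the edge-presence indicator and `Q(n) = 1 − P(n)`:

    Var(PD) = Σ_e l_e² P_e Q_e
            + 2 Σ_{a ancestor of d} l_a l_d P_d (1 − P_a)
            + 2 Σ_{a,b disjoint} l_a l_b [Q(n_a + n_b) − Q(n_a) Q(n_b)]

The ancestor term uses `E[I_a I_d] = P_d` (a sampled descendant implies a
sampled ancestor), and is accumulated in O(edges) by one post-order pass
(subtree sums of `l·P`). The disjoint-pair term is the covariance induced
by the shared gamma factor; for binomial and Poisson `Q` is multiplicative
in `n`, so the term vanishes identically and is skipped; for negative
binomial it is evaluated pairwise in O(edges²) using DFS-interval ancestor
tests (fine up to a few thousand tips; the regime where the closed forms
are compared against enumeration and randomization here). For ε < 0 the
same formula is analytically continued (negative disjoint covariances).

The variance is validated two ways: exact agreement (1e−12) with full 2^N
subset enumeration on trees of ≤ 8 tips, and 3-standard-error agreement
with 10⁴-replicate Monte Carlo on 100-tip trees for all three families.

### Expected UniFrac and normalization

Expected UniFrac is defined as the **ratio of expectations**
`1 − E[shared]/E[union]`, matching how the analytic shared and union
curves are combined; the Monte-Carlo pair sampler also reports the mean of
per-replicate UniFrac so the (small) Jensen bias of this convention is
measurable rather than assumed. Observed UniFrac between two communities
of sizes `T_A`, `T_B` is normalized by the expected UniFrac of two random
samples whose intensities are fitted to those sizes; values below 1 mean
"more similar than random same-sized samples". The motivating fact,
reproduced by the acceptance checks, is that expected UniFrac between two
*random* samples grows with the imbalance of their sizes at fixed mean, so
raw UniFrac values for unequal samples are not comparable without this
normalization (the common alternative — subsampling down to the smaller
size — discards data).

### Null-model classification

For an observed community of `T` distinct tips, the scheme intensity is
fitted by moment matching `N·P(1) = T` (closed-form inverse in every
family — the only observable quantity that is analytic in all three), and
the observed PD is placed against `E[PD] ± z_{1−α/2}·sd`. Below the band:
clustered; above: overdispersed; inside: consistent with random assembly.
The normal approximation is the default (PD is a sum of many weakly
dependent edge terms); a distribution-free Chebyshev band
(`± sd/√α`) is available as `ci_method="chebyshev"` for small or very
skewed metacommunities. Because the null band at the *fitted* intensity
includes tip-count variability while the observed PD is implicitly
conditioned on its tip count, the band is slightly conservative:
calibration on simulated random samples yields ≥ 95% "random" labels at
α = 0.05 rather than exactly 95%.

### Octave binning and power-law fitting

EADs are displayed and fitted in Preston-style half-open base-2 octaves
`[2^k, 2^(k+1))` (half-open avoids double counting; the bins cover
`[1, N]`). The fit is ordinary least squares on log2-transformed octave
values, with two documented conventions, both exposed as options:

* ordinate (`normalize`): bin mass divided by the number of *occupied*
  abundance classes in the bin (default). For a fully occupied support
  this equals mass-per-unit-width (a density); for tree EADs, where high
  octaves contain only a few occupied classes, it estimates the per-class
  trend `L(n)` itself and so avoids the downward bias a raw-width density
  would have. `width` and `none` are available.
* abscissa: log2 of the bin's lower edge (default) or of its geometric
  midpoint.

Zero-mass bins are dropped; at least three positive bins are required.

## Synthetic data

* `fixture_tree()` — `((A:1,B:2):2,(C:1,D:1):1)`, total length 8, EAD
  `{1: 5, 2: 3, 4: 0}`; contains a length-2 edge with exactly two
  descendant tips, the canonical worked example for reading off an EAD.
  Its edge lengths are this package's own fixture choice.
* `yule_tree(n, seed, length_scale)` — pure-birth topology (uniformly
  chosen lineage splits) with i.i.d. exponential branch lengths,
  mean `length_scale` (default 1). This emulates the neutral-topology,
  homogeneous-rate limit; real microbiome trees have rate heterogeneity,
  zero-length edges and multifurcations that the generator omits, so
  passing property tests demonstrate correctness of the mathematics, not
  realism of the tree shape.
* `powerlaw_tree(n, α, seed, scale)` — uniformly random pairwise-merge
  topology whose per-class edge lengths are rescaled so the EAD is
  *exactly* `scale·n^(−α)` on occupied classes (classes with no edge are
  absent). Fixing the EAD exactly makes downstream exponent-recovery
  checks sharp; the cost is that individual branch lengths are not
  independently distributed, which is irrelevant for EAD-level claims.

Defaults used by the validation suite: 4–8-tip trees for exhaustive
enumeration; 100-tip Yule trees with 10⁴ Monte-Carlo replicates for
moment agreement; a 300-tip Yule metacommunity with 200 replicates for CI
calibration; `n_max = 2^12` power-law EADs (α ≈ 1, as observed in
microbiome trees) for curve-shape checks; 2^10-tip power-law trees for
exponent recovery. These sizes make every check sharp at desk scale while
the closed forms themselves are O(edges) and run unchanged on 10⁶-tip
trees.

## Numerical and design choices

* Expected-PD curves against sample size are evaluated on a grid of target
  tip counts inverted through the closed-form intensity solve; the curve
  is strictly increasing in the target. On a power-law EAD with α ≈ 1 the
  log-log curve is linear (R² > 0.99) only in the asymptotic regime after
  the crossover from the small-sample linear regime (E[PD] ≈ p·ΣnL(n));
  the shape checks therefore evaluate two decades of expected tips,
  20–2000 of N = 4096.
* `pd_curve` takes the tree (the variance needs per-edge lengths, which
  the EAD alone cannot supply); `theory_curve` takes a bare EAD and omits
  the band.
* Monte-Carlo replicates are drawn in fixed chunks of 1024, one
  counter-offset Philox stream per chunk: bit-reproducible for a given
  seed, independent of chunking, vectorized within chunks.
* Average-linkage clustering of normalized-UniFrac matrices pre-sorts
  labels lexicographically, so scipy's index-order tie-breaking realizes
  a deterministic lexicographic merge rule; the dendrogram serializes to
  newick with merge-height differences as branch lengths.
* Degenerate inputs: empty tip sets have PD 0; UniFrac and normalization
  raise explicit undefined-distance errors on zero denominators; a null
  with sd = 0 and a deviating observation warns and labels by sign;
  `reps = 1` Monte Carlo flags an infinite standard error.

## Known limitations

* Overdispersed (ε < 0) negative-binomial sampling has closed-form moments
  but no generative sampler, so it is validated only against the analytic
  limits, not simulation.
* The negbinom variance's pairwise term is O(edges²); on trees far beyond
  ~10⁴ edges it becomes the bottleneck (binomial/Poisson variance stays
  O(edges)).
* Fixed-size sampling (hypergeometric/multinomial conditioning) and
  mechanistic dispersal-limitation schemes are out of scope; the three
  families here are phenomenological.
* Expected UniFrac is a ratio of expectations, not the expectation of the
  ratio; the Monte-Carlo diagnostic quantifies the difference per
  application rather than bounding it in general.
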