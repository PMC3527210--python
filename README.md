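# phylosample

Analytical sampling theory for phylogenetic diversity.

`phylosample` treats a local community of co-occurring organisms as a random
sample of individuals from a larger regional pool (the *metacommunity*,
represented by a rooted phylogenetic tree whose tips are individual sampled
sequences), and computes — in closed form — the expected phylogenetic
diversity (PD) of such a sample, its variance, and the expected shared
branch length and UniFrac distance between two samples. This replaces the
"brute force" randomization nulls of classic community phylogenetics, which
become intractable on trees with 10⁵–10⁶ tips (e.g. 16S amplicon surveys of
the human microbiome), and it makes null expectations available for
non-uniform assembly processes (clustered and overdispersed sampling) that
randomization cannot easily emulate.

It is aimed at microbial ecologists and community phylogeneticists who want
to ask: *is the PD of this habitat's community lower (environmental
filtering), higher (competitive exclusion), or about what a random sample of
the same size from the regional pool would give?*

## The theory in brief

The only feature of the metacommunity tree the expectations depend on is its
**edge-length abundance distribution (EAD)**: `L(n)`, the total branch
length summed over all edges with exactly `n` descendant tips — the
phylogenetic analogue of the species abundance distribution (and, like it,
empirically close to a power law `L(n) ∝ n^(−α)` in microbiome trees).

A sampling scheme is characterized by `P(n)`, the probability that a clade
with `n` tips contributes at least one sampled individual:

| family     | `P(n)`                        | interpretation |
|------------|-------------------------------|----------------|
| `binomial` | `1 − (1−p)^n`                 | each individual sampled independently with probability `p` (without replacement) |
| `poisson`  | `1 − e^(−pn)`                 | per-individual counts Poisson with mean `p` (with replacement) |
| `negbinom` | `1 − (1 + εpn)^(−1/ε)`        | a shared gamma factor (mean 1, variance ε) modulates all intensities; `ε > 0` clustered, `ε < 0` overdispersed, `ε → 0` Poisson |

Then, with PD in the rooted convention (every edge with at least one sampled
descendant counts, connecting the sample to the root):

    E[PD]      = Σ_n L(n) · P(n)
    E[shared]  = Σ_n L(n) · P_A(n) · P_B(n)
    E[union]   = Σ_n L(n) · (1 − (1−P_A(n))(1−P_B(n)))
    E[UniFrac] = 1 − E[shared]/E[union]

The variance of sampled PD is also closed-form, using the fact that a
descendant edge's presence implies its ancestor's (and, for negative-binomial
sampling, the covariance between disjoint edges induced by the shared gamma
factor). An observed community is classified *clustered / random /
overdispersed* by fitting the intensity so the null's expected distinct-tip
count matches the observed tip count, then placing the observed PD against
the expectation ± z·sd band.

## Worked example

```python
import numpy as np
import phylosample as ps

tree = ps.fixture_tree()            # ((A:1,B:2):2,(C:1,D:1):1);
ead = ps.compute_ead(tree)
print("EAD:", ead.entries)

scheme = ps.SamplingScheme("binomial", 0.5)
pred = ps.predict(tree, scheme)
print(f"E[PD] = {pred.expected_pd}, Var[PD] = {pred.variance_pd}, "
      f"E[tips] = {pred.expected_tips}")

mc = ps.mc_pd(tree, scheme, reps=100_000, seed=1)
print(f"Monte Carlo: mean = {mc.mean_pd:.4f} +/- {mc.se_mean:.4f}, "
      f"variance = {mc.sd_pd**2:.4f}")
```

prints

```
EAD: {4: 0.0, 2: 3.0, 1: 5.0}
E[PD] = 4.75, Var[PD] = 4.6875, E[tips] = 2.0
Monte Carlo: mean = 4.7545 +/- 0.0069, variance = 4.6965
```

Reading it: the fixture tree has 5.0 units of pendant branch length
(`L(1)`), 3.0 on two-tip edges (`L(2)`), and a zero-length root edge
(`L(4)`). Sampling each of the 4 tips with probability ½ keeps each pendant
edge with probability ½ and each two-tip edge with probability ¾, so
`E[PD] = 5·0.5 + 3·0.75 = 4.75` out of a total branch length of 8 — and the
100 000-replicate randomization null agrees to within its standard error,
while taking five orders of magnitude more work.

Null-model classification of communities on a 300-tip simulated
metacommunity (one genuinely random sample, one single-clade community):

```python
meta = ps.yule_tree(300, seed=11)
model = ps.PDNullModel(meta, {"random-sample": random_tips,
                              "one-clade": clade_tips})
print(model.fit().summary())
```

```
Phylogenetic diversity null-model classification
=================================================
Metacommunity: N=300 tips, total branch length 573.279
Null: binomial, alpha=0.05, CI=normal
Samples: 2 (clustered 1, random 1, overdispersed 0)
    sample_id  observed_tips  observed_pd  fitted_intensity  expected_pd  sd_pd  z_score  ci_low  ci_high     label
    one-clade             28        67.64           0.09333        139.5  20.92   -3.437   98.54    180.5 clustered
random-sample             33        143.7              0.11        156.1  21.22  -0.5842   114.6    197.7    random
```

The clade-restricted community carries far less branch length than a random
sample of the same size (z ≈ −3.4): phylogenetically clustered. The same
analysis is available from the shell (`phylosample classify --tree meta.nwk
--samples members.tsv`), along with `ead`, `fit`, `expected-pd`, `curve`,
`unifrac`, `simulate` and `mc` subcommands.

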