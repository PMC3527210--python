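"""Expected/observed shared branch length, UniFrac, clustering."""

import numpy as np
import pandas as pd
import pytest

import phylosample as ps
from phylosample.errors import PhylosampleError, UndefinedDistanceError

B_HALF = ps.SamplingScheme("binomial", 0.5)
B_ONE = ps.SamplingScheme("binomial", 1.0)
B_ZERO = ps.SamplingScheme("binomial", 0.0)


class TestExpectedShared:
    def test_both_certain(self, ead4):
        assert ps.expected_shared(ead4, B_ONE, B_ONE) == pytest.approx(8.0)

    def test_fixture_half(self, ead4):
        assert ps.expected_shared(ead4, B_HALF, B_HALF) == pytest.approx(2.9375)

    def test_empty_sample_shares_nothing(self, ead4):
        assert ps.expected_shared(ead4, B_ZERO, B_HALF) == 0.0


class TestExpectedUnion:
    def test_fixture_half(self, ead4):
        assert ps.expected_union(ead4, B_HALF, B_HALF) == pytest.approx(6.5625)

    def test_one_certain_gives_total(self, ead4):
        for other in [B_ZERO, B_HALF, B_ONE]:
            assert ps.expected_union(ead4, B_ONE, other) == pytest.approx(8.0)

    @pytest.mark.parametrize("pa,pb", [(0.2, 0.7), (0.5, 0.5), (0.9, 0.1)])
    def test_inclusion_exclusion_identity(self, ead4, pa, pb):
        sa, sb = ps.SamplingScheme("binomial", pa), ps.SamplingScheme("binomial", pb)
        lhs = ps.expected_union(ead4, sa, sb)
        rhs = (ps.expected_pd(ead4, sa) + ps.expected_pd(ead4, sb)
               - ps.expected_shared(ead4, sa, sb))
        assert lhs == pytest.approx(rhs, abs=1e-12)


class TestExpectedUniFrac:
    def test_fixture_half(self, ead4):
        assert ps.expected_unifrac(ead4, B_HALF, B_HALF) == \
            pytest.approx(1 - 2.9375 / 6.5625)

    def test_identical_full_samples(self, ead4):
        assert ps.expected_unifrac(ead4, B_ONE, B_ONE) == pytest.approx(0.0)

    def test_symmetry(self, ead4):
        sa = ps.SamplingScheme("binomial", 0.3)
        sb = ps.SamplingScheme("poisson", 0.8)
        assert ps.expected_unifrac(ead4, sa, sb) == \
            pytest.approx(ps.expected_unifrac(ead4, sb, sa))

    def test_zero_union_undefined(self):
        ead = ps.EAD({1: 1.0}, n_tips=2)
        with pytest.raises(UndefinedDistanceError):
            ps.expected_unifrac(ead, B_ZERO, B_ZERO)

    def test_unequal_sizes_increase_unifrac(self):
        """Two random samples of unequal size are expected to look more
        different than two equal-sized samples with the same mean size."""
        ead = ps.power_law_ead(1.0, 4096)
        pbar = 0.05
        prev = -np.inf
        for delta in [0.0, 0.01, 0.02, 0.03, 0.04]:
            u = ps.expected_unifrac(
                ead, ps.SamplingScheme("binomial", pbar + delta),
                ps.SamplingScheme("binomial", pbar - delta))
            assert u > prev
            prev = u


class TestObservedUniFrac:
    def test_identical_samples_zero(self, t4):
        assert ps.observed_unifrac(t4, {"A", "B"}, {"A", "B"}) == 0.0

    def test_disjoint_clades_one(self, t4):
        assert ps.observed_unifrac(t4, {"A", "B"}, {"C", "D"}) == 1.0

    def test_nested_sets(self, t4):
        assert ps.observed_unifrac(t4, {"A"}, {"A", "B"}) == pytest.approx(0.4)

    def test_empty_set_rejected(self, t4):
        with pytest.raises(PhylosampleError):
            ps.observed_unifrac(t4, set(), {"A"})

    def test_monte_carlo_matches_expected_shared_union(self, yule100):
        s = ps.SamplingScheme("binomial", 0.5)
        mc = ps.mc_beta(yule100, s, s, reps=10_000, seed=5)
        ead = ps.compute_ead(yule100)
        assert abs(ps.expected_shared(ead, s, s) - mc.mean_shared) < 3 * mc.se_shared
        assert abs(ps.expected_union(ead, s, s) - mc.mean_union) < 3 * mc.se_union


class TestNormalize:
    def test_ratio(self):
        assert ps.normalize_unifrac(0.5, 0.5) == 1.0
        assert ps.normalize_unifrac(0.0, 0.3) == 0.0

    def test_zero_expected_undefined(self):
        with pytest.raises(UndefinedDistanceError):
            ps.normalize_unifrac(0.5, 0.0)

    def test_random_samples_normalize_near_one(self, ead4):
        u = ps.expected_unifrac(ead4, B_HALF, B_HALF)
        assert ps.normalize_unifrac(u, u) == pytest.approx(1.0)


class TestClusterDistances:
    def test_single_pair(self):
        m = pd.DataFrame([[0, 0.3], [0.3, 0]], index=["X", "Y"], columns=["X", "Y"])
        d = ps.cluster_distances(m)
        assert d.linkage.shape == (1, 4)
        assert d.linkage[0, 2] == pytest.approx(0.3)
        assert d.to_newick() == "(X:0.3,Y:0.3);"

    def test_forced_merge_order(self):
        m = pd.DataFrame([[0, 0.1, 0.5], [0.1, 0, 0.5], [0.5, 0.5, 0]],
                         index=list("ABC"), columns=list("ABC"))
        d = ps.cluster_distances(m)
        assert d.linkage[0, 2] == pytest.approx(0.1)   # {A,B} first
        assert d.linkage[1, 2] == pytest.approx(0.5)
        assert "(A:0.1,B:0.1)" in d.to_newick()

    def test_tie_break_deterministic(self):
        m = np.full((3, 3), 0.4)
        np.fill_diagonal(m, 0.0)
        d1 = ps.cluster_distances(m, labels=["b", "a", "c"])
        d2 = ps.cluster_distances(m, labels=["c", "a", "b"])
        assert d1.to_newick() == d2.to_newick()

    def test_asymmetric_rejected(self):
        m = np.array([[0.0, 0.1], [0.2, 0.0]])
        with pytest.raises(PhylosampleError):
            ps.cluster_distances(m, labels=["X", "Y"])

    def test_nan_rejected(self):
        m = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(PhylosampleError):
            ps.cluster_distances(m, labels=["X", "Y"])
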