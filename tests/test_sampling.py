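"""Presence probabilities, expected PD, variance, intensity solving."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import phylosample as ps
from phylosample.errors import SchemeDomainError
from conftest import exhaustive_binomial_moments


class TestScheme:
    def test_string_round_trip(self):
        s = ps.SamplingScheme.from_string("negbinom:p=0.1,eps=0.5")
        assert (s.family, s.p, s.eps) == ("negbinom", 0.1, 0.5)
        assert ps.SamplingScheme.from_string(str(s)) == s

    @pytest.mark.parametrize("bad", ["binomial:p=1.5", "poisson:p=-1",
                                     "negbinom:p=0.1", "gauss:p=0.1",
                                     "binomial:p=0.5,eps=1"])
    def test_invalid_specs(self, bad):
        with pytest.raises(SchemeDomainError):
            ps.SamplingScheme.from_string(bad)


class TestPresenceProbability:
    def test_binomial_closed_form(self):
        s = ps.SamplingScheme("binomial", 0.5)
        assert ps.presence_probability(s, 2) == pytest.approx(0.75)

    def test_poisson_closed_form(self):
        s = ps.SamplingScheme("poisson", 0.1)
        assert ps.presence_probability(s, 10) == pytest.approx(1 - math.exp(-1))

    @pytest.mark.parametrize("n", [1, 10, 1000])
    def test_negbinom_poisson_limit(self, n):
        pois = ps.presence_probability(ps.SamplingScheme("poisson", 0.1), n)
        nb = ps.presence_probability(ps.SamplingScheme("negbinom", 0.1, 1e-8), n)
        assert nb == pytest.approx(pois, rel=1e-6)

    def test_negbinom_domain_error_names_class(self):
        s = ps.SamplingScheme("negbinom", 2.0, -0.2)
        with pytest.raises(SchemeDomainError, match="n ="):
            ps.presence_probability(s, 10)

    @given(p=st.floats(0.0, 1.0), n=st.integers(1, 10_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_binomial_in_unit_interval_and_monotone_in_n(self, p, n):
        s = ps.SamplingScheme("binomial", p)
        v = ps.presence_probability(s, n)
        assert 0.0 <= v <= 1.0
        assert v <= ps.presence_probability(s, n + 1) + 1e-15

    @given(p=st.floats(0.001, 0.999), dp=st.floats(1e-6, 0.3))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_intensity_all_families(self, p, dp):
        for fam, eps in [("binomial", None), ("poisson", None),
                         ("negbinom", 0.5), ("negbinom", -0.05)]:
            hi = min(p + dp, 1.0) if fam == "binomial" else p + dp
            lo_s = ps.SamplingScheme(fam, p, eps)
            hi_s = ps.SamplingScheme(fam, hi, eps)
            assert (ps.presence_probability(lo_s, 7)
                    <= ps.presence_probability(hi_s, 7) + 1e-15)


class TestExpectedPD:
    def test_fixture_binomial_half(self, ead4):
        s = ps.SamplingScheme("binomial", 0.5)
        assert ps.expected_pd(ead4, s) == pytest.approx(4.75)

    def test_certainty_gives_total_length(self, ead4):
        assert ps.expected_pd(ead4, ps.SamplingScheme("binomial", 1.0)) == \
            pytest.approx(8.0)

    @pytest.mark.parametrize("scheme", [
        ps.SamplingScheme("binomial", 0.0),
        ps.SamplingScheme("poisson", 0.0),
        ps.SamplingScheme("negbinom", 0.0, 0.5),
    ])
    def test_zero_intensity_zero_pd(self, ead4, scheme):
        assert ps.expected_pd(ead4, scheme) == 0.0

    def test_clustering_lowers_pd_at_matched_tips(self):
        """For a power-law metacommunity, clustered (eps>0) sampling yields
        less expected PD than Poisson at the same expected tip count."""
        ead = ps.power_law_ead(1.0, 1024)
        for target in [5, 20, 100, 400]:
            pois = ps.solve_intensity("poisson", 1024, target)
            clus = ps.solve_intensity("negbinom", 1024, target, eps=1.0)
            assert (ps.expected_pd(ead, clus)
                    <= ps.expected_pd(ead, pois) + 1e-12)

    def test_poisson_tracks_binomial_until_samples_grow(self):
        """At equal intensity, sampling with replacement (Poisson) matches
        sampling without (binomial) for small p and diverges for large p."""
        ead = ps.power_law_ead(1.0, 4096)
        small = 0.002
        assert ps.expected_pd(ead, ps.SamplingScheme("poisson", small)) == \
            pytest.approx(ps.expected_pd(ead, ps.SamplingScheme("binomial", small)),
                          rel=1e-3)
        big = 0.8
        assert (ps.expected_pd(ead, ps.SamplingScheme("poisson", big))
                != pytest.approx(
                    ps.expected_pd(ead, ps.SamplingScheme("binomial", big)),
                    rel=1e-3))


class TestExpectedTips:
    def test_binomial(self):
        assert ps.expected_tips(ps.SamplingScheme("binomial", 0.5), 4) == 2.0
        assert ps.expected_tips(ps.SamplingScheme("binomial", 1.0), 17) == 17.0

    def test_poisson(self):
        assert ps.expected_tips(ps.SamplingScheme("poisson", 0.1), 100) == \
            pytest.approx(100 * (1 - math.exp(-0.1)))


class TestSolveIntensity:
    def test_binomial_closed_form(self):
        assert ps.solve_intensity("binomial", 4, 2).p == pytest.approx(0.5)

    def test_poisson_inverse(self):
        target = 100 * (1 - math.exp(-0.1))
        s = ps.solve_intensity("poisson", 100, target)
        assert s.p == pytest.approx(0.1, rel=1e-10)

    def test_target_above_n_rejected(self):
        with pytest.raises(SchemeDomainError):
            ps.solve_intensity("binomial", 4, 5)

    def test_poisson_cannot_reach_full(self):
        with pytest.raises(SchemeDomainError):
            ps.solve_intensity("poisson", 10, 10)

    @given(frac=st.floats(0.01, 0.95), eps=st.floats(-0.05, 2.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_round_trip_all_families(self, frac, eps):
        n = 500
        target = frac * n
        for fam, e in [("binomial", None), ("poisson", None), ("negbinom", eps)]:
            s = ps.solve_intensity(fam, n, target, eps=e)
            assert ps.expected_tips(s, n) == pytest.approx(target, rel=1e-10)


class TestVariancePD:
    def test_fixture_value(self, t4):
        s = ps.SamplingScheme("binomial", 0.5)
        assert ps.variance_pd(t4, s) == pytest.approx(4.6875)

    def test_degenerate_at_certainty(self, t4):
        assert ps.variance_pd(t4, ps.SamplingScheme("binomial", 1.0)) == 0.0
        assert ps.variance_pd(t4, ps.SamplingScheme("binomial", 0.0)) == 0.0

    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_exhaustive_oracle_fixture(self, t4, ead4, p):
        s = ps.SamplingScheme("binomial", p)
        mean, var = exhaustive_binomial_moments(t4, p)
        assert ps.expected_pd(ead4, s) == pytest.approx(mean, abs=1e-12)
        assert ps.variance_pd(t4, s) == pytest.approx(var, abs=1e-12)

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_exhaustive_oracle_random_trees(self, seed):
        tree = ps.yule_tree(7, seed=seed)
        ead = ps.compute_ead(tree)
        for p in [0.2, 0.5, 0.8]:
            mean, var = exhaustive_binomial_moments(tree, p)
            s = ps.SamplingScheme("binomial", p)
            assert ps.expected_pd(ead, s) == pytest.approx(mean, abs=1e-12)
            assert ps.variance_pd(tree, s) == pytest.approx(var, abs=1e-12)

    def test_monte_carlo_agreement_poisson_negbinom(self, yule100):
        for scheme in [ps.SamplingScheme("poisson", 0.5),
                       ps.SamplingScheme("negbinom", 0.5, 0.5)]:
            mc = ps.mc_pd(yule100, scheme, reps=10_000, seed=7)
            ead = ps.compute_ead(yule100)
            assert abs(ps.expected_pd(ead, scheme) - mc.mean_pd) < 3 * mc.se_mean
            # variance of the sample variance ~ 2 sigma^4 / (reps-1) for
            # near-normal PD sums; allow a generous 10% band instead
            assert ps.variance_pd(yule100, scheme) == pytest.approx(
                mc.sd_pd ** 2, rel=0.10)

    def test_predict_bundle(self, t4):
        pred = ps.predict(t4, ps.SamplingScheme("binomial", 0.5))
        assert pred.expected_pd == pytest.approx(4.75)
        assert pred.variance_pd == pytest.approx(4.6875)
        assert pred.expected_tips == pytest.approx(2.0)
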