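"""Jackknife ratio chain, Welch/paired tests, correlations."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate, stats

from retinostat import synth
from retinostat.ratiostats import (DegenerateSampleError, PairedRatioModel,
                                   PairedSample, correlations,
                                   normalize_paired_batches,
                                   normalized_pool_level, paired_t,
                                   t_sf_two_sided, welch_double_diff, welch_t)


class TestJackknife:
    def test_hand_computed_three_pair_case(self):
        # x=(1,2,3), y=(2,3,7): worked through the leave-one-out formulas
        est = PairedRatioModel(PairedSample([1, 2, 3], [2, 3, 7])).fit()
        assert est.r == pytest.approx(2.0)
        assert est.r_i == pytest.approx([2.0, 9 / 4, 5 / 3])
        assert est.r_c == pytest.approx(float(Fraction(37, 18)))
        s2 = (0 + (9 / 4 - 2) ** 2 + (5 / 3 - 2) ** 2) / 3
        assert est.s == pytest.approx(np.sqrt(s2))
        r_c = Fraction(37, 18)
        s_c2 = sum((Fraction(v) - r_c) ** 2
                   for v in (Fraction(2), Fraction(9, 4), Fraction(5, 3))) / 2
        assert est.s_c == pytest.approx(float(s_c2) ** 0.5)

    @given(c=st.floats(0.1, 10), seed=st.integers(0, 2**16),
           n=st.integers(2, 20))
    def test_constant_ratio_identity(self, c, seed, n):
        """y = c x gives (r, r_c, s, s_c) = (c, c, 0, 0) exactly."""
        x = np.random.default_rng(seed).uniform(0.5, 5.0, n)
        est = PairedRatioModel(PairedSample(x, c * x)).fit()
        assert est.r == pytest.approx(c, rel=1e-12)
        assert est.r_c == pytest.approx(c, rel=1e-12)
        assert est.s == pytest.approx(0.0, abs=1e-10)
        assert est.s_c == pytest.approx(0.0, abs=1e-10)

    def test_bias_correction_beats_naive_ratio(self, rng):
        """With independent numerator/denominator noise the corrected
        estimator is closer to the true ratio on average."""
        true_r, n, reps = 2.0, 6, 40000
        sigma = np.sqrt(np.log1p(0.5**2))
        x = np.exp(rng.normal(-sigma**2 / 2, sigma, (reps, n)))
        y = true_r * np.exp(rng.normal(-sigma**2 / 2, sigma, (reps, n)))
        from retinostat.ratiostats import jackknife_ratio_batch
        r, r_c = jackknife_ratio_batch(x, y)
        assert abs(r_c.mean() - true_r) < abs(r.mean() - true_r)

    def test_order_invariance(self, rng):
        x = rng.uniform(1, 3, 8)
        y = rng.uniform(1, 5, 8)
        perm = rng.permutation(8)
        a = PairedRatioModel(PairedSample(x, y)).fit()
        b = PairedRatioModel(PairedSample(x[perm], y[perm])).fit()
        assert a.r_c == pytest.approx(b.r_c)
        assert a.s_c == pytest.approx(b.s_c)

    def test_nonpositive_denominators_rejected(self):
        with pytest.raises(DegenerateSampleError):
            PairedRatioModel(PairedSample([0.0, 1.0], [1.0, 2.0]))


class TestNormalization:
    def test_pair_means_are_one(self):
        df = pd.DataFrame({
            "batch": ["b1"] * 4 + ["b2"] * 4,
            "pair": [0, 0, 1, 1, 2, 2, 3, 3],
            "genotype": ["WT", "KO"] * 4,
            "intensity": [1.0, 1.5, 2.0, 2.2, 0.5, 0.9, 3.0, 3.3],
        })
        sample = normalize_paired_batches(df)
        assert np.allclose((sample.x + sample.y) / 2, 1.0)

    def test_batch_scale_invariance(self):
        df = pd.DataFrame({
            "batch": ["b1"] * 4,
            "pair": [0, 0, 1, 1],
            "genotype": ["WT", "KO", "WT", "KO"],
            "intensity": [1.0, 1.4, 2.0, 2.6],
        })
        scaled = df.assign(intensity=df["intensity"] * 10)
        a, b = normalize_paired_batches(df), normalize_paired_batches(scaled)
        assert np.allclose(a.x, b.x) and np.allclose(a.y, b.y)

    def test_worked_two_pair_example(self):
        # batch mean = (2+4+6+8)/4 = 5 -> (0.4, 0.8, 1.2, 1.6);
        # pair means 0.6 and 1.4 -> (2/3, 4/3) for both pairs
        df = pd.DataFrame({"batch": ["b"] * 4, "pair": [0, 0, 1, 1],
                           "genotype": ["WT", "KO"] * 2,
                           "intensity": [2.0, 4.0, 6.0, 8.0]})
        sample = normalize_paired_batches(df)
        assert sample.x == pytest.approx([2 / 3, 6 / 7])
        assert sample.y == pytest.approx([4 / 3, 8 / 7])


class TestPairedT:
    def test_identical_pairs_give_p_one(self):
        x = np.array([1.0, 2.0, 3.0])
        assert paired_t(PairedSample(x, x)) == 1.0

    def test_matches_scipy_on_random_data(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 15))
            x = rng.normal(10, 2, n)
            y = x + rng.normal(0.5, 1, n)
            ours = paired_t(PairedSample(x, y))
            ref = stats.ttest_rel(y, x).pvalue
            assert ours == pytest.approx(ref, rel=1e-10)

    def test_zero_variance_nonzero_shift(self):
        x = np.array([1.0, 2.0, 3.0])
        assert paired_t(PairedSample(x, x + 1.0)) == 0.0


class TestWelch:
    def test_equal_means_give_p_one(self):
        res = welch_t(5.0, 0.3, 8, 5.0, 0.5, 10)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_equal_n_equal_sem_satterthwaite(self):
        n = 9
        res = welch_t(1.0, 0.4, n, 2.0, 0.4, n)
        assert res.v == pytest.approx(2 * (n - 1))

    def test_p_matches_quadrature_of_t_density(self):
        """Regularized-incomplete-beta p equals numeric integration of the
        t density over the rejection region."""
        for t, v in [(0.5, 3.0), (1.7, 5.5), (2.9, 12.0), (4.2, 30.0)]:
            dens = lambda u: stats.t.pdf(u, v)
            tail, _ = integrate.quad(dens, t, np.inf)
            assert t_sf_two_sided(t, v) == pytest.approx(2 * tail, abs=1e-10)

    def test_welch_matches_scipy_from_raw_samples(self, rng):
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.8, 2, 7)
        res = welch_t(a.mean(), a.std(ddof=1) / np.sqrt(a.size), a.size,
                      b.mean(), b.std(ddof=1) / np.sqrt(b.size), b.size)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_sems_rejected(self):
        with pytest.raises(DegenerateSampleError):
            welch_t(1.0, 0.0, 5, 2.0, 0.0, 5)


class TestWelchDoubleDiff:
    def test_equal_differences_give_p_one(self):
        res = welch_double_diff(2.0, 0.2, 6, 1.0, 0.2, 6, 3.0, 0.3, 6, 2.0, 0.3, 6)
        assert res.t == 0.0
        assert res.p == 1.0

    def test_reduces_to_welch_t(self):
        """Point-mass third/fourth samples (zero SEM, equal means) leave
        exactly the two-sample Welch test."""
        two = welch_t(1.3, 0.2, 8, 0.9, 0.25, 6)
        four = welch_double_diff(1.3, 0.2, 8, 0.9, 0.25, 6,
                                 0.0, 0.0, 5, 0.0, 0.0, 5)
        assert four.t == pytest.approx(two.t, rel=1e-12)
        assert four.v == pytest.approx(two.v, rel=1e-12)
        assert four.p == pytest.approx(two.p, rel=1e-12)

    def test_all_zero_sems_rejected(self):
        with pytest.raises(DegenerateSampleError):
            welch_double_diff(1, 0, 5, 2, 0, 5, 3, 0, 5, 4, 0, 5)


class TestCorrelations:
    def test_perfectly_increasing(self):
        res = correlations([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)

    def test_strictly_decreasing_spearman(self):
        res = correlations([1.0, 2.0, 3.0], [9.0, 4.0, 1.0])
        assert res.spearman_rho == pytest.approx(-1.0)

    def test_matches_scipy_t_transform(self, rng):
        a = rng.normal(size=15)
        b = 0.5 * a + rng.normal(size=15)
        res = correlations(a, b)
        pr = stats.pearsonr(a, b)
        sr = stats.spearmanr(a, b)
        assert res.pearson_r == pytest.approx(pr.statistic, rel=1e-12)
        assert res.pearson_p == pytest.approx(pr.pvalue, rel=1e-8)
        assert res.spearman_rho == pytest.approx(sr.statistic, rel=1e-12)
        assert res.spearman_p == pytest.approx(sr.pvalue, rel=1e-6)

    def test_p_matches_permutation_oracle(self, rng):
        a = rng.normal(size=12)
        b = 0.8 * a + rng.normal(size=12)
        res = correlations(a, b)
        n_perm = 4000
        null = np.empty(n_perm)
        for k in range(n_perm):
            bp = rng.permutation(b)
            null[k] = np.corrcoef(a, bp)[0, 1]
        p_perm = np.mean(np.abs(null) >= abs(res.pearson_r))
        se = np.sqrt(max(p_perm, 1 / n_perm) * (1 - p_perm) / n_perm)
        assert abs(res.pearson_p - p_perm) < 4 * se + 0.02

    def test_ties_use_average_ranks(self):
        res = correlations([1.0, 2.0, 2.0, 3.0], [1.0, 2.5, 2.5, 4.0])
        ref = stats.spearmanr([1.0, 2.0, 2.0, 3.0], [1.0, 2.5, 2.5, 4.0])
        assert res.spearman_rho == pytest.approx(ref.statistic, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSampleError):
            correlations([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


@given(st.integers(0, 2**16))
def test_p_values_in_unit_interval(seed):
    r = np.random.default_rng(seed)
    n = int(r.integers(3, 12))
    x, y = r.lognormal(0, 0.5, n), r.lognormal(0.2, 0.5, n)
    assert 0.0 <= paired_t(PairedSample(x, y)) <= 1.0
    w = welch_t(x.mean(), x.std(ddof=1) / np.sqrt(n), n,
                y.mean(), y.std(ddof=1) / np.sqrt(n), n)
    assert 0.0 <= w.p <= 1.0


def test_generated_samples_recover_ratio():
    sample, _ = synth.gen_paired_samples(10, 1.34, cv=0.0, seed=7)
    est = PairedRatioModel(sample).fit()
    assert est.r_c == pytest.approx(1.34, rel=1e-12)
    assert est.s_c == pytest.approx(0.0, abs=1e-10)


def test_pool_level_arithmetic():
    assert normalized_pool_level(35.0, [20.0, 23.0]) == pytest.approx(35 / 43)
    with pytest.raises(ValueError):
        normalized_pool_level(1.0, 0.0)
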