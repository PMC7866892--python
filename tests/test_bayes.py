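"""Bayes-factor engine: oracle agreement, limits, map semantics, thresholds."""

import numpy as np
import pytest
from scipy import integrate, stats

from bfmap import (
    CauchyPrior,
    bf10_one_sample,
    bf10_t,
    bf_map,
    corrected_default_scale,
    threshold_bf,
)
from bfmap.bayes import CORRECTION_RULES, _bf10_one_sided_t

from conftest import stack_from_samples


def bf10_oracle_mpmath(t, n, sigma):
    """High-precision oracle: adaptive quadrature of the g-mixture integral.

    Independent of the implementation path: integrates in g (not log g)
    with mpmath's adaptive rule at 40 significant digits.
    """
    import mpmath as mp

    mp.mp.dps = 40
    t_ = mp.mpf(t)
    n_ = mp.mpf(n)
    nu = n_ - 1
    s2 = mp.mpf(sigma) ** 2

    def integrand(g):
        if g <= 0:
            return mp.mpf(0)
        pg = (
            mp.sqrt(s2 / 2)
            / mp.gamma(mp.mpf(1) / 2)
            * g ** mp.mpf(-1.5)
            * mp.e ** (-s2 / (2 * g))
        )
        f = (1 + n_ * g) ** mp.mpf(-0.5) * (
            1 + t_**2 / ((1 + n_ * g) * nu)
        ) ** (-(nu + 1) / 2)
        return pg * f

    pts = [0, s2 / 100, s2, 100 * s2, max(float(s2), t * t / n + 1), mp.inf]
    m1 = mp.quad(integrand, sorted(set(pts)))
    m0 = (1 + t_**2 / nu) ** (-(nu + 1) / 2)
    return float(m1 / m0)


def bf10_oracle_nct(t, n, sigma):
    """Second independent oracle: delta-space integral of the noncentral-t
    density against the Cauchy prior, with scipy's adaptive quadrature."""
    nu = n - 1
    sq = np.sqrt(n)
    m0 = stats.t.pdf(t, nu)

    def integrand(d):
        # scaled by the null density so the integral is the BF itself,
        # keeping quad's absolute tolerance meaningful
        return stats.nct.pdf(t, nu, d * sq) / m0 * stats.cauchy.pdf(d, 0.0, sigma)

    peak = t / sq
    brk = sorted({-np.inf, -10 * sigma, 0.0, 10 * sigma, peak - 5, peak, peak + 5, np.inf})
    return sum(
        integrate.quad(integrand, lo, hi, limit=500)[0]
        for lo, hi in zip(brk[:-1], brk[1:])
    )


class TestAgainstOracles:
    @pytest.mark.parametrize("n", [8, 12, 16, 20])
    @pytest.mark.parametrize("sigma", [0.01, 0.1, 0.707, 2.0])
    def test_grid_against_mpmath(self, n, sigma):
        for t in (0.0, 1.0, 2.0, 3.0, 5.0):
            got = bf10_t(t, n, sigma)
            want = bf10_oracle_mpmath(t, n, sigma)
            assert got == pytest.approx(want, rel=1e-6)

    @pytest.mark.parametrize(
        "t, n, sigma",
        [(3.0, 20, 0.707), (9.0, 20, 3.17e-4), (15.0, 8, 1e-4), (2.0, 12, 2.0)],
    )
    def test_spot_checks_against_nct_route(self, t, n, sigma):
        # entirely different integration variable and library code path
        assert bf10_t(t, n, sigma) == pytest.approx(
            bf10_oracle_nct(t, n, sigma), rel=1e-6
        )

    def test_reference_case(self):
        # conventional default-prior case, frozen from the oracles
        assert bf10_t(3.0, 20, 0.707) == pytest.approx(6.618947618580, rel=1e-9)


class TestLimits:
    def test_null_data_cannot_favor_h1(self):
        for n in (8, 20):
            assert bf10_t(0.0, n, 0.707) < 1.0

    def test_vanishing_scale_gives_unit_bf(self):
        # prior collapses onto the null: models become indistinguishable
        for t in (0.0, 2.0, 5.0):
            assert bf10_t(t, 20, 1e-8) == pytest.approx(1.0, abs=1e-4)

    def test_huge_scale_kills_h1(self):
        assert bf10_t(3.0, 20, 1e6) < 1e-3

    def test_even_and_monotone_in_abs_t(self):
        tg = np.linspace(0.0, 12.0, 49)
        for sigma in (0.01, 0.707):
            up = bf10_t(tg, 16, sigma)
            down = bf10_t(-tg, 16, sigma)
            assert np.allclose(up, down, rtol=1e-12)
            assert np.all(np.diff(up) > 0)

    def test_large_t_stays_finite(self):
        vals = bf10_t(np.array([50.0, 200.0, 2000.0]), 12, 0.707)
        assert np.all(np.isfinite(vals)) and np.all(np.diff(vals) > 0)


class TestOneSample:
    def test_matches_t_statistic_path(self, rng):
        x = rng.normal(0.4, 1.0, size=14)
        t = x.mean() / (x.std(ddof=1) / np.sqrt(x.size))
        assert bf10_one_sample(x, CauchyPrior(0.707)) == pytest.approx(
            bf10_t(t, x.size, 0.707), rel=1e-14
        )

    def test_symmetric_sample_is_null(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])  # t = 0
        assert bf10_one_sample(x, CauchyPrior(0.707)) < 1.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            bf10_one_sample(np.ones(6), CauchyPrior(0.707))

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bf10_one_sample(np.array([1.0]), CauchyPrior(0.707))

    def test_one_sided_halves_recombine(self):
        # the two half-Cauchy BFs average to the two-sided BF
        x = np.array([0.1, 0.9, 0.4, 0.7, 0.2, 0.6, 0.5, 0.3])
        two = bf10_one_sample(x, CauchyPrior(0.707), sides="two")
        up = bf10_one_sample(x, CauchyPrior(0.707), sides="greater")
        down = bf10_one_sample(x, CauchyPrior(0.707), sides="less")
        assert 0.5 * (up + down) == pytest.approx(two, rel=1e-6)
        assert up > down  # positive sample favors the positive tail


class TestBFMap:
    def test_equals_scalar_calls(self, rng):
        samples = rng.normal(0.3, 1.0, size=(10, 6))
        stack = stack_from_samples(samples)
        bm = bf_map(stack, CauchyPrior(0.2))
        flat = bm.bf10.ravel()
        for v in range(6):
            assert flat[v] == pytest.approx(
                bf10_one_sample(samples[:, v], CauchyPrior(0.2)), rel=1e-12
            )

    def test_constant_voxelwise_sample(self, rng):
        col = rng.normal(0.5, 1.0, size=8)
        samples = np.tile(col[:, None], (1, 5))
        bm = bf_map(stack_from_samples(samples), CauchyPrior(0.707))
        expected = bf10_one_sample(col, CauchyPrior(0.707))
        assert np.allclose(bm.bf10.ravel(), expected, rtol=1e-12)

    def test_subject_order_irrelevant(self, rng):
        samples = rng.normal(0.0, 1.0, size=(12, 7))
        perm = rng.permutation(12)
        a = bf_map(stack_from_samples(samples), CauchyPrior(0.707))
        b = bf_map(stack_from_samples(samples[perm]), CauchyPrior(0.707))
        assert np.array_equal(a.bf10, b.bf10)

    def test_zero_variance_voxel_flagged_not_fatal(self, rng):
        samples = rng.normal(0.0, 1.0, size=(8, 4))
        samples[:, 2] = 1.5
        with pytest.warns(UserWarning, match="zero variance"):
            bm = bf_map(stack_from_samples(samples), CauchyPrior(0.707))
        assert bm.n_excluded == 1
        assert np.isnan(bm.bf10.ravel()[2])
        assert np.isfinite(np.delete(bm.bf10.ravel(), 2)).all()


class TestThreshold:
    def test_inclusive_at_cutoff(self):
        bm = _toy_bfmap(np.array([3.0, 3.0, 3.0]))
        assert threshold_bf(bm, 3.0).mask.sum() == 3

    def test_just_below_cutoff(self):
        bm = _toy_bfmap(np.array([2.999, 2.999]))
        assert threshold_bf(bm, 3.0).mask.sum() == 0

    def test_mixed_values(self):
        bm = _toy_bfmap(np.array([1.0, 3.0, 10.0]))
        assert threshold_bf(bm, 3.0).mask.ravel().tolist() == [0, 1, 1]

    def test_monotone_and_idempotent_in_cutoff(self, rng):
        bm = _toy_bfmap(rng.lognormal(0.5, 1.5, size=50))
        loose = threshold_bf(bm, 2.0).mask.astype(bool)
        strict = threshold_bf(bm, 6.0).mask.astype(bool)
        assert np.all(strict <= loose)  # stricter cutoff is a subset
        assert threshold_bf(bm, 2.0).mask.tolist() == loose.astype(np.uint8).tolist()

    def test_bad_cutoff(self):
        with pytest.raises(ValueError):
            threshold_bf(_toy_bfmap(np.array([1.0])), 0.0)

    def test_rule_recorded(self):
        out = threshold_bf(_toy_bfmap(np.array([5.0])), 3.0)
        assert "3" in out.rule


def _toy_bfmap(values):
    from bfmap.bayes import BFMap

    values = np.asarray(values, dtype=float).reshape(-1, 1, 1)
    return BFMap(
        bf10=values,
        prior=CauchyPrior(0.707),
        n=10,
        mask=np.ones(values.shape, dtype=bool),
    )


class TestCorrectedDefaultScale:
    def test_single_test_is_uncorrected(self):
        assert corrected_default_scale(1) == pytest.approx(0.707, abs=5e-4)
        assert corrected_default_scale(1, sigma0=0.3) == pytest.approx(0.3)

    def test_monotone_in_test_count(self):
        for rule in CORRECTION_RULES:
            counts = [1, 10, 1000, 48000, 10**5]
            vals = [corrected_default_scale(m, rule=rule) for m in counts]
            assert np.all(np.diff(vals) >= 0)

    def test_default_rule_closed_form(self):
        m = 10**5
        assert corrected_default_scale(m) == pytest.approx(
            0.707106781 * np.sqrt(m), rel=1e-9
        )

    def test_quantile_rule_closed_form(self):
        m = 10**5
        want = 0.7071067811865476 * np.tan(np.pi * (0.5 - 0.25 / m))
        got = corrected_default_scale(m, rule="bonferroni-quantile")
        assert got == pytest.approx(want, rel=1e-12)

    def test_unknown_rule(self):
        with pytest.raises(ValueError, match="rule"):
            corrected_default_scale(10, rule="nope")


class TestOneSidedScalar:
    def test_sign_sensitivity(self):
        up = _bf10_one_sided_t(2.5, 16, 0.707, tail="greater")
        down = _bf10_one_sided_t(2.5, 16, 0.707, tail="less")
        assert up > bf10_t(2.5, 16, 0.707) > down
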