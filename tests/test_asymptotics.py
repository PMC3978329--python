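"""Closed-form L1 / scaled-J2 power, sample-size and type-I calculators.

The frozen regression values below were recomputed here with direct scipy
arithmetic (independent of the module's code path) and cross-checked by
binomial Monte-Carlo at the tolerances the normal approximation supports.
"""
import math
import warnings

import numpy as np
import pytest
from scipy import stats as sps

from genoerr import (DesignSpec, ErrorRates, InfeasibleDesignError,
                     SmallCountWarning, j2_inflated_alpha, j2_power,
                     j2_sample_size_ratio, l1_inflated_alpha, l1_power,
                     l1_sample_size, perturbed_maf)

pytestmark = pytest.mark.filterwarnings("ignore::genoerr.SmallCountWarning")


def _design(f_case, f_control, errors=None, n=1000, **kw):
    f_case = np.atleast_1d(f_case)
    if errors is None:
        errors = ErrorRates.none(len(f_case))
    return DesignSpec(f_case=f_case, f_control=np.atleast_1d(f_control),
                      errors=errors, n_cases=n, n_controls=n, **kw)


# the m=1 reference design: f 0.001 -> 0.003, N+ = N- = 1000
REF = dict(f_case=[0.003], f_control=[0.001])


class TestL1Power:
    def test_null_design_size_equals_alpha(self):
        d = _design([0.001], [0.001])
        assert l1_power(d).power == pytest.approx(0.05, abs=1e-12)

    def test_reference_design_value(self):
        """Direct transcription of the recipe: C = z_.95 sqrt(var_H0),
        z_b = (C - mu)/sqrt(var_HA), power = 1 - Phi(z_b)."""
        var_h0 = 2 * 0.001 * 0.999 / 2000
        c = sps.norm.ppf(0.95) * math.sqrt(var_h0)
        var_ha = (0.003 * 0.997 + 0.001 * 0.999) / 2000
        expected = sps.norm.sf((c - 0.002) / math.sqrt(var_ha))
        r = l1_power(_design(**REF))
        assert r.power == pytest.approx(expected, abs=1e-12)
        assert r.power == pytest.approx(0.599488, abs=1e-6)

    def test_reference_design_monte_carlo(self, rng):
        """Binomial MC of the one-sided test with the analytic critical
        value; agreement limited by the normal approximation at ~2-6
        expected alleles (the prediction degrades at very low MAF)."""
        r = l1_power(_design(**REF))
        reps = 400_000
        d = (rng.binomial(2000, 0.003, reps) - rng.binomial(2000, 0.001, reps)) / 2000
        assert (d > r.critical_value).mean() == pytest.approx(r.power, abs=0.05)

    def test_nondifferential_errors_reduce_power(self):
        clean = l1_power(_design(**REF)).power
        noisy = l1_power(_design(
            **REF, errors=ErrorRates.nondifferential(0.01, 0.0, m=1))).power
        assert noisy < clean

    def test_small_count_warning_fires(self):
        with pytest.warns(SmallCountWarning):
            l1_power(_design([0.0005], [0.0001]))


class TestL1SampleSize:
    def test_no_errors_ratio_one(self):
        r = l1_sample_size(_design(**REF))
        assert r.sample_size_ratio == pytest.approx(1.0)

    def test_reference_value(self):
        """N+ for 80% power: ((z_.95 sqrt(t_H0) + z_.8 sqrt(t_HA))/mu)^2."""
        t_h0 = 0.001 * 0.999  # (f(1-f) + f(1-f)/k)/2 with k=1
        t_ha = 0.5 * (0.003 * 0.997 + 0.001 * 0.999)
        expected = ((sps.norm.ppf(0.95) * math.sqrt(t_h0)
                     + sps.norm.ppf(0.8) * math.sqrt(t_ha)) / 0.002) ** 2
        r = l1_sample_size(_design(**REF))
        assert r.required_n_cases == pytest.approx(expected, rel=1e-12)
        assert r.required_n_cases == pytest.approx(2006.15, abs=0.01)
        assert r.required_n_cases_ceil == 2007

    @pytest.mark.parametrize("errors", [
        None,
        ErrorRates.nondifferential(0.01, 0.1, m=1),
        ErrorRates.nondifferential(0.05, 0.5, m=1),
    ])
    def test_power_roundtrip(self, errors):
        """l1_power at the returned N+* reproduces target_power to 1e-6."""
        d = _design(**REF, errors=errors or ErrorRates.none(1),
                    target_power=0.8)
        n_star = l1_sample_size(d).required_n_cases
        assert l1_power(d.with_n_cases(n_star)).power == pytest.approx(
            0.8, abs=1e-6)

    def test_errors_inflate_required_n(self):
        base = l1_sample_size(_design(**REF)).required_n_cases
        noisy = l1_sample_size(_design(
            **REF, errors=ErrorRates.nondifferential(0.01, 0.1, m=1)))
        assert noisy.required_n_cases > base
        assert noisy.sample_size_ratio > 1.0

    def test_cancelled_effects_rejected(self):
        d = _design([0.003, 0.001], [0.001, 0.003])
        with pytest.raises(InfeasibleDesignError):
            l1_sample_size(d)


class TestL1InflatedAlpha:
    def test_reference_value(self):
        """Differential eps01 0.012 (cases) vs 0.010 (controls) at
        f = 0.001: alpha* ~ 0.541 (error-free C convention)."""
        er = ErrorRates(eps01_case=[0.012], eps10_case=[0.0],
                        eps01_control=[0.010], eps10_control=[0.0])
        r = l1_inflated_alpha(_design([0.001], [0.001], errors=er))
        fc, fk = perturbed_maf(0.001, 0.012, 0.0), perturbed_maf(0.001, 0.010, 0.0)
        var = (fc * (1 - fc) + fk * (1 - fk)) / 2000
        c = sps.norm.ppf(0.95) * math.sqrt(2 * 0.001 * 0.999 / 2000)
        expected = sps.norm.sf((c - (fc - fk)) / math.sqrt(var))
        assert r.inflated_alpha == pytest.approx(expected, abs=1e-12)
        assert r.inflated_alpha == pytest.approx(0.5410, abs=5e-4)

    def test_reference_value_monte_carlo(self, rng):
        er = ErrorRates(eps01_case=[0.012], eps10_case=[0.0],
                        eps01_control=[0.010], eps10_control=[0.0])
        r = l1_inflated_alpha(_design([0.001], [0.001], errors=er))
        fc, fk = perturbed_maf(0.001, 0.012, 0.0), perturbed_maf(0.001, 0.010, 0.0)
        reps = 300_000
        d = (rng.binomial(2000, fc, reps) - rng.binomial(2000, fk, reps)) / 2000
        assert (d > r.critical_value).mean() == pytest.approx(
            r.inflated_alpha, abs=0.02)

    def test_nondifferential_conventions(self):
        """Under equal case/control rates: alpha* = alpha exactly with the
        perturbed-null convention (as for the permutation test); the
        error-free-C convention exceeds alpha via variance inflation."""
        er = ErrorRates.nondifferential(0.01, 0.1, m=1)
        d = _design([0.001], [0.001], errors=er)
        assert l1_inflated_alpha(d, null_variance="perturbed").inflated_alpha \
            == pytest.approx(0.05, abs=1e-12)
        assert l1_inflated_alpha(d, null_variance="error_free").inflated_alpha > 0.05

    def test_swap_symmetry(self):
        """Swapping case and control rates (k=1) mirrors alpha* in the
        sign of mu*: z* maps to (C + mu*)/sigma*."""
        er = ErrorRates(eps01_case=[0.012], eps10_case=[0.0],
                        eps01_control=[0.010], eps10_control=[0.0])
        sw = ErrorRates(eps01_case=[0.010], eps10_case=[0.0],
                        eps01_control=[0.012], eps10_control=[0.0])
        a = l1_inflated_alpha(_design([0.001], [0.001], errors=er))
        b = l1_inflated_alpha(_design([0.001], [0.001], errors=sw))
        z_mirror = (a.critical_value + a.mean) / math.sqrt(a.variance)
        assert b.inflated_alpha == pytest.approx(float(sps.norm.sf(z_mirror)))

    def test_alternative_design_rejected(self):
        with pytest.raises(ValueError):
            l1_inflated_alpha(_design([0.003], [0.001]))


class TestJ2Power:
    def test_zero_noncentrality_gives_alpha(self):
        d = _design([0.001], [0.001])
        r = j2_power(d)
        assert r.noncentrality == pytest.approx(0.0)
        assert r.power == pytest.approx(0.05, abs=1e-12)

    def test_reference_value(self):
        """lambda = mu^2/sigma2 = 2.005; power = P(chi2_{1,lam} > 3.8415),
        equal to Phi(-z + sqrt(lam)) + Phi(-z - sqrt(lam)) at m=1."""
        var = (0.003 * 0.997 + 0.001 * 0.999) / 2000
        lam = 0.002 ** 2 / var
        z = sps.norm.ppf(0.975)
        expected = (sps.norm.cdf(-z + math.sqrt(lam))
                    + sps.norm.cdf(-z - math.sqrt(lam)))
        r = j2_power(_design(**REF))
        assert r.noncentrality == pytest.approx(lam, rel=1e-12)
        assert r.power == pytest.approx(expected, abs=1e-9)
        assert r.power == pytest.approx(0.293596, abs=1e-6)

    def test_noncentrality_shrinkage_identity(self):
        """Non-differential errors shrink each site's lambda by exactly
        (1 - e10 - e01)^2 (sigma2/sigma*2)."""
        e01, e10 = 0.01, 0.1
        d0 = _design(**REF)
        d1 = _design(**REF, errors=ErrorRates.nondifferential(e01, e10, m=1))
        lam0, lam1 = j2_power(d0).noncentrality, j2_power(d1).noncentrality
        fc = perturbed_maf(0.003, e01, e10)
        fk = perturbed_maf(0.001, e01, e10)
        var0 = (0.003 * 0.997 + 0.001 * 0.999) / 2000
        var1 = (fc * (1 - fc) + fk * (1 - fk)) / 2000
        shrink = (1 - e10 - e01) ** 2 * (var0 / var1)
        assert lam1 == pytest.approx(shrink * lam0, rel=1e-12)
        assert lam1 < lam0

    def test_eps01_dominates_eps10_in_power_loss(self):
        """At equal rate x, eps01-only loses more power than eps10-only,
        across a grid of rare MAFs."""
        for f in (0.0001, 0.001, 0.01):
            base = _design([2 * f], [f])
            p0 = j2_power(base).power
            p01 = j2_power(_design([2 * f], [f],
                                   errors=ErrorRates.nondifferential(0.05, 0.0, m=1))).power
            p10 = j2_power(_design([2 * f], [f],
                                   errors=ErrorRates.nondifferential(0.0, 0.05, m=1))).power
            assert p0 - p01 > p0 - p10
            # same dominance for the burden test
            l0 = l1_power(base).power
            l01 = l1_power(_design([2 * f], [f],
                                   errors=ErrorRates.nondifferential(0.05, 0.0, m=1))).power
            l10 = l1_power(_design([2 * f], [f],
                                   errors=ErrorRates.nondifferential(0.0, 0.05, m=1))).power
            assert l0 - l01 > l0 - l10

    def test_relative_power_loss_grows_as_maf_falls(self):
        """Fixed error rates hit rarer variants harder: the retained
        noncentrality fraction lambda*/lambda falls monotonically with
        MAF, and the relative power loss is larger at the lower of two
        MAFs with non-trivial power."""
        er = lambda: ErrorRates.nondifferential(0.01, 0.1, m=1)
        retained, losses = [], []
        for f in (0.01, 0.001, 0.0001):
            clean = j2_power(_design([case(f)], [f], n=2000))
            noisy = j2_power(_design([case(f)], [f], n=2000, errors=er()))
            retained.append(noisy.noncentrality / clean.noncentrality)
            losses.append((clean.power - noisy.power) / clean.power)
        assert retained[0] > retained[1] > retained[2]
        assert losses[0] < losses[1]


def case(f, rr=3.0):
    return f * rr / (1 + f * (rr - 1))


class TestJ2SampleSize:
    def test_no_errors_ratio_one(self):
        assert j2_sample_size_ratio(_design(**REF)).sample_size_ratio \
            == pytest.approx(1.0)

    def test_matches_power_inversion(self):
        """The noncentrality-matching ratio agrees with numerically
        inverting j2_power to within 1%."""
        from scipy.optimize import brentq
        er = ErrorRates.nondifferential(0.01, 0.0, m=1)
        d = _design(**REF, errors=er)
        target = j2_power(_design(**REF)).power
        ratio = j2_sample_size_ratio(d).sample_size_ratio

        def gap(n):
            return j2_power(d.with_n_cases(n)).power - target

        n_inv = brentq(gap, 100, 10 ** 6, xtol=1e-6)
        assert ratio == pytest.approx(n_inv / 1000, rel=0.01)

    def test_homogeneous_in_effect_scale(self):
        """Scaling every mu by c leaves the ratio unchanged (here: no
        errors, any design has ratio exactly 1; with errors, doubling N
        leaves the ratio unchanged since mu, t are N-free)."""
        er = ErrorRates.nondifferential(0.01, 0.1, m=1)
        r1 = j2_sample_size_ratio(_design(**REF, errors=er, n=1000))
        r2 = j2_sample_size_ratio(_design(**REF, errors=er, n=4000))
        assert r1.sample_size_ratio == pytest.approx(r2.sample_size_ratio)

    def test_annihilated_effects_rejected(self):
        # errors wash the effect out entirely only if mu* = 0: force it
        # with f+ = f- (no effect at all, so the reference sum is 0 too)
        d = _design([0.001], [0.001],
                    errors=ErrorRates.nondifferential(0.01, 0.0, m=1))
        with pytest.raises(InfeasibleDesignError):
            j2_sample_size_ratio(d)


class TestJ2InflatedAlpha:
    def test_nondifferential_gives_alpha(self):
        er = ErrorRates.nondifferential(0.05, 0.5, m=2)
        d = _design([0.001, 0.01], [0.001, 0.01], errors=er)
        r = j2_inflated_alpha(d)
        assert r.noncentrality == pytest.approx(0.0)
        assert r.inflated_alpha == pytest.approx(0.05, abs=1e-12)

    def test_positive_noncentrality_inflates(self):
        er = ErrorRates.differential(0.01, 0.0, 1.2, m=8)
        d = _design([0.001] * 8, [0.001] * 8, errors=er)
        r = j2_inflated_alpha(d)
        assert r.noncentrality > 0
        assert r.inflated_alpha > 0.05

    def test_reference_monte_carlo(self, rng):
        """m=8, f=0.001, case eps01 = 1.2 x control 0.010: analytic
        alpha* matches MC of the scaled statistic (pooled plug-in
        scaling) within 4 SE."""
        er = ErrorRates.differential(0.01, 0.0, 1.2, m=8)
        d = _design([0.001] * 8, [0.001] * 8, errors=er)
        r = j2_inflated_alpha(d)
        fc = perturbed_maf(0.001, 0.012, 0.0)
        fk = perturbed_maf(0.001, 0.010, 0.0)
        reps = 100_000
        cp = rng.binomial(2000, fc, (reps, 8))
        cm = rng.binomial(2000, fk, (reps, 8))
        dd = (cp - cm) / 2000
        f_null = 0.5 * (fc + fk)
        s2 = f_null * (1 - f_null) / 1000
        stat = (dd ** 2 / s2).sum(axis=1)
        mc = (stat > sps.chi2.isf(0.05, 8)).mean()
        se = math.sqrt(mc * (1 - mc) / reps)
        assert r.inflated_alpha == pytest.approx(mc, abs=max(4 * se, 0.01))

    def test_inflation_grows_with_ratio_and_magnitude(self):
        """alpha* increases with |ratio - 1| (both directions) and with
        the error magnitude."""
        def astar(e01, ratio, m=8, f=0.001):
            er = ErrorRates.differential(e01, 0.0, ratio, m=m)
            return j2_inflated_alpha(
                _design([f] * m, [f] * m, errors=er)).inflated_alpha

        assert astar(0.01, 1.0) == pytest.approx(0.05, abs=1e-12)
        assert astar(0.01, 1.2) < astar(0.01, 1.5)
        assert astar(0.01, 1 / 1.2) < astar(0.01, 1 / 1.5)
        assert astar(0.01, 1 / 1.2) > 0.05
        assert astar(0.01, 1.2) < astar(0.05, 1.2)
        # same direction for the L1 calculator at ratios > 1
        def l1star(e01, ratio):
            er = ErrorRates.differential(e01, 0.0, ratio, m=8)
            return l1_inflated_alpha(
                _design([0.001] * 8, [0.001] * 8, errors=er)).inflated_alpha
        assert 0.05 < l1star(0.01, 1.2) < l1star(0.01, 1.5)
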