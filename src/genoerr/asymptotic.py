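"""Closed-form power, sample-size and type-I-inflation calculators.

Two statistics admit tractable large-sample distributions:

* **L1** (burden): ``L1 = sum_i D_i`` is approximately normal with mean
  ``sum_i mu_Di`` and variance ``sum_i sigma2_Di``.  Power against a
  one-sided alternative at level alpha uses the critical value
  ``C = z_{1-alpha} sqrt(sum sigma2_{Di,H0})`` and
  ``pi = 1 - Phi((C - sum mu*_{Di}) / sqrt(sum sigma*2_{Di}))``, where the
  starred moments are evaluated at the error-perturbed frequencies.

* **scaled J2**: ``sum_i (D_i / sigma_Di)^2`` is approximately noncentral
  chi-square with m degrees of freedom and noncentrality
  ``lambda = sum_i (mu_Di / sigma_Di)^2``; power is the noncentral upper
  tail beyond the central chi-square critical value.

Both calculators accept arbitrary differential or non-differential error
regimes; the required case sample size for L1 follows from inverting the
power equation with ``t_i = (f+(1-f+) + f-(1-f-)/k)/2`` and fixed
control:case ratio k, and for scaled J2 from matching noncentralities,
``N+*/N+ = sum(mu^2/t) / sum(mu*^2/t*)``.

The ``null_variance`` option controls which frequencies feed the null
critical value C of the L1 routines.  ``"perturbed"`` pushes the null
MAFs through each group's error rates before computing the null variance —
this is what any test calibrated on the observed (contaminated) data, in
particular the permutation test, implicitly does, and it is the
convention the sample-size derivation uses (t*_{i,H0}).  ``"error_free"``
fixes C at the uncontaminated nominal null.  Power and sample size
default to ``"perturbed"``: it keeps the size exactly at alpha under
non-differential errors and tracks permutation-based empirical power
closely even at large error rates.  ``l1_inflated_alpha`` defaults to
``"error_free"``: the question it answers is what happens to a test whose
critical value was calibrated on the error-free null when differential
errors contaminate the data.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as sps

from .errors import ErrorRates, perturbed_maf

__all__ = [
    "DesignSpec",
    "AsymptoticResult",
    "InfeasibleDesignError",
    "SmallCountWarning",
    "l1_power",
    "l1_sample_size",
    "l1_inflated_alpha",
    "j2_power",
    "j2_sample_size_ratio",
    "j2_inflated_alpha",
]

_NULL_VARIANCE_MODES = ("error_free", "perturbed")


class InfeasibleDesignError(ValueError):
    """Effects cancel exactly (sum of means zero); no finite design works."""


class SmallCountWarning(UserWarning):
    """Expected minor-allele counts below 5; normal approximation degrades."""


@dataclass(frozen=True)
class DesignSpec:
    """A study design for the analytic calculators.

    True (pre-error) case and control MAFs per site, the per-site error
    quadruples, sample sizes (floats allowed — the calculators treat N as
    continuous), the nominal level alpha and the target power.  The
    control:case ratio ``k = N-/N+`` is held fixed when resizing.
    """

    f_case: np.ndarray
    f_control: np.ndarray
    errors: ErrorRates
    n_cases: float
    n_controls: float
    alpha: float = 0.05
    target_power: float = 0.8

    def __post_init__(self) -> None:
        fc = np.atleast_1d(np.asarray(self.f_case, dtype=float))
        fk = np.atleast_1d(np.asarray(self.f_control, dtype=float))
        if fc.shape != fk.shape or fc.ndim != 1:
            raise ValueError("f_case and f_control must be equal-length vectors")
        if np.any((fc < 0) | (fc > 1)) or np.any((fk < 0) | (fk > 1)):
            raise ValueError("frequencies outside [0, 1]")
        object.__setattr__(self, "f_case", fc)
        object.__setattr__(self, "f_control", fk)
        if self.errors.m != fc.shape[0]:
            raise ValueError("error-rate vectors must match the number of sites")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0.0 < self.alpha < 1.0) or not (0.0 < self.target_power < 1.0):
            raise ValueError("alpha and target_power must lie in (0, 1)")

    @property
    def m(self) -> int:
        return self.f_case.shape[0]

    @property
    def k_ratio(self) -> float:
        return self.n_controls / self.n_cases

    def with_n_cases(self, n_cases: float) -> "DesignSpec":
        return DesignSpec(f_case=self.f_case, f_control=self.f_control,
                          errors=self.errors, n_cases=n_cases,
                          n_controls=self.k_ratio * n_cases,
                          alpha=self.alpha, target_power=self.target_power)


@dataclass(frozen=True)
class AsymptoticResult:
    """Prediction plus the intermediate quantities that produced it."""

    power: Optional[float] = None
    inflated_alpha: Optional[float] = None
    required_n_cases: Optional[float] = None
    required_n_cases_ceil: Optional[int] = None
    sample_size_ratio: Optional[float] = None
    critical_value: Optional[float] = None
    z_beta: Optional[float] = None
    noncentrality: Optional[float] = None
    mean: Optional[float] = None
    variance: Optional[float] = None


def _starred(design: DesignSpec) -> tuple[np.ndarray, np.ndarray]:
    """Error-perturbed (case, control) MAFs under the alternative."""
    fc = perturbed_maf(design.f_case, design.errors.eps01_case,
                       design.errors.eps10_case)
    fk = perturbed_maf(design.f_control, design.errors.eps01_control,
                       design.errors.eps10_control)
    return np.atleast_1d(fc), np.atleast_1d(fk)


def _null_freqs(design: DesignSpec, null_variance: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-group frequencies under H0 (f+ = f- = f_control), optionally
    pushed through each group's own error rates."""
    if null_variance not in _NULL_VARIANCE_MODES:
        raise ValueError(f"null_variance must be one of {_NULL_VARIANCE_MODES}")
    f0 = design.f_control
    if null_variance == "error_free":
        return f0, f0
    fc = perturbed_maf(f0, design.errors.eps01_case, design.errors.eps10_case)
    fk = perturbed_maf(f0, design.errors.eps01_control, design.errors.eps10_control)
    return np.atleast_1d(fc), np.atleast_1d(fk)


def _variance(fc: np.ndarray, fk: np.ndarray, n_cases: float,
              n_controls: float) -> np.ndarray:
    return (fc * (1.0 - fc) / (2.0 * n_cases)
            + fk * (1.0 - fk) / (2.0 * n_controls))


def _t_scale(fc: np.ndarray, fk: np.ndarray, k: float) -> np.ndarray:
    """t_i = (f+(1-f+) + f-(1-f-)/k) / 2, so sigma2_Di = t_i / N+."""
    return 0.5 * (fc * (1.0 - fc) + fk * (1.0 - fk) / k)


def _warn_small_counts(design: DesignSpec, fc: np.ndarray, fk: np.ndarray) -> None:
    counts = np.concatenate([2.0 * design.n_cases * fc,
                             2.0 * design.n_controls * fk])
    if np.any(counts < 5.0):
        warnings.warn(
            "expected minor-allele count below 5 at some site; the normal "
            "approximation (and hence these predictions) degrades at very "
            "low aggregate MAF", SmallCountWarning, stacklevel=3)


# -- L1 (burden) -------------------------------------------------------------

def l1_power(design: DesignSpec, null_variance: str = "perturbed") -> AsymptoticResult:
    """One-sided asymptotic power of the L1 burden test."""
    f0c, f0k = _null_freqs(design, null_variance)
    var_h0 = _variance(f0c, f0k, design.n_cases, design.n_controls).sum()
    if var_h0 <= 0:
        raise InfeasibleDesignError("zero null variance at every site")
    fc, fk = _starred(design)
    _warn_small_counts(design, fc, fk)
    mu = (fc - fk).sum()
    var_ha = _variance(fc, fk, design.n_cases, design.n_controls).sum()
    c = sps.norm.ppf(1.0 - design.alpha) * math.sqrt(var_h0)
    z_beta = (c - mu) / math.sqrt(var_ha)
    return AsymptoticResult(power=float(sps.norm.sf(z_beta)), critical_value=c,
                            z_beta=float(z_beta), mean=float(mu),
                            variance=float(var_ha))


def l1_sample_size(design: DesignSpec,
                   null_variance: str = "perturbed") -> AsymptoticResult:
    """Case sample size N+* giving the target power, and the inflation
    ratio relative to the same design without genotype errors.

    Uses the same null-variance convention as :func:`l1_power`, so
    evaluating ``l1_power`` at the returned N+* reproduces the target
    power exactly.
    """
    z_alpha = sps.norm.ppf(1.0 - design.alpha)
    z_beta = sps.norm.ppf(1.0 - design.target_power)
    k = design.k_ratio

    def _n_plus(fc_h0, fk_h0, fc_ha, fk_ha):
        mu = (fc_ha - fk_ha).sum()
        if mu == 0.0:
            raise InfeasibleDesignError(
                "case-control effects cancel exactly (sum of means is zero)")
        t_h0 = _t_scale(fc_h0, fk_h0, k).sum()
        t_ha = _t_scale(fc_ha, fk_ha, k).sum()
        return ((z_alpha * math.sqrt(t_h0) - z_beta * math.sqrt(t_ha)) / mu) ** 2

    f0c, f0k = _null_freqs(design, null_variance)
    fc, fk = _starred(design)
    n_star = _n_plus(f0c, f0k, fc, fk)
    # error-free reference design
    n_ref = _n_plus(design.f_control, design.f_control,
                    design.f_case, design.f_control)
    return AsymptoticResult(required_n_cases=float(n_star),
                            required_n_cases_ceil=int(math.ceil(n_star)),
                            sample_size_ratio=float(n_star / n_ref))


def l1_inflated_alpha(design: DesignSpec,
                      null_variance: str = "error_free") -> AsymptoticResult:
    """Realized size of the nominal-alpha L1 test under a null design with
    (possibly differential) genotype errors.

    The critical value C comes from the error-free null (default); the
    realized size evaluates the error-contaminated null moments against
    it:  ``alpha* = 1 - Phi((C - sum mu*_{H0}) / sqrt(sum sigma*2_{H0}))``.
    """
    if not np.allclose(design.f_case, design.f_control):
        raise ValueError("inflated-alpha calculation requires a null design "
                         "(f_case == f_control at every site)")
    f0c, f0k = _null_freqs(design, null_variance)
    var_h0 = _variance(f0c, f0k, design.n_cases, design.n_controls).sum()
    if var_h0 <= 0:
        raise InfeasibleDesignError("zero null variance at every site")
    c = sps.norm.ppf(1.0 - design.alpha) * math.sqrt(var_h0)
    fc, fk = _starred(design)  # contaminated null frequencies (f+ = f-)
    _warn_small_counts(design, fc, fk)
    mu = (fc - fk).sum()
    var = _variance(fc, fk, design.n_cases, design.n_controls).sum()
    z = (c - mu) / math.sqrt(var)
    return AsymptoticResult(inflated_alpha=float(sps.norm.sf(z)),
                            critical_value=c, z_beta=float(z),
                            mean=float(mu), variance=float(var))


# -- scaled J2 ---------------------------------------------------------------

def _noncentrality(fc: np.ndarray, fk: np.ndarray, n_cases: float,
                   n_controls: float) -> float:
    mu = fc - fk
    sigma2 = _variance(fc, fk, n_cases, n_controls)
    if np.any(sigma2 <= 0):
        raise InfeasibleDesignError(
            "degenerate site (zero variance) in scaled-J2 design")
    return float(np.sum(mu * mu / sigma2))


def _ncx2_sf(c: float, df: int, lam: float) -> float:
    if lam == 0.0:
        return float(sps.chi2.sf(c, df))
    return float(sps.ncx2.sf(c, df, lam))


def j2_power(design: DesignSpec) -> AsymptoticResult:
    """Asymptotic power of the variance-scaled J2 statistic.

    lambda* = sum (mu*_Di / sigma*_Di)^2 from the error-perturbed
    frequencies; power = P(chi2_{m,lambda*} > chi2_{m,alpha}).
    """
    fc, fk = _starred(design)
    _warn_small_counts(design, fc, fk)
    lam = _noncentrality(fc, fk, design.n_cases, design.n_controls)
    c = float(sps.chi2.isf(design.alpha, design.m))
    return AsymptoticResult(power=_ncx2_sf(c, design.m, lam),
                            critical_value=c, noncentrality=lam)


def j2_sample_size_ratio(design: DesignSpec) -> AsymptoticResult:
    """Sample-size inflation N+*/N+ that restores the error-free
    noncentrality:  sum(mu^2/t) / sum(mu*^2/t*)."""
    k = design.k_ratio
    mu = design.f_case - design.f_control
    t = _t_scale(design.f_case, design.f_control, k)
    fc, fk = _starred(design)
    mu_star = fc - fk
    t_star = _t_scale(fc, fk, k)
    if np.any(t <= 0) or np.any(t_star <= 0):
        raise InfeasibleDesignError("degenerate site (zero variance scale)")
    denom = np.sum(mu_star * mu_star / t_star)
    if denom == 0.0:
        raise InfeasibleDesignError("errors annihilate every effect")
    ratio = float(np.sum(mu * mu / t) / denom)
    n_star = ratio * design.n_cases
    return AsymptoticResult(sample_size_ratio=ratio,
                            required_n_cases=float(n_star),
                            required_n_cases_ceil=int(math.ceil(n_star)))


def j2_inflated_alpha(design: DesignSpec) -> AsymptoticResult:
    """Realized size of scaled J2 under a null design with differential
    errors: alpha* = P(chi2_{m,lambda*} > chi2_{m,alpha}) >= alpha, with
    equality iff lambda* = 0 (e.g. non-differential errors)."""
    if not np.allclose(design.f_case, design.f_control):
        raise ValueError("inflated-alpha calculation requires a null design")
    null = design.f_control
    fc = perturbed_maf(null, design.errors.eps01_case, design.errors.eps10_case)
    fk = perturbed_maf(null, design.errors.eps01_control,
                       design.errors.eps10_control)
    fc, fk = np.atleast_1d(fc), np.atleast_1d(fk)
    _warn_small_counts(design, fc, fk)
    lam = _noncentrality(fc, fk, design.n_cases, design.n_controls)
    c = float(sps.chi2.isf(design.alpha, design.m))
    return AsymptoticResult(inflated_alpha=_ncx2_sf(c, design.m, lam),
                            critical_value=c, noncentrality=lam)
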