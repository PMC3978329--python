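"""Geometric length/joint statistics for gene-based rare-variant tests.

Most gene-based rare-variant tests of case-control association can be
written in one of two generic forms built from the per-variant minor-allele
counts ``c+_i`` (cases) and ``c-_i`` (controls):

* the *length* (burden / collapsing) statistic

  ``L_p = ||c+/(2N+)||_p - ||c-/(2N-)||_p``

  compares the L^p norms of the case and control minor-allele-frequency
  vectors — it is sensitive to differences in aggregate frequency;

* the *joint* (variance-component style) statistic

  ``J_p = ||c+/(2N+) - c-/(2N-)||_p``

  aggregates per-variant frequency differences ``D_i`` and is sensitive to
  both the magnitude and the direction of the case-control differences.

Setting p to 1 recovers the classical burden test; p = 2 with per-site
variance scaling gives a SKAT-like variance-component statistic.  For
p = infinity both families reduce to per-group (length) or per-site (joint)
maxima; the joint infinity statistic is the *signed* maximum difference
``max_i D_i`` by default.

Under the null hypothesis f+_i = f-_i for all i, with counts binomial and
sites unlinked, the scaled difference ``D_i = c+_i/(2N+) - c-_i/(2N-)`` has

    mean      mu_Di    = f+_i - f-_i
    variance  sigma2_Di = f+_i(1-f+_i)/(2N+) + f-_i(1-f-_i)/(2N-)

and the variance-scaled joint statistic ``sum_i D_i^2 / sigma2_Di`` is
asymptotically chi-square with m degrees of freedom.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "CohortCounts",
    "FrequencyPair",
    "DiffMoments",
    "TestResult",
    "DegenerateSiteError",
    "STATISTICS",
    "length_statistic",
    "joint_statistic",
    "diff_moments",
    "scaled_joint2",
    "length_from_freqs",
    "joint_from_freqs",
    "evaluate_statistic",
]

#: the eight (family, norm) combinations used throughout the simulation study
STATISTICS: tuple[tuple[str, float], ...] = (
    ("length", 1), ("length", 2), ("length", 4), ("length", math.inf),
    ("joint", 1), ("joint", 2), ("joint", 4), ("joint", math.inf),
)


class DegenerateSiteError(ValueError):
    """A site has zero null variance (f in {0, 1}); drop or merge it."""


def _check_norm(p: float) -> float:
    p = float(p)
    if not (p >= 1.0):  # also rejects NaN
        raise ValueError(f"norm p must satisfy p >= 1, got {p!r}")
    return p


@dataclass(frozen=True)
class CohortCounts:
    """Per-variant minor-allele counts in cases and controls.

    This is the sufficient statistic for every test in the family: ``m``
    variant sites, ``n_cases`` (N+) and ``n_controls`` (N-) diploid
    individuals, and count vectors with ``0 <= c_i <= 2N``.
    """

    n_cases: int
    n_controls: int
    case_counts: np.ndarray
    control_counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "case_counts",
                           np.asarray(self.case_counts, dtype=np.int64))
        object.__setattr__(self, "control_counts",
                           np.asarray(self.control_counts, dtype=np.int64))
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")
        if self.case_counts.ndim != 1 or self.control_counts.ndim != 1:
            raise ValueError("count vectors must be one-dimensional")
        if self.case_counts.shape != self.control_counts.shape:
            raise ValueError(
                f"mismatched count vectors: {self.case_counts.shape} cases "
                f"vs {self.control_counts.shape} controls")
        if np.any(self.case_counts < 0) or np.any(self.case_counts > 2 * self.n_cases):
            raise ValueError("case counts outside [0, 2*n_cases]")
        if np.any(self.control_counts < 0) or np.any(self.control_counts > 2 * self.n_controls):
            raise ValueError("control counts outside [0, 2*n_controls]")

    @property
    def m(self) -> int:
        return self.case_counts.shape[0]

    @property
    def case_freq(self) -> np.ndarray:
        """Per-site sample MAF in cases, c+_i / (2 N+)."""
        return self.case_counts / (2.0 * self.n_cases)

    @property
    def control_freq(self) -> np.ndarray:
        return self.control_counts / (2.0 * self.n_controls)

    @property
    def diff(self) -> np.ndarray:
        """Scaled count differences D_i."""
        return self.case_freq - self.control_freq


@dataclass(frozen=True)
class FrequencyPair:
    """True per-allele MAFs at one site: cases, controls, population."""

    f_case: float
    f_control: float
    f_pop: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("f_case", "f_control"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.f_pop is None:
            # low-prevalence approximation: population MAF ~= control MAF
            object.__setattr__(self, "f_pop", self.f_control)
        elif not (0.0 <= self.f_pop <= 1.0):
            raise ValueError(f"f_pop={self.f_pop} outside [0, 1]")


@dataclass(frozen=True)
class DiffMoments:
    """First two moments of the scaled count difference D_i."""

    mean: float
    variance: float

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")


@dataclass
class TestResult:
    """One evaluated statistic: family, norm, value, optional permutation p."""

    family: str
    norm: float
    value: float
    p_value: Optional[float] = None
    n_permutations: Optional[int] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.family not in ("length", "joint"):
            raise ValueError(f"family must be 'length' or 'joint', got {self.family!r}")
        _check_norm(self.norm)

    @property
    def label(self) -> str:
        p = "inf" if math.isinf(self.norm) else f"{self.norm:g}"
        return ("L" if self.family == "length" else "J") + p


# -- vectorized statistic kernels -------------------------------------------
#
# These operate on frequency arrays whose last axis indexes variant sites,
# so a (B, m) array of permuted frequencies yields B statistics in one call.

def _pnorm(x: np.ndarray, p: float, axis: int = -1) -> np.ndarray:
    if math.isinf(p):
        return np.max(np.abs(x), axis=axis)
    if p == 1:
        return np.sum(np.abs(x), axis=axis)
    return np.sum(np.abs(x) ** p, axis=axis) ** (1.0 / p)


def length_from_freqs(case_freq: np.ndarray, control_freq: np.ndarray,
                      norm: float, axis: int = -1) -> np.ndarray:
    """L_p from per-group MAF vectors; for p=inf the difference of maxima."""
    p = _check_norm(norm)
    if math.isinf(p):
        return np.max(case_freq, axis=axis) - np.max(control_freq, axis=axis)
    return _pnorm(case_freq, p, axis) - _pnorm(control_freq, p, axis)


def joint_from_freqs(case_freq: np.ndarray, control_freq: np.ndarray,
                     norm: float, axis: int = -1,
                     absolute_max: bool = False) -> np.ndarray:
    """J_p from per-group MAF vectors.

    For p=inf the default is the signed maximum difference ``max_i D_i``;
    ``absolute_max=True`` uses ``max_i |D_i|`` instead (useful when
    protective variants can make the extreme difference negative).
    """
    p = _check_norm(norm)
    d = np.asarray(case_freq) - np.asarray(control_freq)
    if math.isinf(p):
        if absolute_max:
            return np.max(np.abs(d), axis=axis)
        return np.max(d, axis=axis)
    return _pnorm(d, p, axis)


def evaluate_statistic(case_freq: np.ndarray, control_freq: np.ndarray,
                       family: str, norm: float, axis: int = -1) -> np.ndarray:
    if family == "length":
        return length_from_freqs(case_freq, control_freq, norm, axis)
    if family == "joint":
        return joint_from_freqs(case_freq, control_freq, norm, axis)
    raise ValueError(f"unknown statistic family {family!r}")


# -- public single-cohort operations ----------------------------------------

def length_statistic(counts: CohortCounts, norm: float) -> float:
    """General length (burden) statistic L_p; may be negative."""
    return float(length_from_freqs(counts.case_freq, counts.control_freq, norm))


def joint_statistic(counts: CohortCounts, norm: float,
                    absolute_max: bool = False) -> float:
    """General joint statistic J_p (>= 0 for finite p)."""
    return float(joint_from_freqs(counts.case_freq, counts.control_freq,
                                  norm, absolute_max=absolute_max))


def diff_moments(freqs: FrequencyPair, n_cases: int, n_controls: int) -> DiffMoments:
    """Mean and variance of D_i given true case/control MAFs.

    mu = f+ - f-;  sigma^2 = f+(1-f+)/(2N+) + f-(1-f-)/(2N-).
    """
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample sizes must be positive")
    fc, fk = freqs.f_case, freqs.f_control
    mean = fc - fk
    var = fc * (1.0 - fc) / (2.0 * n_cases) + fk * (1.0 - fk) / (2.0 * n_controls)
    return DiffMoments(mean=mean, variance=var)


def scaled_joint2(counts: CohortCounts, null_freq: np.ndarray) -> float:
    """Variance-scaled J_2^2 = sum_i D_i^2 / sigma2_Di, ~ chi^2_m under H0.

    ``null_freq`` supplies per-site null MAFs f_i (f+ = f- = f_i) from which
    the null variances are computed; any site with zero null variance
    (f_i in {0, 1}) raises :class:`DegenerateSiteError` — monomorphic sites
    must be dropped or merged before scaling.
    """
    f = np.asarray(null_freq, dtype=float)
    if f.shape != (counts.m,):
        raise ValueError(f"null_freq must have length m={counts.m}")
    if np.any((f < 0) | (f > 1)):
        raise ValueError("null frequencies outside [0, 1]")
    sigma2 = f * (1.0 - f) * (0.5 / counts.n_cases + 0.5 / counts.n_controls)
    if np.any(sigma2 <= 0):
        bad = np.nonzero(sigma2 <= 0)[0]
        raise DegenerateSiteError(
            f"zero null variance at site(s) {bad.tolist()}; drop or merge them")
    d = counts.diff
    return float(np.sum(d * d / sigma2))
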