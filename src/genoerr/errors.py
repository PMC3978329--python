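"""Allele-level genotype misclassification model.

Genotype callers make two kinds of per-allele mistakes at a biallelic site:

* ``eps01`` — a major allele is miscalled as the minor allele (this turns
  common homozygotes into apparent heterozygotes, the dominant error mode
  for rare variants because almost everyone is a common homozygote);
* ``eps10`` — a minor allele is miscalled as the major allele.

Each of a diploid individual's two alleles is misclassified independently,
so the error-perturbed MAF in a phenotype group is

    f* = f (1 - eps10) + (1 - f) eps01.

Errors are *non-differential* when cases and controls share the same rates
(the null f+ = f- is then preserved, but effect sizes shrink by the factor
``1 - eps10 - eps01``) and *differential* otherwise (spurious case-control
frequency differences appear even under the null).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np

from .stats import CohortCounts

__all__ = [
    "ErrorRates",
    "GenotypeMatrix",
    "perturbed_maf",
    "apply_errors",
    "expected_misclassifications",
    "mean_shrinkage",
]

SeedLike = Union[int, np.random.SeedSequence, None]


def _entropy_from(seed: SeedLike) -> int:
    """Collapse any accepted seed into one integer < 2**31."""
    if seed is None:
        seed = np.random.SeedSequence().entropy
    if isinstance(seed, np.random.SeedSequence):
        return int(seed.generate_state(1, np.uint32)[0] % (2 ** 31))
    return int(seed) % (2 ** 31)


def _substream(entropy: int, *key: int) -> np.random.Generator:
    """Deterministic substream for a (channel, group, site, ...) key.

    Streams are independent per key, so adding a variant site or another
    phenotype group never perturbs the draws of earlier sites.
    """
    ss = np.random.SeedSequence(entropy, spawn_key=tuple(int(k) for k in key))
    return np.random.Generator(np.random.PCG64(ss))


@dataclass(frozen=True)
class ErrorRates:
    """Per-site, per-group allele misclassification rates.

    Each field is a length-m vector: eps01 (major->minor) and eps10
    (minor->major) separately for cases and controls.  Rates live in
    [0, 1) with ``eps01 + eps10 < 1`` per group, which keeps the
    effect-size shrinkage factor ``1 - eps10 - eps01`` positive.
    """

    eps01_case: np.ndarray
    eps10_case: np.ndarray
    eps01_control: np.ndarray
    eps10_control: np.ndarray

    def __post_init__(self) -> None:
        arrays = {}
        for name in ("eps01_case", "eps10_case", "eps01_control", "eps10_control"):
            a = np.atleast_1d(np.asarray(getattr(self, name), dtype=float))
            if a.ndim != 1:
                raise ValueError(f"{name} must be a scalar or 1-D vector")
            arrays[name] = a
        m = max(a.shape[0] for a in arrays.values())
        for name, a in arrays.items():
            if a.shape[0] == 1 and m > 1:
                a = np.repeat(a, m)
            if a.shape[0] != m:
                raise ValueError("error-rate vectors have inconsistent lengths")
            if np.any((a < 0) | (a >= 1)):
                raise ValueError(f"{name} must lie in [0, 1)")
            object.__setattr__(self, name, a)
        if np.any(self.eps01_case + self.eps10_case >= 1) or \
           np.any(self.eps01_control + self.eps10_control >= 1):
            raise ValueError("eps01 + eps10 must be < 1 within each group")

    @classmethod
    def none(cls, m: int) -> "ErrorRates":
        z = np.zeros(m)
        return cls(z, z, z, z)

    @classmethod
    def nondifferential(cls, eps01, eps10, m: int = 1) -> "ErrorRates":
        e01 = np.broadcast_to(np.asarray(eps01, dtype=float), (m,)).copy()
        e10 = np.broadcast_to(np.asarray(eps10, dtype=float), (m,)).copy()
        return cls(e01, e10, e01, e10)

    @classmethod
    def differential(cls, eps01_control, eps10_control, ratio: float,
                     m: int = 1) -> "ErrorRates":
        """Case rates = ratio x control rates on both error channels."""
        e01 = np.broadcast_to(np.asarray(eps01_control, dtype=float), (m,)).copy()
        e10 = np.broadcast_to(np.asarray(eps10_control, dtype=float), (m,)).copy()
        return cls(ratio * e01, ratio * e10, e01, e10)

    @property
    def m(self) -> int:
        return self.eps01_case.shape[0]

    @property
    def is_differential(self) -> bool:
        return not (np.array_equal(self.eps01_case, self.eps01_control)
                    and np.array_equal(self.eps10_case, self.eps10_control))

    def for_group(self, case: bool) -> tuple[np.ndarray, np.ndarray]:
        if case:
            return self.eps01_case, self.eps10_case
        return self.eps01_control, self.eps10_control


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x variants minor-allele dosages with case/control labels."""

    dosages: np.ndarray    # (n, m), values in {0, 1, 2}
    phenotype: np.ndarray  # (n,), 1 = case, 0 = control

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages)
        y = np.asarray(self.phenotype)
        if d.ndim != 2:
            raise ValueError("dosages must be a 2-D individuals x variants matrix")
        if y.shape != (d.shape[0],):
            raise ValueError("phenotype length must match the number of individuals")
        if not np.isin(d, (0, 1, 2)).all():
            raise ValueError("dosages must be 0, 1 or 2")
        if not np.isin(y, (0, 1)).all():
            raise ValueError("phenotype labels must be 0 (control) or 1 (case)")
        object.__setattr__(self, "dosages", d.astype(np.int8, copy=False))
        object.__setattr__(self, "phenotype", y.astype(np.int8, copy=False))

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def n_cases(self) -> int:
        return int(self.phenotype.sum())

    @property
    def n_controls(self) -> int:
        return self.n_individuals - self.n_cases

    def counts(self) -> CohortCounts:
        case = self.phenotype == 1
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError("need at least one case and one control")
        return CohortCounts(
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            case_counts=self.dosages[case].sum(axis=0),
            control_counts=self.dosages[~case].sum(axis=0),
        )


def perturbed_maf(f, eps01, eps10):
    """Error-perturbed MAF  f* = f(1 - eps10) + (1 - f) eps01."""
    f = np.asarray(f, dtype=float)
    e01 = np.asarray(eps01, dtype=float)
    e10 = np.asarray(eps10, dtype=float)
    for name, a in (("f", f), ("eps01", e01), ("eps10", e10)):
        if np.any((a < 0) | (a > 1)):
            raise ValueError(f"{name} outside [0, 1]")
    out = f * (1.0 - e10) + (1.0 - f) * e01
    return float(out) if out.ndim == 0 else out


def mean_shrinkage(eps01: float, eps10: float) -> float:
    """Factor ``1 - eps10 - eps01`` by which non-differential errors shrink
    the mean case-control frequency difference mu_Di."""
    if eps01 < 0 or eps10 < 0 or eps01 + eps10 >= 1:
        raise ValueError("require eps01, eps10 >= 0 and eps01 + eps10 < 1")
    return 1.0 - eps10 - eps01


def expected_misclassifications(carrier_count: int, rate: float) -> float:
    """Expected number of misclassification events among ``carrier_count``
    alleles (or individuals) each at risk ``rate``."""
    if carrier_count < 0:
        raise ValueError("carrier_count must be non-negative")
    if not (0.0 <= rate <= 1.0):
        raise ValueError("rate must lie in [0, 1]")
    return rate * carrier_count


def apply_errors(genotypes: GenotypeMatrix, rates: ErrorRates,
                 seed: SeedLike = None) -> GenotypeMatrix:
    """Flip alleles independently with the group's per-site error rates.

    Each individual's two alleles are independent Bernoulli trials: a minor
    allele survives with probability ``1 - eps10`` and each major allele
    converts with probability ``eps01``, so a dosage-d genotype becomes
    ``Binomial(d, 1 - eps10) + Binomial(2 - d, eps01)``.  With all rates
    zero the output is bit-for-bit identical to the input.

    One (group, site) substream per draw: adding a variant site never
    perturbs the errors applied at earlier sites.
    """
    if rates.m != genotypes.m:
        raise ValueError(f"rates cover {rates.m} sites, matrix has {genotypes.m}")
    entropy = _entropy_from(seed)
    out = genotypes.dosages.copy()
    for gidx, case in enumerate((True, False)):
        mask = genotypes.phenotype == (1 if case else 0)
        if not mask.any():
            continue
        e01v, e10v = rates.for_group(case)
        for s in range(genotypes.m):
            e01, e10 = e01v[s], e10v[s]
            if e01 == 0.0 and e10 == 0.0:
                continue
            rng = _substream(entropy, gidx, s)
            d = out[mask, s].astype(np.int64)
            kept = rng.binomial(d, 1.0 - e10)
            gained = rng.binomial(2 - d, e01)
            out[mask, s] = kept + gained
    return GenotypeMatrix(dosages=out, phenotype=genotypes.phenotype)
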