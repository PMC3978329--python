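"""Case-control cohort simulator and the study's simulation setting grids.

Control genotypes are drawn under Hardy-Weinberg equilibrium at the
population MAF f; case genotypes under HWE at the case MAF implied by the
per-allele relative risk,

    f+  =  f RR / (1 + f (RR - 1)),

the standard multiplicative-allele map under the rare-disease
approximation (RR = 1 gives f+ = f; protective variants use RR = 1/r and
the map is self-inverse).  Sites are simulated independently — no linkage
disequilibrium.  Genotype errors are then overlaid allele-by-allele with
group-specific rates (see :mod:`genoerr.errors`), and both the error-free
and the error-contaminated cohorts are returned.

The three grid builders enumerate the full factorial study designs used to
characterize error impact: 210 non-differential settings (6 causal mixes x
5 MAF configurations x 7 error settings, m = 8, 1000 cases / 1000
controls), 140 differential null settings (5 x 7 x 4 case:control
error-rate ratios, all RR = 1), and a 70-setting follow-up with a single
causal variant among m = 8 or 16.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import (ErrorRates, GenotypeMatrix, SeedLike, _entropy_from,
                     _substream, apply_errors)
from .stats import CohortCounts

__all__ = [
    "VariantSpec",
    "GeneSetting",
    "SettingGrid",
    "SimulatedCohort",
    "case_maf",
    "simulate_cohort",
    "nondifferential_grid",
    "differential_grid",
    "followup_grid",
    "grid_manifest",
    "MAF_SETTINGS",
    "ERROR_SETTINGS",
    "RR_BY_MAF",
    "DIFFERENTIAL_RATIOS",
]

#: the five per-gene MAF configurations (m = 8), largest MAF first
MAF_SETTINGS: dict[str, tuple[float, ...]] = {
    "all_1pct": (0.01,) * 8,
    "all_0.1pct": (0.001,) * 8,
    "all_0.01pct": (0.0001,) * 8,
    "mix_1pct_0.1pct": (0.01,) * 2 + (0.001,) * 6,
    "mix_1pct_0.01pct": (0.01,) * 2 + (0.0001,) * 6,
}

#: the seven (eps01, eps10) error settings
ERROR_SETTINGS: tuple[tuple[float, float], ...] = (
    (0.0, 0.0), (0.0, 0.1), (0.0, 0.5),
    (0.01, 0.0), (0.05, 0.0), (0.01, 0.1), (0.05, 0.5),
)

#: per-allele relative risk attached to each MAF stratum (risk-increasing);
#: risk-reducing variants use the reciprocal
RR_BY_MAF: dict[float, float] = {0.01: 1.5, 0.001: 3.0, 0.0001: 5.0}

#: case:control error-rate ratios of the differential study
DIFFERENTIAL_RATIOS: tuple[float, ...] = (1.2, 1.5, 1 / 1.2, 1 / 1.5)

_CAUSAL_KINDS = ("non_causal", "risk_increasing", "risk_reducing")

# Causal-status mixes; statuses are assigned to sites in order, and the MAF
# vectors above list larger-MAF sites first, so causal labels land on the
# larger-MAF sites in the mixed configurations.
_CAUSAL_MIXES: dict[str, tuple[float, float]] = {
    # name -> (fraction risk increasing, fraction risk reducing)
    "all_non_causal": (0.0, 0.0),
    "all_risk_increasing": (1.0, 0.0),
    "all_risk_reducing": (0.0, 1.0),
    "half_increasing_half_reducing": (0.5, 0.5),
    "half_increasing_half_non_causal": (0.5, 0.0),
    "quarter_each_half_non_causal": (0.25, 0.25),
}


@dataclass(frozen=True)
class VariantSpec:
    """One variant site: population MAF, per-allele relative risk, role."""

    maf: float
    relative_risk: float = 1.0
    causal: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 < self.maf < 1.0):
            raise ValueError("maf must lie in (0, 1)")
        if self.relative_risk <= 0:
            raise ValueError("relative_risk must be positive")
        if self.causal is None:
            rr = self.relative_risk
            inferred = ("non_causal" if rr == 1.0
                        else "risk_increasing" if rr > 1.0 else "risk_reducing")
            object.__setattr__(self, "causal", inferred)
        if self.causal not in _CAUSAL_KINDS:
            raise ValueError(f"causal must be one of {_CAUSAL_KINDS}")
        if (self.causal == "non_causal") != (self.relative_risk == 1.0):
            raise ValueError("non_causal holds exactly when relative_risk == 1")
        if (self.causal == "risk_reducing") != (self.relative_risk < 1.0):
            raise ValueError("risk_reducing holds exactly when relative_risk < 1")

    @property
    def case_maf(self) -> float:
        return case_maf(self.maf, self.relative_risk)


@dataclass(frozen=True)
class GeneSetting:
    """One simulation scenario: variants, sample sizes, error rates, label."""

    variants: tuple[VariantSpec, ...]
    n_cases: int
    n_controls: int
    errors: ErrorRates
    label: str
    error_ratio: float = 1.0  # case:control rate ratio used to build `errors`

    def __post_init__(self) -> None:
        object.__setattr__(self, "variants", tuple(self.variants))
        if len(self.variants) < 1:
            raise ValueError("need at least one variant")
        if self.errors.m != len(self.variants):
            raise ValueError("error-rate vectors must match the number of variants")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")

    @property
    def m(self) -> int:
        return len(self.variants)

    @property
    def mafs(self) -> np.ndarray:
        return np.array([v.maf for v in self.variants])

    @property
    def case_mafs(self) -> np.ndarray:
        return np.array([v.case_maf for v in self.variants])

    @property
    def relative_risks(self) -> np.ndarray:
        return np.array([v.relative_risk for v in self.variants])

    @property
    def avg_maf(self) -> float:
        return float(self.mafs.mean())

    @property
    def pct_risk_increasing(self) -> float:
        return float(np.mean([v.causal == "risk_increasing" for v in self.variants]))

    @property
    def pct_risk_reducing(self) -> float:
        return float(np.mean([v.causal == "risk_reducing" for v in self.variants]))

    @property
    def is_null(self) -> bool:
        """True when no variant modifies risk (type-I-error scenario)."""
        return all(v.causal == "non_causal" for v in self.variants)


@dataclass(frozen=True)
class SettingGrid:
    settings: tuple[GeneSetting, ...]
    kind: str  # non_differential | differential | followup

    def __post_init__(self) -> None:
        object.__setattr__(self, "settings", tuple(self.settings))
        labels = [s.label for s in self.settings]
        if len(set(labels)) != len(labels):
            raise ValueError("setting labels must be unique")

    def __len__(self) -> int:
        return len(self.settings)

    def __iter__(self):
        return iter(self.settings)

    def by_label(self, label: str) -> GeneSetting:
        for s in self.settings:
            if s.label == label:
                return s
        raise KeyError(label)


@dataclass(frozen=True)
class SimulatedCohort:
    """Error-free and error-contaminated realizations of one setting."""

    setting: GeneSetting
    truth: GenotypeMatrix
    observed: GenotypeMatrix

    @property
    def true_counts(self) -> CohortCounts:
        return self.truth.counts()

    @property
    def observed_counts(self) -> CohortCounts:
        return self.observed.counts()


def case_maf(f: float, relative_risk: float) -> float:
    """Case MAF under a per-allele relative risk: f RR / (1 + f (RR - 1))."""
    if not (0.0 < f < 1.0):
        raise ValueError("f must lie in (0, 1)")
    if relative_risk <= 0:
        raise ValueError("relative_risk must be positive")
    return f * relative_risk / (1.0 + f * (relative_risk - 1.0))


def simulate_cohort(setting: GeneSetting, seed: SeedLike = None) -> SimulatedCohort:
    """Draw one cohort: HWE genotypes per group and site, then errors.

    Sites use independent substreams keyed by (group, site), so extending a
    gene with further variants leaves earlier sites' genotypes unchanged.
    """
    entropy = _entropy_from(seed)
    m = setting.m
    n_plus, n_minus = setting.n_cases, setting.n_controls
    dosages = np.empty((n_plus + n_minus, m), dtype=np.int8)
    for s, v in enumerate(setting.variants):
        # channel 0 = genotype draws (channel 1 is reserved for errors)
        rng_case = _substream(entropy, 0, 0, s)
        rng_ctrl = _substream(entropy, 0, 1, s)
        dosages[:n_plus, s] = rng_case.binomial(2, v.case_maf, size=n_plus)
        dosages[n_plus:, s] = rng_ctrl.binomial(2, v.maf, size=n_minus)
    phenotype = np.concatenate([np.ones(n_plus, dtype=np.int8),
                                np.zeros(n_minus, dtype=np.int8)])
    truth = GenotypeMatrix(dosages=dosages, phenotype=phenotype)
    observed = apply_errors(truth, setting.errors,
                            seed=np.random.SeedSequence(entropy, spawn_key=(1,)))
    return SimulatedCohort(setting=setting, truth=truth, observed=observed)


def _rr_for(maf: float, role: str) -> float:
    if role == "non_causal":
        return 1.0
    base = RR_BY_MAF[maf]
    return base if role == "risk_increasing" else 1.0 / base


def _mix_roles(mix: str, m: int) -> list[str]:
    frac_inc, frac_red = _CAUSAL_MIXES[mix]
    n_inc = round(frac_inc * m)
    n_red = round(frac_red * m)
    return (["risk_increasing"] * n_inc + ["risk_reducing"] * n_red
            + ["non_causal"] * (m - n_inc - n_red))


def _err_label(e01: float, e10: float) -> str:
    return f"e01={e01:g}|e10={e10:g}"


def nondifferential_grid(n_cases: int = 1000, n_controls: int = 1000) -> SettingGrid:
    """210 settings: 6 causal mixes x 5 MAF configurations x 7 error
    settings, m = 8; 35 settings (the all-non-causal mix) are null."""
    settings = []
    for mix in _CAUSAL_MIXES:
        for maf_name, mafs in MAF_SETTINGS.items():
            roles = _mix_roles(mix, len(mafs))
            variants = tuple(VariantSpec(maf=f, relative_risk=_rr_for(f, role),
                                         causal=role)
                             for f, role in zip(mafs, roles))
            for e01, e10 in ERROR_SETTINGS:
                label = f"nd|mix={mix}|maf={maf_name}|{_err_label(e01, e10)}"
                settings.append(GeneSetting(
                    variants=variants, n_cases=n_cases, n_controls=n_controls,
                    errors=ErrorRates.nondifferential(e01, e10, m=len(mafs)),
                    label=label))
    return SettingGrid(settings=tuple(settings), kind="non_differential")


def differential_grid(n_cases: int = 1000, n_controls: int = 1000) -> SettingGrid:
    """140 null settings: 5 MAF x 7 error x 4 case:control ratios; RR = 1
    everywhere; the ratio scales both error channels in the cases."""
    settings = []
    for maf_name, mafs in MAF_SETTINGS.items():
        variants = tuple(VariantSpec(maf=f) for f in mafs)
        for e01, e10 in ERROR_SETTINGS:
            for ratio in DIFFERENTIAL_RATIOS:
                label = (f"diff|maf={maf_name}|{_err_label(e01, e10)}"
                         f"|ratio={ratio:.4f}")
                settings.append(GeneSetting(
                    variants=variants, n_cases=n_cases, n_controls=n_controls,
                    errors=ErrorRates.differential(e01, e10, ratio, m=len(mafs)),
                    label=label, error_ratio=ratio))
    return SettingGrid(settings=tuple(settings), kind="differential")


def _followup_mafs(name: str, m: int) -> tuple[float, ...]:
    if m == 8:
        return MAF_SETTINGS[name]
    # m = 16 doubles each stratum of the printed configurations
    doubled = {
        "all_1pct": (0.01,) * 16,
        "all_0.1pct": (0.001,) * 16,
        "all_0.01pct": (0.0001,) * 16,
        "mix_1pct_0.1pct": (0.01,) * 4 + (0.001,) * 12,
        "mix_1pct_0.01pct": (0.01,) * 4 + (0.0001,) * 12,
    }
    return doubled[name]


def followup_grid(n_cases: int = 1000, n_controls: int = 1000) -> SettingGrid:
    """70 settings: {5 MAF x 7 error} x m in {8, 16}, exactly one causal
    (risk-increasing) variant placed at the first — largest-MAF — site."""
    settings = []
    for m in (8, 16):
        for maf_name in MAF_SETTINGS:
            mafs = _followup_mafs(maf_name, m)
            variants = [VariantSpec(maf=mafs[0],
                                    relative_risk=RR_BY_MAF[mafs[0]],
                                    causal="risk_increasing")]
            variants += [VariantSpec(maf=f) for f in mafs[1:]]
            for e01, e10 in ERROR_SETTINGS:
                label = f"fu|m={m}|maf={maf_name}|{_err_label(e01, e10)}"
                settings.append(GeneSetting(
                    variants=tuple(variants), n_cases=n_cases,
                    n_controls=n_controls,
                    errors=ErrorRates.nondifferential(e01, e10, m=m),
                    label=label))
    return SettingGrid(settings=tuple(settings), kind="followup")


def grid_manifest(grid: SettingGrid) -> pd.DataFrame:
    """One row per setting: label, sizes, MAFs, RRs and error rates."""
    rows = []
    for s in grid:
        rows.append({
            "label": s.label,
            "kind": grid.kind,
            "m": s.m,
            "n_cases": s.n_cases,
            "n_controls": s.n_controls,
            "mafs": ",".join(f"{f:g}" for f in s.mafs),
            "relative_risks": ",".join(f"{r:g}" for r in s.relative_risks),
            "eps01_control": float(s.errors.eps01_control[0]),
            "eps10_control": float(s.errors.eps10_control[0]),
            "eps01_case": float(s.errors.eps01_case[0]),
            "eps10_case": float(s.errors.eps10_case[0]),
            "error_ratio": s.error_ratio,
            "avg_maf": s.avg_maf,
            "pct_risk_increasing": s.pct_risk_increasing,
            "pct_risk_reducing": s.pct_risk_reducing,
            "is_null": s.is_null,
        })
    return pd.DataFrame(rows)
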