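"""Grid orchestration and the meta-regression summarizer.

``run_grid`` evaluates every (setting, statistic) pair of a named grid by
Monte-Carlo permutation testing and writes one tidy TSV row per pair with
the empirical rate, its binomial SE and the covariates the summarizer
needs.  Runs are deterministic given the root seed (per-setting seeds are
derived from the setting label, so execution order and parallel
scheduling are irrelevant) and resumable (completed setting/statistic
pairs found in the output file are skipped).

``summarize_grid`` fits the ordinary-least-squares meta-regressions that
relate empirical power (or type-I error) to the design factors, using the
ordinal error-magnitude coding 0/1/5 (eps01: 0%, 1%, 5%; eps10: 0%, 10%,
50%), average MAF per 0.1%, causal-mix percentages per 10 points, and the
case:control error-rate ratio per 10% relative difference.
"""
from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import SeedLike
from .permutation import PermutationPlan, empirical_rates
from .simulate import (GeneSetting, SettingGrid, differential_grid,
                       followup_grid, nondifferential_grid)
from .stats import STATISTICS

__all__ = [
    "RunConfig",
    "SummaryModel",
    "run_grid",
    "summarize_grid",
    "error_magnitude_code",
    "load_config",
]

_GRIDS = {
    "non_differential": nondifferential_grid,
    "differential": differential_grid,
    "followup": followup_grid,
}

_E01_CODES = {0.0: 0.0, 0.01: 1.0, 0.05: 5.0}
_E10_CODES = {0.0: 0.0, 0.1: 1.0, 0.5: 5.0}


@dataclass
class RunConfig:
    """Configuration of one grid run."""

    grid: str = "non_differential"
    n_reps: int = 1000
    n_permutations: int = 1000
    alpha: float = 0.05
    seed: int = 0
    statistics: Sequence[tuple[str, float]] = field(default_factory=lambda: STATISTICS)
    out_dir: Union[str, os.PathLike, None] = None
    n_workers: int = 1
    labels: Optional[Sequence[str]] = None  # restrict to these settings

    def __post_init__(self) -> None:
        if self.grid not in _GRIDS:
            raise ValueError(f"grid must be one of {sorted(_GRIDS)}")
        if self.n_reps < 1 or self.n_permutations < 1 or self.n_workers < 1:
            raise ValueError("counts must be positive")
        if not self.statistics:
            raise ValueError("statistic list must be non-empty")
        self.statistics = [(f, float(p)) for f, p in self.statistics]


def load_config(path: Union[str, os.PathLike]) -> RunConfig:
    """Read a RunConfig from a YAML mapping (statistics as e.g. 'L1, J2'
    or a list of [family, norm] pairs)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "statistics" in raw:
        raw["statistics"] = _parse_statistics(raw["statistics"])
    return RunConfig(**raw)


def _parse_statistics(spec) -> list[tuple[str, float]]:
    if isinstance(spec, str):
        spec = [s.strip() for s in spec.split(",") if s.strip()]
    out = []
    for item in spec:
        if isinstance(item, str):
            fam = "length" if item[0].upper() == "L" else "joint"
            norm = math.inf if item[1:].lower() in ("inf", "∞") else float(item[1:])
            out.append((fam, norm))
        else:
            fam, norm = item
            out.append((fam, math.inf if str(norm) == "inf" else float(norm)))
    return out


def error_magnitude_code(eps01: float, eps10: float) -> float:
    """Ordinal 0/1/5 coding of the study's error magnitudes; for settings
    with both channels active the (shared) ordinal level is the max."""
    for value, codes, name in ((eps01, _E01_CODES, "eps01"),
                               (eps10, _E10_CODES, "eps10")):
        if not any(np.isclose(value, k) for k in codes):
            raise ValueError(
                f"{name}={value} is not one of the study's grid rates "
                f"{sorted(codes)}; the 0/1/5 coding is defined only there")
    c01 = next(v for k, v in _E01_CODES.items() if np.isclose(eps01, k))
    c10 = next(v for k, v in _E10_CODES.items() if np.isclose(eps10, k))
    return max(c01, c10)


def _setting_row(setting: GeneSetting, kind: str, family: str, norm: float,
                 rate, config: RunConfig) -> dict:
    return {
        "label": setting.label,
        "kind": kind,
        "family": family,
        "norm": "inf" if math.isinf(norm) else f"{norm:g}",
        "rate": rate.rate,
        "mc_se": rate.mc_se,
        "n_reps": rate.n_reps,
        "n_permutations": config.n_permutations,
        "alpha": config.alpha,
        "seed": config.seed,
        "m": setting.m,
        "n_cases": setting.n_cases,
        "n_controls": setting.n_controls,
        "is_null": setting.is_null,
        "avg_maf": setting.avg_maf,
        "pct_risk_increasing": setting.pct_risk_increasing,
        "pct_risk_reducing": setting.pct_risk_reducing,
        "eps01_control": float(setting.errors.eps01_control[0]),
        "eps10_control": float(setting.errors.eps10_control[0]),
        "error_ratio": setting.error_ratio,
    }


def _evaluate_setting(setting: GeneSetting, kind: str,
                      config: RunConfig) -> list[dict]:
    plan = PermutationPlan(n_permutations=config.n_permutations,
                           seed=config.seed)
    rates = empirical_rates(setting, config.statistics, config.n_reps,
                            plan, config.alpha)
    return [_setting_row(setting, kind, fam, norm, rates[(fam, norm)], config)
            for fam, norm in config.statistics]


def run_grid(config: RunConfig) -> pd.DataFrame:
    """Run every setting x statistic of the configured grid.

    Returns the tidy results table; when ``config.out_dir`` is set the
    table is also written to ``results_<grid>.tsv`` there, appending to —
    and skipping settings already present in — an existing file.
    """
    grid: SettingGrid = _GRIDS[config.grid]()
    settings = list(grid)
    if config.labels is not None:
        wanted = set(config.labels)
        settings = [s for s in settings if s.label in wanted]
        missing = wanted - {s.label for s in settings}
        if missing:
            raise KeyError(f"labels not in grid: {sorted(missing)}")

    out_path = None
    done: set[str] = set()
    previous = pd.DataFrame()
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / f"results_{config.grid}.tsv"
        if out_path.exists():
            previous = pd.read_csv(out_path, sep="\t", dtype={"norm": str})
            n_stats = len(config.statistics)
            counts = previous.groupby("label").size()
            done = set(counts.index[counts >= n_stats])
    todo = [s for s in settings if s.label not in done]

    if config.n_workers > 1 and len(todo) > 1:
        from joblib import Parallel, delayed
        chunks = Parallel(n_jobs=config.n_workers)(
            delayed(_evaluate_setting)(s, grid.kind, config) for s in todo)
    else:
        chunks = []
        for s in todo:
            rows = _evaluate_setting(s, grid.kind, config)
            chunks.append(rows)
            if out_path is not None:  # incremental, resumable append
                frame = pd.DataFrame(rows)
                frame.to_csv(out_path, sep="\t", index=False, mode="a",
                             header=not out_path.exists())
    new = pd.DataFrame([r for rows in chunks for r in rows])
    result = pd.concat([previous, new], ignore_index=True) if len(previous) else new
    if out_path is not None and (config.n_workers > 1 or len(previous)):
        result.to_csv(out_path, sep="\t", index=False)
    return result


@dataclass
class SummaryModel:
    """OLS fit of an empirical rate on the study's design factors."""

    response: str
    coefficients: pd.Series
    standard_errors: pd.Series
    n_obs: int
    fit: object  # statsmodels results, for diagnostics

    def __repr__(self) -> str:  # compact, table-like
        rows = "\n".join(f"  {k:32s} {v:+.4f} (se {self.standard_errors[k]:.4f})"
                         for k, v in self.coefficients.items())
        return f"SummaryModel(response={self.response!r}, n={self.n_obs})\n{rows}"


def _covariates(results: pd.DataFrame, response: str) -> pd.DataFrame:
    cov = pd.DataFrame(index=results.index)
    cov["error_magnitude"] = [
        error_magnitude_code(e01, e10)
        for e01, e10 in zip(results["eps01_control"], results["eps10_control"])]
    cov["avg_maf"] = results["avg_maf"] / 0.001          # per 0.1% MAF
    if response == "power":
        cov["pct_risk_increasing"] = results["pct_risk_increasing"] * 10  # per 10%
        cov["pct_risk_reducing"] = results["pct_risk_reducing"] * 10
    else:
        ratio = results["error_ratio"].to_numpy(dtype=float)
        rel = np.maximum(ratio, 1.0 / ratio) - 1.0       # relative difference
        cov["error_ratio"] = rel * 10.0                  # per 10% difference
    return cov


def summarize_grid(results: pd.DataFrame, response: str = "power") -> SummaryModel:
    """Regress the empirical rate on the design factors.

    ``results`` should hold rows from one grid kind and one statistic
    (one row per setting).  ``response`` selects the power covariates
    (error magnitude, average MAF, percent risk increasing / reducing) or
    the type-I covariates (error magnitude, average MAF, case:control
    error-rate ratio).
    """
    if response not in ("power", "type_I"):
        raise ValueError("response must be 'power' or 'type_I'")
    x = _covariates(results, response)
    x_mat = sm.add_constant(x, has_constant="add")
    if np.linalg.matrix_rank(x_mat.to_numpy()) < x_mat.shape[1]:
        raise ValueError("rank-deficient design: covariates are collinear on "
                         "these rows (did you filter to a single factor level?)")
    fit = sm.OLS(results["rate"].to_numpy(dtype=float), x_mat).fit()
    return SummaryModel(response=response, coefficients=fit.params,
                        standard_errors=fit.bse, n_obs=int(fit.nobs), fit=fit)
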