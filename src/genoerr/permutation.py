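"""Phenotype-permutation inference and empirical power / type-I estimation.

The permutation p-value for a statistic T is the proportion of B random
case/control relabelings (preserving N+ and N-) whose permuted statistic
meets or exceeds the observed value.  The default tie rule counts
``T_perm >= T_obs`` — conservative, never returns p = 0, and reproduces the
deflation seen at very low aggregate MAF where the permutation
distribution is highly discrete; ``strictly_greater`` is available.  No
(B+1)-smoothing is applied.

All statistics depend on the data only through per-group allele counts, so
each batch of B relabelings is realized as one indicator-matrix product:
B x n case indicators times the n x m dosage matrix gives every permuted
count vector at once.
"""
from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .errors import GenotypeMatrix, SeedLike, _entropy_from
from .simulate import GeneSetting, simulate_cohort
from .stats import TestResult, evaluate_statistic

__all__ = [
    "PermutationPlan",
    "EmpiricalRate",
    "permutation_pvalue",
    "permutation_pvalues",
    "empirical_rate",
    "empirical_rates",
]

_TIE_RULES = ("greater_or_equal", "strictly_greater")
# absolute slack when comparing permuted to observed statistics: both sides
# are ratios of integers over 2N, so genuine ties differ only by float
# round-off many orders below this
_TIE_ATOL = 1e-12


@dataclass(frozen=True)
class PermutationPlan:
    """Number of relabelings B, RNG seed, and the tie rule."""

    n_permutations: int = 1000
    seed: SeedLike = None
    tie_rule: str = "greater_or_equal"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.tie_rule not in _TIE_RULES:
            raise ValueError(f"tie_rule must be one of {_TIE_RULES}")


@dataclass(frozen=True)
class EmpiricalRate:
    """Monte-Carlo power or type-I estimate with its binomial SE."""

    rate: float
    n_reps: int

    @property
    def mc_se(self) -> float:
        return float(np.sqrt(self.rate * (1.0 - self.rate) / self.n_reps))


def _label_key(label: str) -> int:
    digest = hashlib.blake2s(label.encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2 ** 31)


def _permuted_group_freqs(gm: GenotypeMatrix, n_permutations: int,
                          rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """(B, m) case and control MAF matrices under random relabelings."""
    n, n_plus = gm.n_individuals, gm.n_cases
    x = gm.dosages.astype(np.float64)
    total = x.sum(axis=0)
    u = rng.random((n_permutations, n))
    idx = np.argpartition(u, n_plus - 1, axis=1)[:, :n_plus]
    ind = np.zeros((n_permutations, n))
    ind[np.arange(n_permutations)[:, None], idx] = 1.0
    case_counts = ind @ x
    ctrl_counts = total[None, :] - case_counts
    return (case_counts / (2.0 * n_plus),
            ctrl_counts / (2.0 * (n - n_plus)))


def _pvalue(observed: float, permuted: np.ndarray, tie_rule: str) -> float:
    if tie_rule == "greater_or_equal":
        return float(np.mean(permuted >= observed - _TIE_ATOL))
    return float(np.mean(permuted > observed + _TIE_ATOL))


def permutation_pvalues(genotypes: GenotypeMatrix,
                        statistics: Sequence[tuple[str, float]],
                        plan: PermutationPlan) -> list[TestResult]:
    """Permutation p-values for several statistics from one shared batch of
    relabelings (the relabelings, not just the seed, are common)."""
    if genotypes.n_cases == 0 or genotypes.n_controls == 0:
        raise ValueError("need at least one case and one control to permute")
    rng = np.random.Generator(np.random.PCG64(_entropy_from(plan.seed)))
    case_f, ctrl_f = _permuted_group_freqs(genotypes, plan.n_permutations, rng)
    counts = genotypes.counts()
    obs_case, obs_ctrl = counts.case_freq, counts.control_freq
    results = []
    for family, norm in statistics:
        obs = float(evaluate_statistic(obs_case, obs_ctrl, family, norm))
        perm = evaluate_statistic(case_f, ctrl_f, family, norm, axis=1)
        results.append(TestResult(family=family, norm=norm, value=obs,
                                  p_value=_pvalue(obs, perm, plan.tie_rule),
                                  n_permutations=plan.n_permutations))
    return results


def permutation_pvalue(genotypes: GenotypeMatrix,
                       statistic: tuple[str, float],
                       plan: PermutationPlan) -> TestResult:
    """Permutation p-value of one (family, norm) statistic."""
    return permutation_pvalues(genotypes, [statistic], plan)[0]


def empirical_rates(setting: GeneSetting,
                    statistics: Sequence[tuple[str, float]],
                    n_reps: int,
                    plan: PermutationPlan,
                    alpha: float = 0.05) -> dict[tuple[str, float], EmpiricalRate]:
    """Simulate ``n_reps`` cohorts and estimate P(p < alpha) per statistic.

    The rate is power when the setting contains causal variants and the
    type-I error rate otherwise.  Per-replicate seeds are derived from
    (plan.seed, setting label, replicate index), so results do not depend
    on execution order and other settings' draws.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must lie in (0, 1]")
    root = _entropy_from(plan.seed)
    key = _label_key(setting.label)
    statistics = list(statistics)
    hits = {stat: 0 for stat in statistics}
    for rep in range(n_reps):
        ss = np.random.SeedSequence(root, spawn_key=(key, rep))
        sim_seed, perm_seed = ss.spawn(2)
        cohort = simulate_cohort(setting, seed=sim_seed)
        rep_plan = PermutationPlan(n_permutations=plan.n_permutations,
                                   seed=perm_seed, tie_rule=plan.tie_rule)
        for res in permutation_pvalues(cohort.observed, statistics, rep_plan):
            # a level-1 test rejects always, even though p-values tie at 1
            if res.p_value < alpha or alpha >= 1.0:
                hits[(res.family, res.norm)] += 1
    return {stat: EmpiricalRate(rate=hits[stat] / n_reps, n_reps=n_reps)
            for stat in statistics}


def empirical_rate(setting: GeneSetting, statistic: tuple[str, float],
                   n_reps: int, plan: PermutationPlan,
                   alpha: float = 0.05) -> EmpiricalRate:
    """Empirical power / type-I error rate for one statistic."""
    return empirical_rates(setting, [statistic], n_reps, plan, alpha)[statistic]
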