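# Methods

## The statistics

For a gene region with `m` biallelic variant sites genotyped in `N+` cases
and `N-` controls, let `c+_i` and `c-_i` be the minor-allele counts at site
`i` and write the per-group frequency vectors `c+/(2N+)` and `c-/(2N-)`.
Two families cover most published gene-based rare-variant tests:

- **Length (burden / collapsing):**
  `L_p = ||c+/(2N+)||_p − ||c-/(2N-)||_p` — compares the L^p norms of the
  two frequency vectors; signed, one-sided toward an excess in cases.
- **Joint (variance-component style):**
  `J_p = ||c+/(2N+) − c-/(2N-)||_p` — aggregates the per-site differences
  `D_i = c+_i/(2N+) − c-_i/(2N-)`.

`p ∈ {1, 2, 4, 8, ∞}` are exposed; `p = 1` is the classical burden test
and `p = 2` with per-site variance weights is SKAT-like.  `L_∞` is the
difference of per-group maxima; `J_∞` is the **signed** maximum
`max_i D_i` (the statistic is used one-sided throughout; an unsigned
`max_i |D_i|` variant exists behind `absolute_max=True` for architectures
with strong protective variants).  Norm 8 serves as the practical
finite-`p` stand-in for the high-norm regime and is reported alongside ∞.

Under the null `f+_i = f-_i` for all `i`, with counts binomial
(`c±_i ~ Binom(2N±, f±_i)`), HWE, and no LD between sites:

    mu_Di     = f+_i − f-_i
    sigma²_Di = f+_i(1−f+_i)/(2N+) + f-_i(1−f-_i)/(2N-)

The variance-scaled statistic `J²_2,scaled = Σ_i (D_i/σ_Di)²` is
asymptotically `χ²_m` under the null and noncentral `χ²_{m,λ}` with
`λ = Σ_i (μ_Di/σ_Di)²` under the alternative.  `scaled_joint2` refuses
monomorphic sites (zero null variance) with `DegenerateSiteError`; the
unscaled statistics retain them (they contribute 0).

## The error model

Genotype misclassification is modelled per allele: `eps01` is the chance a
major allele is called minor, `eps10` the reverse.  Each of an
individual's two alleles flips independently, so a dosage-`d` genotype
becomes `Binom(d, 1−eps10) + Binom(2−d, eps01)`; a hom-major→het genotype
error therefore occurs at rate `≈ 2·eps01(1−eps01)`, and rare-homozygote
errors arise only as double flips (no separate genotype-level channel).
The perturbed MAF is

    f* = f(1 − eps10) + (1 − f) eps01.

Non-differential errors (equal rates in both phenotype groups) preserve
the null (`f+* − f-* = 0` when `f+ = f-`) but shrink every effect by
`1 − eps10 − eps01` while inflating the count variance whenever
`eps01 > eps10·f/(1−f)` — for rare variants, essentially always.  That is
why the major→minor channel dominates: at `f = 0.1%` in 10,000
individuals, ~9990 common homozygotes each face `eps01` while only ~10
minor alleles face `eps10`.  Differential errors (rates depending on
phenotype) shift the null mean by
`f((eps10⁻−eps10⁺)+(eps01⁻−eps01⁺)) + (eps01⁺−eps01⁻)` per site and
inflate the type-I error rate.

## Closed-form calculators

`L1 = Σ_i D_i` is treated as normal; `J²_2,scaled` as (non)central χ².

- **Power (L1):** critical value `C = z_{1−α}·sqrt(Σ σ²_{Di,H0})`, then
  `π = 1 − Φ((C − Σμ*_{Di}) / sqrt(Σ σ*²_{Di}))` with starred moments at
  the error-perturbed frequencies.
- **Sample size (L1):** with `k = N-/N+` fixed and
  `t_i = (f+(1−f+) + f-(1−f-)/k)/2` (so `σ²_Di = t_i/N+`),
  `N+* = ((z_{1−α}√Σt*_{H0} − z_β√Σt*_{HA}) / Σμ*)²`; reported both
  continuous and rounded up, plus the ratio to the error-free
  requirement.
- **Type I (L1):** `α* = 1 − Φ((C − Σμ*_{H0}) / sqrt(Σσ*²_{H0}))` for a
  null design with differential rates.
- **Scaled J2:** `π = P(χ²_{m,λ*} > χ²_{m,α})` with
  `λ* = Σ(μ*_Di/σ*_Di)²`; sample-size ratio `Σ(μ²/t) / Σ(μ*²/t*)` from
  matching noncentralities; `α*` analogously from the differential λ*.

### The null-variance convention

There are two defensible choices for the frequencies behind the L1 null
critical value `C`.  `null_variance="perturbed"` (default for `l1_power`
and `l1_sample_size`) pushes the null MAFs through each group's error
rates first — this is what any test calibrated on the observed,
contaminated data does implicitly (the permutation test above all), it
keeps the size exactly at α under non-differential errors, and it tracks
permutation-based empirical power closely even at eps10 = 50%
(measured here: at 1% MAF with errors (0.05, 0.5), empirical permutation
power 0.245 vs 0.222 predicted; the error-free convention predicts 0.560).
`null_variance="error_free"` fixes `C` at the uncontaminated null; it is
the natural convention for `l1_inflated_alpha` (its default), where the
question is precisely what happens to a test calibrated error-free when
contaminated data arrive.  Under the error-free convention
non-differential errors alone push the realized size above α through
variance inflation; under the perturbed convention (and in permutation
tests) `α* = α` holds exactly for non-differential errors.

Noncentral-χ² tails come from `scipy.stats.ncx2` (central `chi2` at
λ = 0), which is accurate far beyond the λ ≤ 10⁴ range used here.
Calculators emit `SmallCountWarning` (without refusing) when any expected
minor-allele count `2N·f*` falls below 5: the normal approximation
visibly degrades there, and Monte-Carlo checks show ±0.04 absolute error
at 2–6 expected alleles while being 2–3 decimal places accurate at 1%
MAF.  Sample sizes are treated as continuous quantities inside the
calculators so the power ↔ sample-size round trip is exact to 1e-6.

## Simulator and study grids

Controls are drawn under HWE at the population MAF `f`; cases under HWE
at the case MAF implied by a per-allele relative risk via
`f+ = fRR/(1 + f(RR−1))` — the standard multiplicative-allele map under
the rare-disease approximation, self-inverse for protective `RR = 1/r`.
Sites are independent (no LD) and errors are overlaid afterwards with
group-specific rates.  RNG streams are keyed per (channel, group, site)
from one root seed, so adding a variant site never perturbs the draws at
earlier sites, and per-replicate seeds in the Monte-Carlo loops derive
from (root seed, setting label, replicate), making results independent of
execution order and safe to parallelize.

The three factorial grids fix `N+ = N- = 1000`:

- **Non-differential** (210 settings, `m = 8`): 5 MAF configurations
  (all 1%, all 0.1%, all 0.01%, 2×1% + 6×0.1%, 2×1% + 6×0.01%) × 7
  error settings `(eps01, eps10) ∈ {(0,0), (0,.1), (0,.5), (.01,0),
  (.05,0), (.01,.1), (.05,.5)}` × 6 causal mixes (all non-causal — the 35
  null settings; all risk-increasing; all risk-reducing; ½+½ increasing/
  reducing; ½ increasing + ½ non-causal; ¼+¼+½).  Risk-increasing RRs
  follow the site's MAF stratum (1% → 1.5, 0.1% → 3, 0.01% → 5);
  protective variants use the reciprocals.  Causal statuses are assigned
  increasing-first, reducing-second, non-causal-last in descending-MAF
  site order, so causal labels land on the larger-MAF sites in mixed
  configurations (the original enumeration does not pin this down; this
  is the package's fixed convention, not a claim about anyone else's).
- **Differential** (140 null settings): 5 MAF × 7 error × case:control
  rate ratios {1.2, 1.5, 1/1.2, 1/1.5}, with `RR = 1` everywhere.  The
  ratio multiplies **both** error channels in the cases (the alternative
  — scaling only eps01 — is unresolvable from the printed description;
  one convention is adopted and documented).
- **Follow-up** (70 settings): the 35 MAF × error combinations × `m ∈ {8,
  16}` with exactly one causal (risk-increasing) variant at the
  largest-MAF site; the `m = 16` MAF configurations double each stratum
  (4×1% + 12×lower in the mixed settings).

What the simulator deliberately does **not** emulate: LD between sites,
population stratification, covariates, read-level sequencing error
(errors act on true genotypes, not on reads), genotype-likelihood or
dosage uncertainty, and rare-homozygote-specific error channels.  Tests
passing against this generator therefore validate the statistics and the
allele-level error arithmetic, not robustness to correlated variants or
structured cohorts.

## Permutation inference

P-values come from `B` random case/control relabelings preserving group
sizes; every statistic is a function of per-group allele counts, so one
`B×n` indicator-matrix product per replicate yields all permuted counts
at once.  The default tie rule counts `T_perm ≥ T_obs` (conservative;
never returns 0; reproduces the type-I deflation seen at very low
aggregate MAF, where the permutation distribution is strongly discrete);
`strictly_greater` is available since "exceeds" is the other defensible
reading.  No `(B+1)`-smoothing is applied — `p = (#{T_perm ≥ T_obs})/B`
— though the smoothed estimator is the usual remedy when exact validity
at tiny B matters.  Power/type-I estimates reject at `p < α` (a level-1
"test" rejects always).

## Meta-regression

`summarize_grid` fits OLS of the empirical rate on coded design factors:
error magnitude on the ordinal 0/1/5 scale (eps01 0/1/5%, eps10 0/10/50%;
with both channels active the shared level is used), average MAF per
0.1%, causal percentages per 10 points (power response), and the
case:control ratio per 10% relative difference `10·(max(r, 1/r) − 1)`
(type-I response).  The coding is defined only on the grid's levels;
off-grid rates are rejected rather than silently extrapolated.

## Problem sizes used by the test suite

The suite runs everything at desk scale: type-I control is checked on 6
null settings at 1000 replicates × 500 permutations; analytic-vs-
empirical power agreement on 6 all-1%-MAF settings at 500 × 500; the
meta-regression sign pattern on 45 eps01-only causal settings at 120 ×
150.  These sizes give Monte-Carlo SEs of ~0.7–2 points, comfortably
inside the 3–7% acceptance band and the ±10-point agreement margin, and
were fixed as the package's own choice of test scale.  The full-scale
study (all 350 settings × 8 statistics × 1000 × 1000) runs through
`run_grid` / the `genoerr grid` CLI, which is resumable and
parallelizable for that purpose.

## Known limitations

- The analytic calculators inherit the normal/χ² approximations; below
  ~5 expected minor alleles per group they are indicative only (hence the
  warning contract).
- `J²_2,scaled` treats the per-site variance as known; in data mode the
  pooled plug-in MAF is the natural scaling, and Monte-Carlo checks show
  the noncentral approximation matches that choice (control-side plug-in
  scaling drifts upward).
- No finite-sample variance correction is applied anywhere (the
  large-sample unbiasedness of D-variance estimates under
  non-differential misclassification is taken as given).
- Single-gene scope: no multiple-testing machinery across genes.
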