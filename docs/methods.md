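# Methods

## The synthetic cohort generator

The generator emulates a constant-temperature rearing experiment: cohorts of
individuals are followed daily from oviposition, through egg, larval and
pupal development, to adult emergence, reproduction and death.  It is the
package's substitute for raw rearing records and defines the study
conditions every downstream module is exercised under.

**Stage durations.** Whole-day durations are drawn from a gamma distribution
parameterised by the configured mean and SD (shape = (mean/SD)², so
positivity is guaranteed), rounded to the nearest day and floored at 1.  The
per-stage SD defaults to 15% of the mean; the assays report only means, so
the dispersion is a modelling choice of typical insect rearing variability.
Stage means are anchored at the reported totals (e.g. *P. nasuta* 64.8 d at
16 °C, 19 d at 30 °C; *P. coffea* 87.35 d at 19 °C, 32.78 d at 28 °C) and
split across egg/larva/pupa in proportion to the per-stage thermal constants
(12/51/37% for *P. nasuta*, 8.5/45.8/45.7% for *P. coffea*).

**Survival.** Each stage applies an independent Bernoulli filter.  Where the
source reports per-stage survival (*P. coffea*: egg 0.75 at 16 °C, larva
0.41 at 32 °C, adult 0.87 at 25 °C, …) those values are used directly; where
only egg-to-adult survival is reported (*P. nasuta*) each of the four stages
receives the 4th root of the total.  The adult stage's survival probability
models post-emergence establishment: individuals failing it die on adult day
1 without reproducing.  Consequently the probability of *emerging* is the
product of the three immature survivals (total^(3/4) under the 4th-root
decomposition) while the expected net reproductive rate uses the full
4-stage product:

    E[R0] = female_proportion × s_egg s_larva s_pupa s_adult × mean fecundity.

Nonviable temperatures are encoded as zero survival at the stage where
development stops (32/35 °C for both species; 16 °C past the egg for
*P. coffea*), not as absent treatments.

**Sex and reproduction.** Sex is Bernoulli(female proportion) at emergence;
female proportions follow the reported values (*P. nasuta* 0.96 at 16 °C
declining to 0.21 at 30 °C; *P. coffea* ≈ 0.52 throughout).  Lifetime
fecundity is negative binomial with the reported means (peaks of 27 and 38
eggs/female at 25 °C) and dispersion parameter 5 — overdispersed relative to
Poisson, as insect egg counts generally are.  Eggs are spread over adult
life with a symmetric triangular age profile (reproduction rising to
mid-life, then declining) and binned into observation intervals: 1 day for
*P. coffea* (daily censusing) and 15 days for *P. nasuta* (host beans were
dissected every 15 days).  No age-specific fecundity schedule was reported,
so the triangular profile is an explicit assumption; every life-table
quantity except the age pattern of m_x is insensitive to it because interval
totals are conserved exactly.

**What the generator does not emulate:** fluctuating temperatures,
host-density limitation, parasitoid–host dynamics, within-cohort correlation
between development speed and fecundity, and observation error in stage
boundaries.  Passing tests therefore demonstrate that the estimators recover
known truth under the design's statistical structure — not that field data
satisfy that structure.

## Nonparametric comparisons

Kruskal–Wallis uses midranks with the standard tie correction
H_c = H / (1 − Σ(t³−t)/(N³−N)) and a χ² reference on k−1 df; the degenerate
all-values-identical case is reported as H = 0, p = 1.  Dunn's z for groups
i, j is

    z_ij = (R̄_i − R̄_j) / sqrt( (N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j) ),

two-sided normal p, with no adjustment by default (holm and bonferroni
available).  For k = 2 this z satisfies z² = H_c, which the tests verify
numerically.  Letter displays use the insert-and-absorb algorithm: one
column initially holds all groups, each significant pair splits the columns
containing both members, subset columns are absorbed, and letters are
assigned in descending-median order; non-transitive significance patterns
yield multi-letter groups rather than errors.

Egg-to-adult survival is modelled as a saturated one-factor binomial GLM on
the logit scale.  The group MLE is logit(p̂) with SE = sqrt(1/s + 1/f);
boundary groups (s = 0 or f = 0) get a +0.5 continuity correction and are
flagged.  Pairwise differences use Wald z statistics with Holm adjustment —
a deliberately lighter multiple-comparison machinery than single-step
Tukey-style contrasts on the GLM, which would require multivariate-normal
quantiles out of proportion to four-to-six group comparisons.

## Linear development-rate model

The development rate is the reciprocal of the *mean* duration among
completers per temperature — one regression point per temperature, matching
the convention of reporting a single fitted equation per stage — and OLS
gives 1/d = a + bT.  Temperatures where a stage was completed by at least
one individual contribute a point for that stage even when later stages fail
there, which is why temperature ranges differ across stages.  The lower
threshold t = −a/b and thermal constant K = 1/b require b > 0; a
non-positive slope is rejected as biologically invalid rather than returned.
Reported coefficients are conventionally rounded (a, b to 4 dp; t to 1 dp;
K to the nearest degree-day) but all internal computation is unrounded.

## Age-stage two-sex life table

Age is in integer days from oviposition (age 0) to the last observed death.
s_xj is the fraction of the initial cohort alive in stage j at age x — both
sexes and pre-adult deaths stay in the denominator, so male development and
immature mortality dilute fecundity exactly as the two-sex framework
intends.  Interval egg counts are spread uniformly over the adult days each
interval covers, making Σ l_x m_x × n equal the cohort's total egg count
exactly for any observation interval.

The intrinsic rate solves Σ_x e^{−r(x+1)} l_x m_x = 1 with the exponent
x+1 (ages indexed from 0) — the convention of age-stage two-sex life-table
software, stated explicitly because the classical Euler–Lotka form uses x.
The left side is strictly decreasing in r, so the solver brackets the root
by doubling, bisects to a narrow interval, and polishes with safeguarded
Newton steps to |Σ − 1| < 1e−12.  Derived quantities: λ = e^r,
T = ln(R0)/r, Dt = ln 2 / r; T is reported as not-applicable (NaN) at
r = 0 and Dt for r ≤ 0.

**Bootstrap.** Individuals (not individual-days) are resampled with
replacement; per replicate the per-capita egg-age schedule φ_x is a weighted
column mean of the per-individual egg matrices, giving R0 = Σφ_x and r from
a vectorised bisection (80 iterations, resolution far below the Monte Carlo
noise).  Intervals are 95% percentile intervals (not BCa), with the R0 lower
bound clamped at zero — the net reproductive rate cannot be negative.
Replicates with R0 = 0 leave r, λ, T, Dt undefined; they are excluded from
those percentiles and their count is reported.  Two-cohort comparisons
resample both cohorts per replicate and use the tail probabilities of the
difference distribution with the small-sample correction
p = 2·min((c+1)/(B+1), …).  The default B is 10,000; the pipeline and tests
use 200–2,000, which keeps Monte Carlo error well below the effect sizes of
interest at desk scale.

## Degree-day phenology

NG = (Tm − t)·d/K per month (d = days in month) and per year, clamped at 0
below the threshold.  The calendar is a common year (February = 28 days,
365 days total), which reproduces the published *P. coffea* grid exactly at
2 decimals; annual values are computed from 365 days directly, never by
summing rounded monthly cells.  Isotherm bands are left-open/right-closed
(t_low < Tm ≤ t_high) and each band is evaluated at its boundary
temperature, the open >23 °C band at its lower boundary 23 °C; user-supplied
representative temperatures can override this.

## Pipeline and reproducibility

One seed feeds a `SeedSequence` that fans out independent streams to cohort
generation, per-temperature bootstraps, and pairwise comparisons, so stages
can be re-run in isolation and identical config+seed yields byte-identical
output tables.  Every table carries a `# config_hash=` header identifying
the analysis configuration (output location excluded).  Stages that cannot
run on the given data — life tables where nothing reproduces, thermal fits
with fewer than two viable temperatures — are skipped with a logged warning
rather than aborting the run.

## Known limitations

- The linear rate model is fitted only over the viable range; it cannot
  represent the rate decline near the upper lethal limit, so K and t
  extrapolate poorly above ~30 °C (where development fails outright).
- Percentile intervals can undercover for strongly skewed parameters at
  small cohort sizes; coverage is verified by simulation at n = 200.
- The triangular fecundity-age profile is an assumption; analyses that
  depend on the *shape* of m_x (not its total) inherit it.
- Generation-number estimates treat each isotherm band as a single constant
  temperature and ignore within-month variability.
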