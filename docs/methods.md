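# Methods

## The age-stage, two-sex life table

A cohort study starts with `n01` newly laid eggs followed daily until the
last individual dies. Each individual's record holds the integer age (in
days, 0-based) at which it entered each developmental stage — for the
packaged mite schema: egg, larva, protonymph, deutonymph, then one of two
adult stages (adult-female, adult-male) — its death age, and its daily egg
counts. An individual with death age `d` is counted alive at ages
`x < d`; its stage at age `x` is the stage with the greatest entry age
`≤ x`. A stage "entered on day x" means the daily census at age x first
recorded it; sub-day timing is not modelled.

From the census counts `n_xj` (live, non-excluded individuals of age x in
stage j) and egg totals `E_xj`:

    s_xj = n_xj / n01                   age-stage survival
    l_x  = Σ_j s_xj                     age-specific survival
    f_xj = E_xj / n_xj  (0 if n_xj = 0) daily eggs per live stage-j female
    m_x  = Σ_j s_xj f_xj / Σ_j s_xj     daily eggs per live individual

Two-sex bookkeeping matters: males and individuals that die immature stay
in the denominator of `m_x`, so the net-maternity sequence collapses to
`l_x m_x = E_x / n01` and

    R0 = Σ_x l_x m_x = (number of females / n01) × (mean eggs per female).

That identity is exact and is exposed as
`net_reproductive_rate_from_counts`; it is also the conservation-of-eggs
invariant the test suite checks against the schedules.

The maximum observed age ω is cohort-specific (the greatest death age);
schedules are length ω+1 with `l_ω = 0`.

**Sex ratio.** The published treatment summaries print sex ratio values
equal to females/`n01`, although the column is labelled ♀/(♂+♀). The
package computes both (`sex_ratio` and `sex_ratio_of_adults`) and reports
the `n01`-denominator one as the headline value; it never silently
reconciles the two.

**Censoring.** The data model carries a censored flag (alive at last
observation). Censored individuals contribute survival exposure through
their last observed day for `s_xj` and are excluded from death-derived
summaries; the analyses here assume an uncensored cohort and constructing
a cohort with censored records emits a warning.

## Demographic parameters

The intrinsic rate of increase solves the Euler–Lotka equation in the
age-counted-from-zero convention,

    Σ_x e^{-r(x+1)} l_x m_x = 1,

whose left side is strictly decreasing in r, so iterative bisection is
monotone and guaranteed. Defaults: bracket [-0.5, 1.5] day⁻¹ (covering
biologically plausible arthropod rates on both sides of zero), residual
tolerance 1e-10, maximum 200 halvings (the default bracket reaches
machine precision in ~60). The solver records the achieved residual,
iteration count, and bracket. `λ = e^r` and `T = ln(R0)/r` are evaluated
from the same point estimates to full floating precision; `T` is NaN at
`r = 0` (undefined at replacement) rather than zero.

Point estimates are computed from the full-cohort schedules. Published
tables of this method family usually print bootstrap means, so
small discrepancies from the closed-form identities (e.g. a printed λ
that is not exactly `e^r` of the printed r) are expected; the reporting
layer therefore writes both the point estimates and the bootstrap means.

## Bootstrap inference

The resampling unit is the whole individual life history — the only unit
consistent with the cohort design. Each replicate draws `n01` individuals
with replacement, recomputes schedules and parameters, and the SE is the
SD over valid replicates, with percentile CIs. Default `B = 100,000`
matches the published procedure; the tests and analysis drivers use
10³–10⁴ for desk-scale runtime, and B is a flag everywhere.

Undefined replicates (e.g. no females drawn, so APOP/TPOP/fecundity have
no value) are dropped from that parameter's distribution and counted in
`b_valid`; `R0 = 0` is a defined outcome and such replicates are kept for
R0. The paired test pairs replicate b of cohort A with replicate b of
cohort B (independent resamples, common index) and declares significance
when the percentile CI of the differences excludes zero.

Each parameter draws from its own RNG stream derived from the master seed
and a fixed parameter id, so adding parameters to a run never perturbs
existing draws and fixed seeds are bit-reproducible. Internally the
resampler reduces every parameter to per-individual arrays (egg-by-age
rows, lifetime totals, timing scalars), so a replicate is a row-gather
plus a reduction, and the intrinsic rate is solved by a vectorized
bisection over the replicate net-maternity matrices; the test suite
checks this path replicate-for-replicate against a literal
rebuild-the-cohort-and-recompute oracle on the same index draws.

**Compact letter display.** Treatments share a letter iff not
significantly different; letters are the maximal cliques of the
not-different graph. A non-transitive significance pattern yields
overlapping letters (noted in the log) rather than an error.

## Population projection

The projection is the deterministic expected-value renewal recursion over
the empirical schedules, with `φ_x = Σ_j s_xj f_xj`:

    B(t)   = Σ_{x=0}^{min(t-1, ω)} φ_x B(t-1-x),   B(0) = initial eggs
    N_j(t) = Σ_{x=0}^{min(t, ω)}   s_xj B(t-x)

Eggs laid by mothers of age x during day t−1 join the age-0 egg class on
day t. This day-of-laying convention is forced by consistency:
substituting `B(t) = C e^{rt}` reproduces the Euler–Lotka equation with
exponent −r(x+1) term for term, so the projection's trailing log-growth
converges to the bisection solver's r (the module's primary
cross-validation, asserted to |Δ| < 10⁻³ at horizon 300). The same-day
alternative would discount one day less and overshoot r by ≈ r/T.
The recursion is linear in the pulse and produces fractional expected
individuals — smooth exponential trajectories, not an agent-based
simulation; stochastic projection is out of scope.

## Synthetic cohort generator

The generator emulates the study conditions: cohorts of n = 50 eggs per
treatment with stage-specific mortality, stage-duration distributions,
sex ratios, adult longevities, and a rise-peak-decline daily fecundity
schedule. Per individual, independently:

1. **Immature path** — for each stage, an integer duration from a
   discretized normal (rounded, truncated at 1 day) and a Bernoulli death
   draw with the stage's per-entrant probability. An individual dying in
   a stage dies on the day it would have molted (it occupies the stage
   for its full drawn duration) — the convention shared with the analytic
   mode.
2. **Adulthood** — a Bernoulli sex draw; adult longevity per sex from a
   discretized normal; females draw an adult pre-oviposition period
   (APOP, discretized normal, minimum 1 day).
3. **Fecundity** — daily counts are Poisson around a triangular curve
   over adult age (0 at emergence, peak at adult day 5, declining to 0 at
   a preset-specific end day of 20–26), gated by the individual's APOP
   and truncated at death. A negative-binomial option provides
   overdispersion. The curve's scale is calibrated once per spec so the
   *expected* lifetime eggs per female equals the preset's fecundity
   target under the APOP and longevity distributions.

Preset parameter sources: per-entrant stage death probabilities are the
published bracketed stage-death counts divided by the expected entrants
(control 1,0,1,1 of 50; paw1 10,7,0,4 — whose 42% total the preset
follows, documenting the conflict with the printed 52% headline; paw2
6,6,1,0); sex probabilities are the published female fractions of
surviving adults (41/47, 21/29, 25/37), which make the expected
female/`n01` ratio hit the printed 0.82/0.42/0.50; duration and longevity
means come from the published stage tables. Duration dispersions default
to small SD (0.5–0.8 d) — the published tables give SEs of means, which
bound but do not identify individual-level variance — and adult longevity
SDs default to 3–5 d. With these choices the presets reproduce, in
expectation, the published immature mortalities, sex ratios, fecundities,
and hence (by the two-sex identity) the published R0 values; large-cohort
runs land within a few percent of the published r as well.

What the generator does **not** emulate: correlation between development
speed and fecundity (individuals are independent in all traits),
day-to-day autocorrelation in laying, male remating dynamics, or any
mechanism of the treatment effect. Realized APOP can exceed the drawn
APOP when early low-rate laying days draw zero eggs, so generated APOP
means run ~0.2–0.4 d above the printed targets; fecundity, mortality and
sex-ratio targets are exact in expectation. Passing tests on synthetic
cohorts therefore validate the estimators and their identities, not the
biological claims of any particular dataset.

**Analytic mode.** With all dispersions zero the spec implies closed-form
schedules (`expected_schedules`): piecewise-constant `s_xj` with cohort
fractions multiplying by (1−q_j) at each molt, and `f` equal to the
calibrated curve. These are the oracle for parameter-recovery tests
(generate a cohort, compute r, compare with the analytic r).

## Problem sizes and numerical choices

- Law-of-large-numbers and R0-recovery suites use generated cohorts of
  5,000–50,000 individuals; the recovery check uses n = 50,000 so its
  Monte-Carlo SD (~0.6%) sits well inside the 2% agreement asserted.
- Bootstrap calibration: the paired test's type-I error is measured over
  500 independent null pairs (both cohorts from the control preset) at
  B = 2,000 and asserted to lie in [0.02, 0.09] around the nominal 5% —
  the band covers Monte-Carlo error at 500 trials plus the usual mild
  small-n inflation of percentile bootstrap tests at n01 = 50.
- Grid-scan cross-checks of the bisection solver use a 10⁻⁶ step.
- Ties and degenerate inputs: `f_xj = 0` where `n_xj = 0`; `m_x = 0`
  where `l_x = 0`; empty statistic sets yield NaN with explicit
  `defined`/`degenerate` flags, never silent zeros; `B = 1` bootstrap
  yields SE = 0 flagged degenerate.
- Fractional eggs are disallowed in data; an oviposition day requires ≥ 1
  whole egg.

## Known limitations

- Exact reproduction of the published Tables (SEs, bootstrap means, and
  the printed 60-day projection totals) requires the study's raw cohort
  data, which are unpublished; the reproducible quantities are the
  arithmetic identities among printed values, the count-derived
  proportions, and the property suites documented above.
- Censored records are carried but the estimators assume uncensored
  cohorts, matching the study design (all individuals followed to death).
- The projection has no density dependence, immigration, or mating
  structure; it is the linear renewal model implied by the schedules.
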