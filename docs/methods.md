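# Methods

## Generative model

Each simulated applicant *i* carries `k_latents` unobservable characteristics
ℓ᎐ᵢⱼ ~ N(0, 1), iid across applicants and traits (default k = 4; at least two
are required, since compensation between traits is the phenomenon of
interest).  Degree completion treats the traits as independent hurdles:

1. **Sufficiency.** Each trait contributes a sufficiency probability
   sᵢⱼ = Φ((ℓᵢⱼ − μ)/σ), the probability that the applicant's level on that
   single trait is adequate for finishing the degree.  Defaults μ = −1,
   σ = 1, so a median applicant has per-trait sufficiency Φ(1) ≈ .84 and a
   trait one standard deviation below the mean still has Φ(0) = .5.
2. **Product rule.** P(complete)ᵢ = ∏ⱼ sᵢⱼ.  Any zero sufficiency makes
   failure certain; all-ones make completion certain.  The population mean
   is E[Φ((L−μ)/σ)]ᵏ = Φ(−μ/√(1+σ²))ᵏ, ≈ 33.4 % at the defaults
   (`expected_population_completion` evaluates the 1-D integral by
   quadrature rather than hard-coding the closed form, so non-default μ, σ
   are covered).
3. **Outcome.** Completion is one Bernoulli draw per applicant.  Alternative
   completion functional forms (e.g. additive) can be injected by
   subclassing, but only the product rule is validated.

**Predictors.** The application shows four percentile scores — Test, Grades,
Letters, Statement.  A predictor's raw score is a row of the factor-loading
matrix Λ applied to the latents, plus N(0, noise_sd²) measurement error
(default noise_sd = 1).  Rows of Λ are constrained to unit sum of squares so
all predictors share the same signal-to-noise ratio; `validate_loadings`
flags deviations above 0.02, a tolerance that accommodates matrices printed
to two decimals (the correlated matrix's Grades row sums to 1.0086 and is
used exactly as printed, without renormalisation).  Raw scores are then rank
ordered across the whole pool: percentile = 100·rank/n with ranks 1…n, a
continuous value in (0, 100].  An *invalid* predictor skips all of this and
draws its percentile Uniform(0, 100], independent of the latents.  Under a
unit loading and unit noise, two repeat measurements of the same applicants
correlate 0.5 on the raw scale and (6/π)·arcsin(0.25) ≈ .483 on the
percentile scale (the bivariate-normal rank-correlation identity);
`test_retest_reliability` estimates this by direct simulation and is checked
against the identity in the tests.

**Admissions.** The canonical policy accepts the top ⌊f·n⌋ applicants by the
weighted sum of the four percentiles (default f = 0.10, unit weights; 1.3 on
Test models over-weighting, 0 models dropping the Test).  Floor rounding was
chosen because "top fraction" does not specify a rounding rule and floor is
deterministic.  Ties — measure-zero for continuous scores but possible in
degenerate inputs — are broken by a random key from a dedicated substream.
Two cutoff variants model a hard Test threshold with the committee blind to,
or aware of, the Test beyond the threshold; they are qualitative
demonstrations with no canonical cutoff value and default to the 50th
percentile.

## Randomness and reproducibility

A single root seed is expanded into named substreams
(`latents`, `noise:<predictor>`, `ties:<predictor>`, `invalid:<predictor>`,
`outcomes`, `select:<policy>`) via `SeedSequence` spawn keys hashed from the
stream name.  Consequences that the tests rely on:

* the same root seed yields the *same cohort* under every policy, so policy
  comparisons are paired;
* outcomes depend only on the latents and the `outcomes` stream, so two
  scenarios under one seed share identical applicants and completions;
* swapping a valid Test for an invalid one leaves every other predictor
  column bit-identical — the no-Test policy then accepts exactly the same
  students, which the suite asserts exactly.

## Summary statistics

`completion_curve` bins applicants by ⌈percentile⌉ into integer bins 1…100
and reports, per bin, the acceptance rate (accepted/total over all
applicants) and the completion rate (mean outcome over accepted only).
`curve_correlation` and `regression_slope` treat each occupied bin as one
unweighted observation — they describe the plotted per-percentile series,
not individual-level outcomes, which is the only reading under which the
accept-everyone cells produce r ≈ .96 rather than the individual-level ≈ .15.
Significance uses the t distribution with (bins − 2) df.  Slopes are kept in
completion-proportion per percentile internally and ×100 (percent per
percentile) in outputs.

**Bin inclusion.** A bin enters the curve statistics only if it holds at
least `min_count` = 10 accepted students *and* its acceptance rate is at
least `min_rate` = 1 %.  The count floor alone is not scale-invariant: as the
simulated population grows, ever-deeper low-Test bins — populated only by
extreme-compensation admits — keep crossing the count threshold, and the
near-zero correlations drift with n.  The 1 % rate floor pins the included
span (≈ 79 of 100 bins for the correlated scenario at 10 % acceptance,
matching the visible span of the acceptance curve) regardless of n.

**Known sensitivity.** The near-zero curve correlations of the over-weighted
and correlated scenarios are knife-edge quantities: the positive rise at the
low-Test end and the collider-driven decline at the top nearly cancel, so
the Pearson r over bins moves by ±0.2 or more as the inclusion window shifts
by a few bins, and per-bin Bernoulli noise attenuates it toward zero at
small n.  Zero crossings of the selectivity sweep should therefore be read
as "within a grid step or two of 10 % acceptance", not as exact.  The
test-vs-rest collider correlation is reported in two readings — Pearson r of
Test against the *sum* of the other three percentiles (≈ −.60 for the
invalid-Test scenario at 10 % acceptance) and the *mean of the three
pairwise* correlations (≈ −.248); the sum compounds the effect across
predictors, so the two differ by more than a factor of two.

## Problem sizes

Defaults are 10⁶ applicants for the policy grid and 2×10⁵ per point for the
80-point selectivity sweep, with every tolerance in the tests scaled to the
Monte-Carlo error at those sizes (completion percentages ±0.2 pp sd;
binned-curve r ± ~0.13 sd per cohort, hence averaged over seeded
replicates).  The acceptance script uses 3 replicates of 10⁶ for completion
percentages and 8 replicates of 4×10⁶ for the two curve-correlation blocks,
where attenuation bias is material at smaller n.

## What the generator does and does not emulate

The pool is an idealisation: latents are exactly Gaussian, independent, and
equally weighted in completion; measurement error is Gaussian and
homoscedastic; applicants neither self-select into applying nor decline
offers; a single institution selects in one round.  Passing tests therefore
demonstrate the *logic* of compensatory-selection distortion — that
conditioning on a composite induces negative dependence among its inputs and
can reverse or erase a predictor's observed validity — not the magnitude of
any effect in real admissions data, where trait distributions, differential
measurement reliability, multi-school markets, and applicant behaviour all
move the numbers.

## Known limitations

* Completion is binary; time-to-degree and intermediate milestones are out
  of scope.
* Multiplicative (product-based) composite scoring and non-product
  completion rules are configuration hooks, not validated paths.
* The near-zero curve correlations are reproducible only up to the window
  sensitivity discussed above; their sign at exactly 10 % acceptance is not
  a stable property of the model.
* No correction methods for range restriction or collider stratification
  are implemented; the package generates the pathology, it does not undo it.
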