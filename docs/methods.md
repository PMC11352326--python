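# Methods

## Model overview

`targetheight` treats adult standing height per sex as normally
distributed in a reference population, `H_sex ~ N(μ_sex, σ_sex)`, and a
child's adult height as a linear function of the parents' *peak* heights
plus within-family noise. The clinical prediction pipeline composes four
deterministic maps:

1. `peak_height`: undo age-related shrinkage of each parent;
2. `to_common_scale`: sex correction onto a shared scale;
3. `mid_parental`: arithmetic mean of the two common-scale values;
4. regression to the mean on the standardized scale, then inverse sex
   correction to the child's sex.

All heights are carried as floating-point cm; rounding to 0.1 cm (the
measurement precision of the underlying data) happens only at
presentation.

## Reference population

The shipped default (`CDC_DERIVED`) is *derived*, not copied from a chart
file: σ_female = 10.6/1.64 ≈ 6.46 cm and σ_male = 11.7/1.64 ≈ 7.13 cm
(from the convention that ±1.64 SDS spans ±10.6 cm for women and ±11.7 cm
for men), μ_female = 163.0 cm (female median), and μ_male fixed by
requiring 163 cm to sit at the male 3rd percentile:
μ_male = 163 − Φ⁻¹(0.03)·σ_male ≈ 176.42 cm. These four numbers reproduce
the package's worked examples self-consistently and can be overridden by
a YAML/JSON config.

Percentile ↔ height conversion uses the normal quantile function by
default. When a `PercentileTable` (a growth chart's age-20 row) is
supplied, monotone piecewise-linear interpolation on the probit scale is
used instead, which respects chart skewness between the tabulated
percentiles.

### Growth-chart fixture

`data/cdc_statage_age20_synthetic.csv` is a **synthetic** stand-in for the
CDC 2000 stature-for-age chart's final (240-month) row. Its female column
is the `CDC_DERIVED` normal quantiles at the nine standard percentiles;
its male column is the unique linear-in-height profile matching the
published male−female anchors (12.2 cm at P3, 14.7 cm at P97). By
construction it reproduces the zero-intercept multiplicative factor
(1.0826 → 1.08) and the linear sex-difference profile; it is *not* a copy
of the CDC file and should not be used as a clinical chart.

## Age (shrinkage) correction

Cumulative height loss is `s(a) = accel_sex · (a − 30)²` for a > 30 and 0
otherwise — a shrinkage *rate* increasing linearly with age ("accelerates
at a constant rate"), continuous at onset, monotone and convex beyond it.
The published per-sex coefficients of the longitudinal model this mirrors
are not available, so the default uses a single acceleration for both
sexes, `2.7/(62 − 30)² ≈ 0.0026367 cm/y²`: a calibration anchored on the
observation that uncorrected parents (age 62 ± 5 in the reference cohort)
bias the target 2.7 cm low. This calibrated default is a documented
stand-in; both accelerations and the onset age are configurable. Children
in a clinical query pass through the same correction, which is a no-op at
or below age 30.

## Sex correction schemes

| preset | map (female → common) | common scale |
|---|---|---|
| `tanner13` | + 13 cm | male-equivalent cm |
| `add10.82-sample` | + 10.82 cm | male-equivalent cm |
| `mult1.08` | × 1.08 | male-equivalent cm |
| `mult1.066-sample` | × 1.066 | male-equivalent cm |
| `zscore-cdc` | (h − μ_F)/σ_F | SDS (dimensionless) |
| `zscore-sample` | (h − μ̂_F)/σ̂_F | SDS (dimensionless) |

Males pass through unchanged on the cm scales. Every scheme's inverse is
exact (round-trip identity to 1e−9 is a tested invariant). The additive
and multiplicative cm schemes agree only at h = 13/0.08 = 162.5 cm and
diverge linearly away from it, which is why the additive scheme's errors
concentrate at the height extremes. The `-sample` constants (10.82 cm,
1.066) are published cohort-specific values shipped as constants; the
`zscore-sample` reference is estimated per-analysis from the age-corrected
cohort, since those means/SDs are not otherwise distributable.

## Regression to the mean

On the standardized scale, `z_target = β·z_midparent + c` with shipped
defaults (β, c) = (0.79, −0.077), the fitted child-on-midparent relation
under z-score correction. For cm-scale schemes the male-equivalent
midparent is standardized against the *male* reference parameters, the
map applied, and the result de-standardized — making all schemes
structurally parallel. With β < 1 the map pulls extreme midparents toward
the center: |z_target| < |z_midparent| whenever |z_midparent| >
|c|/(1 − β) ≈ 0.37.

## Deviation probability and cutoffs

Within a family, siblings' adult heights scatter around the (age-, sex-,
regression-corrected) target approximately normally, with SD ≈ 4.5 cm
(sons) / 4.2 cm (daughters) within families, and 4.7 / 4.4 cm when all
children are pooled. The pooled values are the clinical default: a child
presenting in the clinic is compared against all-family variability. For
a signed deviation d (projected − target), the package reports the
one-sided tail `P(D ≤ d)` (for d < 0), the two-sided value (exactly twice
the tail), and the verdicts of the classical bands (±10/±9 cm; ±1.64 SDS
converted through the reference SD) for comparison. Probabilities are
displayed rounded to the nearest percent. Note that Normal(0, 4.7) puts
1.7% below −10 cm and Normal(0, 4.5) puts 1.3%; a published intermediate
figure of 1.5% for boys matches neither basis exactly, so the package
simply reports the computed value for the basis selected.

## Cohort analysis

`MidparentModel` regresses each child's common-scale (optionally
age-corrected) height on the family's common-scale midparent, one
observation per child — not family means, so large families weigh more,
matching the per-child scatter view. The slope is the midparent
heritability estimate; `systematic_error` is mean(child − midparent) on
the common scale and is therefore reported in cm for additive or
multiplicative schemes and in standardized units for z-score schemes (the
results object labels the units). Family-level regression to the mean
(`family_level_rtm`) is the separate family-mean view: per family, mean
child minus midparent against midparent, with Pearson r and a two-sided
t-test p-value (n − 2 df). `within_family_residuals` measures sibling
scatter around each family's corrected target on the child's own sex
scale; families contribute a within-family SD for a sex only with ≥2
children of that sex, and a switch (`rtm=None`) measures residuals around
the raw midparent instead, as a sensitivity analysis. Missing parental
ages abort the analysis unless `assume_peak=True` is passed explicitly —
a silent fallback would quietly reintroduce the 2.7 cm bias.

## Synthetic cohorts

`simulate_cohort` draws parents' peak standardized heights from a
bivariate standard normal with spousal correlation 0.2 (the real cohort's
spousal correlation is unpublished; 0.2 is a typical assortative-mating
value and is configurable, including 0), parental ages from N(62, 5²)
(clipped to [40, 100]), family sizes uniform on 7–16, child sexes
Bernoulli(1/2), and each child's standardized peak as
`β·z_midparent + c + ε` with ε ~ N(0, sd_sex/σ_sex), sd = 4.5/4.2 cm and
generative intercept c = 0 by default. Measured heights are peak minus
the shrinkage of the person's simulated age (children uniform on 20–45,
so child-side age correction is a near-no-op for most). No secular trend
is generated by default — intergenerational differences arise purely from
parental shrinkage — but a constant `secular_trend` hook exists for
sensitivity tests.

What the simulator does **not** emulate: measurement replicates,
genotypes, non-normal height distributions, family-specific residual
variances, and any real secular trend. Passing tests on synthetic cohorts
therefore demonstrate parameter recovery and internal consistency of the
pipeline, not the empirical values of the controlled-access family data;
the published real-cohort regression rows are treated as documentation
only.

## Numerical choices and problem sizes

- OLS fits via `statsmodels`; the test suite checks them against a
  closed-form sums-based oracle to 1e−9.
- The zero-intercept sex factor uses the closed form Σmf/Σf².
- Degenerate inputs: zero midparent variance and all-zero female heights
  raise; constant family differences make the regression-to-the-mean
  correlation undefined (reported as NaN); a constant residual-SD profile
  reports r = 0.
- Property tests (hypothesis) run derandomized; simulation-based tests
  use fixed seeds and 3·SE or χ² 99% acceptance bands.
- Simulated problem sizes in the test suite — 200–1000 families for
  recovery checks, 4000 for moment-convergence checks — keep the full
  suite around five seconds while leaving Monte-Carlo bands comfortably
  narrow.

## Known limitations

- The shrinkage default is a single calibrated acceleration, not a fitted
  longitudinal model; per-sex coefficients should be supplied when known.
- The normal model ignores growth-chart skewness except when a percentile
  table is interpolated directly.
- Residual SDs carry ~20% sampling uncertainty (23 families), which the
  probability reports do not propagate.
- The reference-cohort parameters derive from families of
  predominantly single ancestry; portability of the residual-scatter
  constants to other populations is an open empirical question.
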