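# Methods

This note documents the statistical model behind `lpoagree`, the choices
made where the design was genuinely open, and what the synthetic-data tests
do and do not establish about real data.

## Quantification model

The assay treats each extract phase as contributing one absorbance ratio per
analyte, normalised by that phase's 220 nm absorbance (isolated double
bonds), so the measure is insensitive to the total lipid yield of a phase:
multiplying all four absorbances of one phase by any c > 0 leaves DC, TC and
SB unchanged. The correction coefficients (0.14, 0.16, 52) are treated as
fixed assay constants applied to the **sum** of the two phase ratios. The
trailing-coefficient typography of the source equations admits a reading in
which the coefficient multiplies only the lower-phase term; the sum reading
was adopted because the three equations are structurally parallel and the
coefficients are described collectively as correction coefficients for the
products, not for a phase. Concentrations are relative units; no molar
calibration is attempted.

Negative net absorbances (possible after blank subtraction) are rejected by
default so instrument problems surface early; `clamp_negative_od` clamps
them to 0 with a logged warning instead. Computation never rounds;
presentation rounding (2 dp for DC/TC, 1 dp for SB) exists only in report
writers.

## Agreement model

All agreement statistics operate on one stratum at a time (analyte ×
cycle-phase × timepoint), with x = plasma, y = saliva, differences oriented
saliva − plasma.

**OLP regression.** The slope is sign(r)·s_y/s_x and the intercept
ȳ − b·x̄. The analytic slope CI is the standard geometric-mean-regression
interval: with B = F₁₋α(1, n−2)·(1−r²)/(n−2), the limits are b(√(B+1) ∓ √B)
(for b > 0; the order is normalised for negative slopes). The intercept CI
evaluates a = ȳ − b*·x̄ at the opposing slope limits. The source study names
OLP regression but not a CI construction; this F-based interval is the
standard analytic choice for geometric-mean regression, and a percentile
bootstrap of the same estimator (`ci_method="bootstrap"`, default 20,000
resamples, degenerate resamples redrawn) is provided as an independent
route. Empirically at n = 12, ρ = 0.85 the analytic slope CI covers the
true slope in ≈94.9% of replicates and the intercept CI covers the true
intercept in ≈94.1% — both computed by the test suite. Per-dataset bootstrap
widths scatter around the analytic width (they depend on the point
configuration, not only the sample moments); the two routes are compared on
expected widths over replicate datasets, which agree within a few percent.

**Bland–Altman.** Limits of agreement use the fixed multiplier 1.96 (the
normal 95% convention), never a t quantile; t quantiles on n−1 df appear
only in the CI half-widths: t·s_d/√n for the mean difference and
t·s_d·√(1/n + 1.96²/(2(n−1))) for each limit. Sample SDs use the n−1
denominator throughout. When s_d = 0 the limits collapse to the mean
difference; the result is flagged `degenerate` (LoA CIs undefined) rather
than raised, since an exactly-constant offset is still interpretable: its
point mean-difference "CI" classifies differential bias, and the
differences-on-means slope is exactly 0, so no proportional bias.
Differential bias ⇔ 0 outside the mean-difference CI; proportional bias ⇔ 0
outside the differences-on-means slope CI (equivalently p < α two-sided).

**Multiplicity.** Bonferroni adjustment is applied to correlation p-values
only, and only when a family size > 1 is passed; the family is configurable
because the original analysis states the correction was applied "if
required" without defining the family. Default family in the CLI examples
is 3 (the number of analytes per stratum).

## Inference and power

Effect sizes are Cohen's d_z (mean of within-pair differences over their
SD) — the only variant under which a paired t-test with n pairs has
noncentrality d·√n, and hence the only one that makes a minimum detectable
effect of 0.89 at n = 12, α = 0.05, power 80% arithmetically coherent. All
tests are two-sided by default. Power is P(|T′| > t_{n−1,1−α/2}) with T′
noncentral t; the minimum detectable effect inverts this by root-finding on
d ∈ (0, 10] to 1e-6 accuracy in power (Brent's method on the power gap).
scipy's noncentral-t CDF returns NaN in a narrow band of large
noncentrality; the implementation replaces that numerically negligible tail
with its limit. Shapiro–Wilk is a gate that warns and annotates rather than
halts: real data may fail normality, and the downstream statistics remain
defined even if their coverage statements weaken.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes — not
the biology. Per analyte: plasma is Gaussian around a stratum mean with an
additive subject random intercept (ICC 0.5 by default) shared across
strata, so pre/post pairs are within-subject correlated and paired tests
are meaningful; saliva is the conditional mean given plasma at correlation
ρ plus independent noise (noise SD defaults to s·√(1−ρ²), making the
marginal correlation exactly ρ), optionally distorted by differential
(additive) and proportional (multiplicative) bias. Stratum means shift by
`exercise_effect_d` and `phase_effect_d` plasma SDs. With ICC 0.5 the
within-subject pre/post difference SD equals the plasma SD, so
`exercise_effect_d` is also the paired-design d_z being simulated.

Defaults (n = 12 subjects; ρ = 0.82/0.85/0.90 and pre-follicular means
0.50/0.40/220 relative units for DC/TC/SB; exercise d = 1.5; phase d = 0.6,
1.0 for SB): correlations sit in the high-agreement range such a validation
study reports, DC/TC live on a ~0.3–0.7 and SB on a ~150–350 relative-unit
scale consistent with the intercept magnitudes such assays print, exercise
effects are strongly detectable at n = 12, and the luteal phase reads
higher, most markedly for SB. These are plausibility anchors chosen once;
they are not published study values, which were never released per-subject.

Marginals are Gaussian (matching the all-data-normal regime the method
assumes); a `lognormal` switch exists for robustness testing. Truncation at
zero is by redraw, not clamping, preserving distributional shape near the
bulk; redraw counts are logged. Everything is driven by one seed:
identical configs are bit-identical on a platform, and numerically equal to
~1e-12 across platforms.

`cohort_to_od` back-generates optical densities as the exact right-inverse
of the quantification equations: the total ratio-sum c/k is split between
phases by a `split` fraction against fixed 220 nm absorbances. Absorbances
above a cap (default 3.0, a typical spectrophotometer ceiling) raise an
infeasibility error; with the default generator a 220 nm absorbance of 0.5
(a more dilute extract) keeps every channel under the cap.

**What passing tests show — and don't.** The simulation studies establish
that the estimators are calibrated under the generator's assumptions
(bivariate normality, one value per subject and stratum, no measurement
drift, missingness absent). They do not establish robustness to skewed
analytes, outliers, repeated specimens per subject, or heteroscedastic
differences (for which Bland–Altman recommends transformation first — not
modelled here).

## Numerical and scale choices

- Degenerate inputs (zero variance, r = 0, n below the minimum) raise typed
  errors; the batch runner records per-stratum failures and continues.
- Simulation sizes in the test suite (e.g. 5,000 coverage replicates at
  n = 12, 20,000 paired-t replicates, 1,000 round-trip cohorts) were chosen
  so Monte-Carlo error is several times smaller than the asserted bands.
- The shipped default fixture seed (2) is one where the no-bias cohort
  shows no bias flag in any stratum — the regime the generator encodes; at
  nominal α ≈ 5% per flag, individual no-bias cohorts occasionally flag by
  chance, which the calibration tests quantify instead of hiding.
- Row order of all reports: analyte (DC, TC, SB) × phase (F, L) ×
  timepoint (pre, post).

## Known limitations

- The OLP intercept CI (endpoint substitution) is mildly anti-conservative
  (≈94% empirical coverage at n = 12); the bootstrap route is available
  where that matters.
- No non-parametric fallback (e.g. Wilcoxon) and no mixed-effects analysis
  of the full 2×2 design; strata are analyzed independently by design.
- The correction coefficients' physical provenance is not modelled; they
  are overridable constants.
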