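# Methods

## Data model

CT tables are wide: one row per sample (reaction/cDNA preparation), one
column per gene, cells holding cycle-threshold values in cycles (lower
CT = more starting template). A table carries at most one per-row
annotation: a categorical group label (control-vs-condition designs) or
a known input-RNA amount in ng (serial-dilution designs). Missing or
"undetermined" reactions are explicit missing values. Reference-gene
normalization requires at least two genes, and every per-group summary
uses the sample standard deviation (n − 1 denominator), so groups need
at least two replicates.

Missing-value policy (the upstream convention leaves this open, so it
is this package's choice): in `separate_tube` mode missing cells are
excluded pairwise from each gene's mean/SD; in `same_tube` mode a row
missing either the target or the reference gene is dropped entirely,
because the within-row pairing is what the mode exists to preserve.

## Quality assessment (dilution series)

For each gene, ordinary least squares of CT on log₁₀(amount) over all
replicate-level points gives the standard curve CT = b + m·log₁₀(amount).
R² is the squared Pearson correlation (equivalently 1 − SSE/SST for
simple OLS; defined as 0 when the response is constant). The
amplification efficiency is E = 10^(−1/m): perfect doubling every cycle
gives m = −1/log₁₀2 ≈ −3.32 and E = 2.

The comparative model additionally assumes target and reference amplify
equally efficiently. The check regresses the per-row
ΔCT = CT(target) − CT(reference) on log₁₀(amount); replicates within a
dilution are paired by row (one row = one replicate set). Under equal
efficiencies the slope is 0; because balanced row pairing makes the
ΔCT-trend slope exactly the difference of the two per-gene curve
slopes, the E = 10^(−1/m) criterion is applied to the per-gene curves
(where it is meaningful) and the ΔCT trend is reported as slope/R²
separately. R² of a near-flat trend is intentionally uninformative and
is reported without a threshold.

Quality thresholds are advisory and configurable, never enforced:
|ΔCT-trend slope| > 0.1 or per-gene efficiency outside [1.8, 2.2]
produce warnings. The defaults are this package's choice of the
field's usual rules of thumb ("slope very small", "E close to 2").
Efficiency is also exposed on the (E − 1)·100 percentage scale.

The per-dilution ΔCT summary (the numeric content of the trend plot)
reports mean ΔCT with SD √(s₁² + s₂²) from the two genes' per-dilution
SDs — the separate-tube convention, which is what published summary
tables of such experiments print.

## Relative quantification

**Comparative (ΔΔCT) model.** Per group, `separate_tube` computes each
gene's mean and SD first: ΔCT = mean(target) − mean(reference) with
s = √(s₁² + s₂²); `same_tube` computes per-row ΔCTs, then their mean
and sample SD. Then ΔΔCT = ΔCT(group) − ΔCT(calibrator group), and the
relative expression is 2^(−ΔΔCT). Each group's interval carries its
*own* s only — the calibrator's error is not re-propagated into other
groups. This is the convention that makes the calibrator's result
exactly 0 ± its own replicate scatter (fold change 1), and it is the
only rule consistent with the worked example the test-suite reproduces
(the condition group's ΔΔCT SD equals its ΔCT SD). The interval is
asymmetric on the fold-change scale: (2^(−(ΔΔCT+s)), 2^(−(ΔΔCT−s))).

**Relative standard-curve model.** Every CT is inverted through its
gene's curve, amount = 10^((CT − b)/m) (always positive). Per group,
`separate_tube` normalizes mean amounts, X̄(target)/X̄(reference), with
CV combined as cv = √(cv₁² + cv₂²) and SD = cv·X̄; `same_tube` ratios
within each row first. The calibrated value divides by the calibrator
group's normalized amount; its error is the group's own CV times the
calibrated value (again, no calibrator re-propagation), and the
interval is value ± SD, floored at 0. When all genes amplify with
E = 2 the two models agree up to replicate noise, which the test suite
checks on synthetic data.

Point estimates in the two modes coincide on complete balanced data
(subtraction commutes with averaging); only the error terms differ.
Rounding happens at presentation time only.

## Significance testing

The per-row ΔCT removes the input-amount nuisance, and the difference
in mean ΔCT between a condition and the control group is the ΔΔCT, so
testing ΔΔCT = 0 is a two-sample location problem:

* **t-test** — Welch by default (`pooled=True` for the classical
  variant; on balanced equal-variance designs the two coincide), with
  the t-based 95% CI. Welch is the default because comparability of
  variances across conditions is exactly the assumption one often
  cannot check in small qPCR designs.
* **Wilcoxon rank-sum** — location estimate is the Hodges–Lehmann
  median of all n·m pairwise treatment-minus-control ΔCT differences;
  the CI inverts the rank-sum test over the ordered pairwise
  differences. The null U distribution is computed exactly (counting
  recurrence) when n·m ≤ 400 and there are no ties, otherwise the
  normal approximation selects the order statistics; p-values come from
  `scipy.stats.mannwhitneyu` under the same exact/asymptotic rule. The
  exact interval construction matches R's `wilcox.test(conf.int=TRUE)`,
  which the tests verify against frozen values computed with R 4.3.3.
* **Linear model** — OLS of ΔCT on treatment-coded group indicators
  with the control group as baseline; works for any number of groups,
  each non-baseline coefficient being that group's ΔΔCT with a t-based
  CI. On balanced two-group designs the coefficient equals the
  difference of group means exactly. The model is fit on ΔCT rather
  than on raw CT with a gene × group interaction; the two
  parameterizations give the same contrast in the two-group case and
  the interaction form is not implemented.

Estimates are oriented as treatment − control, so negative ΔΔCT means
up-regulation in treatment. The confidence level defaults to 95%.
Multiple target genes are tested independently with no correction by
default; `adjust_p=True` applies Benjamini–Hochberg across genes as an
optional extension.

## Synthetic data

Generators invert the standard-curve relation: a gene with efficiency E
and intercept b at template amount a yields
CT = b − log₁₀(a)/log₁₀(E) plus additive Gaussian noise on the CT scale
(the standard error model for cycle thresholds; no heteroscedasticity).
Everything is reproducible from an integer seed. The dilution generator
can recentre noise within each (gene, dilution) cell so per-dilution
means equal their noiseless values exactly — useful for deterministic
fixtures. Synthetic data emulate replicate scatter and known fold
changes but not real-data pathologies (pipetting outliers, inhibition,
plate effects, heteroscedastic noise at high CT), so passing tests show
correctness of the computations, not robustness to such artifacts.

The packaged datasets:

* `ct1` — 6 brain + 6 kidney separate-tube replicates of c-myc and
  GAPDH. One published kidney GAPDH replicate (24.18) is inconsistent
  with its own published column summary (22.66 ± 0.08): no six-value
  sample containing 24.18 can have that mean and SD, so it is treated
  as a transcription artifact. The default fixture replaces it with
  22.76, the unique value to two decimals reproducing both the mean
  and the SD; the verbatim series is available via
  `ct1(corrected=False)`.
* `ct3` — the seven-dilution triplicate series. Only per-dilution
  means ± SDs were published, so replicates are reconstructed
  deterministically as {μ − s, μ, μ + s}, which has exactly mean μ and
  sample SD s; balanced symmetric replicates leave all least-squares
  fits identical to fits on the means. The published dilution list
  repeats 0.02 ng twice; the last level is taken as 0.01 ng, completing
  the monotone series 1, 0.5, 0.2, 0.1, 0.05, 0.02, 0.01.
* `ct4_like` — a synthetic 24+24 control/treatment two-gene design with
  per-row ΔCT ~ Normal(5.2, 0.4) in controls and true ΔΔCT = −0.68
  (both genes E = 2; CT noise split equally between the genes so the
  paired ΔCT has SD 0.4). The real experiment it emulates was never
  published at replicate level, so statistical checks against it are
  property-based: estimator agreement, type-I error within [0.03, 0.07]
  at α = 0.05 over 1,000 null simulations, mean estimate within ±0.05
  of −0.68 and CI coverage within [0.92, 0.98] over 500 simulations —
  the simulation sizes used by the test suite.

## Numerical conventions and limitations

* SDs are sample SDs (n − 1) throughout; all arithmetic at double
  precision, rounding only for display.
* OLS via `scipy.stats.linregress`; a design with a single distinct x
  is rejected as degenerate.
* Fold changes and amounts are strictly positive by construction; the
  curve model's lower interval bound is clamped at 0 when the SD
  exceeds the estimate.
* Not implemented (out of scope): efficiency-corrected (Pfaffl-type)
  quantification, multi-reference geometric-mean normalization,
  absolute copy-number quantification, CT extraction from raw
  fluorescence, instrument-native file formats, and mixed-effects
  models.
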