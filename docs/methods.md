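# Methods

This note records the statistical procedure the package implements, the
choices made where the method admits more than one reasonable convention,
and what the synthetic-data tests do and do not demonstrate.

## Design and data model

The analysed design is two species crossed with a fixed temperature grid —
by default twelve levels from 0 to 38.5 °C in 3.5 °C steps — with exactly
one pooled sample per (species, temperature) cell. The 7 °C level is
excluded from analysis by default (its samples are loaded, flagged, and
dropped from design matrices), leaving 22 observations per transcript.
Regression designs of this kind gain power from the number of gradient
levels rather than from replication within levels; the cost is that
residual variance absorbs both biological and technical noise, which the
permutation calibration addresses globally rather than per transcript.

Expression enters as TPM and is modelled as `log(TPM + 1)` with the
natural log. The base is a pure rescaling of coefficients and does not
affect inference; `+1` keeps zeros finite. Species is coded 0/1 with the
lexicographically first label as reference, so results do not depend on
file row order. Temperature is used uncentred in °C; at this scale the
design matrix (largest column ≈ 38.5² ≈ 1.5e3) is well conditioned and the
coefficients match the natural parameterisation of the model equation.

## Per-transcript regression and significance

Each transcript is fit by OLS with six parameters: intercept, species
offset, linear and quadratic temperature, and species × temperature
(linear, quadratic) interactions. The per-transcript p-value is the
omnibus F-test of this full model against the intercept-only model — a
single p-value per transcript, which is what the downstream FDR adjustment
(Benjamini–Hochberg step-up, α = 0.05 by default) operates on. Degenerate
responses are given explicit conventions: a response with no variance gets
p = 1 (no evidence), a perfect non-constant fit gets p = 0.

All transcripts share one design matrix, so the implementation solves all
fits in a single pseudo-inverse product; a unit test checks the vectorised
path against statsmodels OLS fit by fit.

## Permutation-null calibration

Quadratic screening over tens of thousands of transcripts produces false
positives that BH alone does not fully control, because transcripts are
correlated and the omnibus test also reacts to species mean differences.
The calibration therefore re-permutes temperature labels uniformly within
each species block (preserving the per-species temperature multiset and
all species contrasts), refits every transcript, and counts BH-significant
transcripts at the same α. Over B replicates (default 100; replicate b
uses sub-seed `seed + b`) the 95th percentile of the counts — nearest-rank
convention, i.e. the ⌈0.95·B⌉-th order statistic, since counts are
integers — is the null expectation. The retained "true positive" set is
the top `max(0, observed − q95)` transcripts by ascending adjusted p
(ties: raw p, then transcript id). This count-difference rule is one
deterministic reading of "retain the transcripts exceeding null
expectation"; it is an interpretation, and it is deliberately conservative:
when the observed count does not exceed the null, nothing is retained.

One permutation per replicate is applied to all transcripts, preserving
between-transcript correlation in the null counts; independent
per-transcript permutation is available as an option and gives a narrower
null distribution.

## Model selection and predicted curves

Retained transcripts get a final model by stepwise AIC (backward with
re-addition, i.e. "both"), searching single-term moves over the five
non-intercept terms. The search respects marginality — a quadratic term
requires its linear term, an interaction requires its main effects, the
quadratic interaction requires the linear interaction and the quadratic
main effect — because non-hierarchical polynomials are not invariant to
re-centring the temperature axis. The species main effect is kept
throughout by default (removable via option): the species contrast is the
design's core comparison, not a nuisance to prune. Term sweeps follow a
fixed ordering and moves require a strict AIC improvement, so selection is
deterministic. For exact fits the residual sum of squares is floored at a
denormal-scale constant inside the AIC formula, which makes ties between
zero-residual submodels break toward fewer parameters.

AIC's per-term penalty of 2 is weak: on pure-noise data the search keeps
at least one spurious temperature term in roughly half to three quarters
of transcripts. This is a property of AIC selection itself, not a defect
of the search; the permutation calibration, not stepwise selection, is
what controls the size of the retained set.

Predicted per-species curves are the selected polynomial evaluated on a
dense 0.1 °C grid across the experimental range (discretisation error of
the argmax temperature ≤ 0.05 °C, far below the 10 / 31 °C category
boundaries); absent terms contribute zero.

## Shape classification

A species is *thermally responsive* for a transcript when its predicted
curve's range (max − min, log scale) strictly exceeds a flatness epsilon
(default 0.5 log units ≈ a 65 % change; a selected model with no
temperature terms is automatically non-responsive). A transcript
responsive in neither species is excluded; responsive in the other species
only is NotResp. Otherwise the Bimodal rule is tested first: predicted
expression at both grid extremes (0 and 38.5 °C — the only anchors the
"low and high temperatures" wording admits) must exceed the predicted
value at the 25 °C rearing temperature by at least `multiplier × SE`
(default multiplier 1, inclusive comparison). The dispersion used is the
transcript's full-model residual standard error — the only per-transcript
dispersion available on the prediction scale; the SD of observed values or
of predicted values are selectable alternatives, and this choice is a
documented interpretation rather than a settled convention. Failing the
Bimodal rule, the category follows the argmax temperature of the predicted
curve: < 10 °C Low, > 31 °C High, otherwise Intermediate. The
band-boundary convention (Intermediate as the closed interval [10, 31])
makes the three bands an exhaustive partition; the choice matters only for
argmax values inside a 1 °C sliver. Exact argmax ties resolve to the
coldest maximiser on the dense grid.

## Comparative battery

The category table (2 species × 5 categories) and the paired 5 × 5
transition table drive the tests:

* Pearson χ² (no correction) on the full 2 × 5 table;
* per-category 2 × 2 χ² with Yates continuity correction, the second
  column being the species' full classified total minus the category
  count (NotResp included in the total) — the convention that reproduces
  the published statistics from the bundled count table to printed
  precision;
* a one-proportion χ² with continuity correction on the per-species
  responsive totals (the four responsive categories summed) against 0.5;
* the Stuart–Maxwell marginal-homogeneity statistic `dᵀS⁻¹d` on the first
  k−1 marginal differences, solved through a pseudo-inverse so that
  structurally empty categories degrade gracefully; for k = 2 it equals
  the uncorrected McNemar statistic, which the tests assert;
* deviation matrices, observed − expected under marginal independence;
* pooled-variance two-sample t-tests (induction-temperature comparisons)
  and rank tests. The baseline-expression comparison is described in the
  field both as Mann–Whitney and via a signed-rank V statistic; both modes
  are implemented (`paired_rank_test(paired=...)`) and the paired mode
  reports V = sum of positive-difference ranks of `y − x` with a
  tie-corrected normal approximation.

p-values are reported at full precision throughout; "< 0.001"-style
bounds are formatting, not computation.

## Induction temperatures and the tradeoff test

Induction temperature is computed on predicted curves evaluated at the
experimental temperatures, by consecutive-pair differencing; the pair with
the greatest direction-appropriate change is selected and its midpoint
reported, ties breaking toward the mode's extreme. Upregulation modes
serve Low/High transcripts and the corresponding ends of Bimodal ones;
downregulation modes serve Intermediate transcripts and are restricted to
pairs whose midpoint lies below/above 20 °C. Differencing predicted (not
raw) values is what makes interior induction temperatures well defined on
smooth monotone segments; raw-observation differencing is the natural
alternative and can be applied by passing observed values as a curve.

Inducibility is `(max TPM − min TPM)/min TPM × 100` with TPM recovered as
`exp(value) − 1`; transcripts whose minimum TPM is not strictly positive
are excluded with a count (an exclusion signal, not an error).
Constitutive expression is the predicted value at 25 °C, evaluated from
the polynomial exactly rather than from the nearest grid point. The
genetic-assimilation test regresses the between-species log ratio of
constitutive TPM on the log ratio of inducibility (natural log,
first-species-over-second by default; the slope's sign is invariant to the
convention, which is flippable). A negative slope is the assimilation
signature.

## Synthetic data

The generator emulates the study conditions: 2 species × 12 temperatures,
one sample per cell (excluded levels are generated and dropped at analysis
time, as with real data), curves drawn per transcript from flat, linear,
unimodal (concave quadratic) and bimodal (convex quadratic) families, and
additive Gaussian noise on the log scale with TPM truncated at zero.
Defaults: 2.5 % of transcripts responsive (the rate the method was built
to detect), noise SD 0.3 on the log scale, baseline log-expression
N(3, 1.5²) clipped to [0.5, 8] (TPM roughly 0.6–3000), responsive-family
weights 0.4/0.4/0.2 linear/unimodal/bimodal, and 60 % of responsive
transcripts drawing an independent shape in the second species (10 % of
those flat, yielding NotResp calls). Shape parameters are drawn so that
every responsive family clears the flatness epsilon on its noiseless curve
(linear slopes 0.02–0.08 per °C, unimodal curvatures 0.003–0.01 with
interior peaks, bimodal curvatures 0.004–0.012 with troughs at 14–26 °C).
The "intended category" in the truth table is defined as the classifier's
output on the noiseless curve with the generator's noise SD as the
dispersion — truth and classifier are consistent by construction, so
recovery tests isolate the effect of noise and estimation, not of
definition mismatches.

Because the quadratic families lie inside the fitted model class,
noiseless coefficient recovery is exact to numerical precision; an
out-of-class cubic family exists for misspecification stress tests. A
separate tradeoff generator builds curve pairs whose second species is a
power-law transform of the first on the TPM scale — the exponent sets the
inducibility log-ratio exactly and the scale factor is solved so the
constitutive log-ratio equals a requested slope times that ratio plus
noise — giving datasets with a known tradeoff slope.

What the generator does **not** emulate: count-level sampling noise and
its mean–variance relationship, library-size and composition effects,
transcript-length bias, correlated expression modules, and within-sample
pooling of individuals. Passing recovery tests therefore demonstrates the
estimator and decision rules are correct under the stated noise model, not
that the pipeline is robust to quantification artefacts upstream of a TPM
table.

## Numerical conventions and degenerate inputs

Zero-variance responses and perfect fits have the explicit p-value
conventions above; rank-deficient designs, a missing species, or fewer
than 8 observations / 4 distinct temperatures per species raise fit
errors. χ² tests require positive margins; Stuart–Maxwell requires some
off-diagonal mass and rejects negative quadratic forms beyond tolerance
with diagnostics. The t-test returns 0 for identical constant samples and
errors on zero pooled variance with unequal means. All stochastic steps
take explicit seeds; permutation replicates derive sub-seeds as
`seed + replicate`, and the pipeline manifest records the seed trail and a
SHA-256 checksum per output so end-to-end determinism is checkable by
rerunning.

## Problem sizes in the shipped checks

The test suite and acceptance script use scaled study conditions chosen to
exercise every code path while keeping runs interactive: 1000 noiseless
draws for coefficient recovery; 10 all-flat datasets of 2000 transcripts
with B = 20 for null calibration; one 2000-transcript dataset with ~500
responsive transcripts at noise SD 0.1 for category recovery; 100 seeds of
150 curve pairs for tradeoff recovery. B = 100 remains the pipeline
default for real analyses.

## Known limitations

* One sample per cell means residual variance conflates noise sources;
  nothing in the model separates them.
* The retention rule calibrates only the *size* of the significant set,
  then keeps the best-ranked transcripts; it does not provide
  per-transcript permutation p-values.
* The Bimodal dispersion choice and the 30–31 °C band boundary are
  conventions; results within 1 °C of a boundary or within one residual
  SE of the Bimodal margin are sensitive to them.
* AIC stepwise selection retains spurious terms at the expected χ²(1) > 2
  rate; downstream summaries should rely on the calibrated retained set,
  not on per-transcript term lists.
* Inducibility is undefined for transcripts whose predicted minimum TPM
  is ≤ 0; they are excluded and counted, which can bias tradeoff panels
  toward higher-expressed transcripts.
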