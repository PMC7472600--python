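# Methods

## Scope and data flow

The package implements the computational stages of erythrocyte-membrane
fatty-acid profiling: calibration-curve quantitation of integrated GC-FAME
peak tables, closure of the ten-fatty-acid cluster to relative percentages,
derived lipid parameters, healthy-cohort reference benchmarking, and the
cohort statistics (sex comparison, covariate correlations).  Everything
upstream of an integrated peak table — membrane isolation, lipid extraction,
transesterification, instrument control, peak detection/integration — is out
of scope; run metadata rides along untouched.  Breed-stratified and
neuter-status analyses are deliberately not offered: realistic single-clinic
cohorts cannot power them.

## Quantitation

Each fatty acid's detector response is modelled as a straight line
`area = slope·conc + intercept`, fitted by ordinary least squares with a free
intercept (`force_zero_intercept` forces the line through the origin for
detectors with verified zero blank).  Choices on degenerate inputs:

- fewer than 3 standards, or fewer than 2 distinct levels → error;
  a fitted slope ≤ 0 → error (the line cannot be inverted);
- r² < 0.995 logs a warning but does not abort — a poor calibration is a
  data-quality flag, not a structural failure;
- back-calculated quantities below zero (area under the fitted intercept)
  are clipped to 0 with a logged warning;
- a cluster peak absent from a sample's table is treated as quantity 0 with
  a warning (in healthy profiles every cluster member is present, so absence
  signals an upstream integration problem rather than a true zero);
- samples whose cluster coverage (cluster area / total area) falls below the
  0.97 threshold are flagged and retained, never dropped: coverage is a
  cohort property, not an exclusion rule.

Closure divides by the summed cluster quantities, so percentages are exactly
scale-invariant and sum to 100 (asserted to 1e-9 relative).

## Derived parameters

Family totals, SFA/MUFA, n-6/n-3, PUFA balance, and the unsaturation (UI)
and peroxidation (PI) indexes are computed at full precision and rounded
only at the report layer (2 decimals).  The conventional "total MUFA × 1"
term of UI (and × 0.025 of PI) is stored as a per-member weight on each
MUFA, which is equivalent because the index is linear in the summands and
keeps every formula a single weighted sum over the registry.  Undefined
ratios (zero denominator) become NaN at panel level rather than exceptions,
so cohort summaries can drop them per-parameter with an honest n.  All index
formulas read their weights from the cluster registry; an alternative panel
can be loaded from YAML and flows through every operation unchanged.

Linearity has a practical consequence used throughout the tests: the UI/PI
and family totals of a mean composition equal the mean of the per-sample
values, so published per-sex mean columns double as exact worked examples.
The ratio parameters are *not* linear, so a ratio of column means differs
from the mean of per-sample ratios (e.g. n-6/n-3 of the female mean column
is ≈26.2 while the per-dog mean is ≈32.8); the package never conflates the
two.

## Reference benchmark

"Interval values" are raw min–max order statistics with the median, the
convention for first-of-kind veterinary reference panels; robust
clinical-chemistry interval estimators are intentionally not implemented.
For n ≥ 40 the rows also carry nonparametric 2.5/97.5 percentiles (linear
interpolation).  Distribution exports use Freedman–Diaconis bins by default
(configurable); a constant parameter yields a single unit-width bin.  The
annotated band on distribution plots is the 2.5–97.5 percentile range and is
labelled as such — no parametric confidence construction is implied.
Medians are not additive across parameters: the Total SFA median generally
differs from the sum of member medians, which is expected behaviour.

## Statistics

The normality gate is the D'Agostino–Pearson omnibus K² (skewness +
kurtosis z-scores, χ²(2) under the null), applied per variable at α = 0.05
with a validity floor of n = 20; below the floor a variable is routed to the
nonparametric path.  The two-group comparison uses the Welch (unequal
variance) t-test when both groups pass the gate — Welch rather than
pooled-variance Student as the safer default, with `pooled_variance=True`
for exact replication of classical outputs — and otherwise the two-sided
Mann–Whitney test: exact by full enumeration of the C(nₐ+n_b, nₐ) group
assignments (midranks, so ties are exact) when both groups have n ≤ 8, and
the tie-corrected normal approximation above.  Correlations are Pearson when
both vectors pass the gate, Spearman otherwise, always reported signed.
No multiple-testing correction is applied by default; Benjamini–Hochberg is
an explicit opt-in that only tightens significance flags.

Calibration of the gated procedures is verified by simulation at the study's
group sizes (30/38): type-I error within [0.03, 0.07] under normal and
lognormal nulls over 1000 replicates, and mean recovery of ρ = 0.4 at n = 68
within 0.03 over 500 replicates.

## Synthetic cohorts

The generator reproduces the *structure* of a healthy reference cohort so
the pipeline is testable end-to-end:

- **Covariates.** Sex counts exact (38 F / 30 M of 68 by default); age and
  bodyweight are truncated lognormals over the stated ranges (2–156 months,
  median target 41; 2.6–43 kg, median at the geometric midpoint 10.6 kg)
  with log-scale sigmas 0.75 and 0.55 — right-skewed, as clinic cohorts are.
  Neuter rates (6/30 M, 12/38 F) and a 35% mixed-breed share match the
  reference cohort's bookkeeping; breed is cosmetic.
- **Compositions.** Additive-logistic-normal: latent Gaussian log abundances
  y, closed by p = 100·exp(y)/Σexp(y).  Chosen over a Dirichlet because a
  full latent covariance admits injected covariate correlations while
  guaranteeing positivity and exact closure.  Per-sex latent means/scales
  are calibrated by fixed-seed Monte-Carlo moment matching (N = 20 000,
  40 damped iterations) so the *closed-scale* per-sex means and sds hit the
  published per-sex columns; the calibration is deterministic, cached per
  spec, and part of the model definition rather than of the per-seed draw.
- **Correlation injection.** Published associations are injected as linear
  terms in the latent mean on standardized log-covariates: age→EPA (+0.396),
  bodyweight→palmitic (+0.385), →palmitoleic (+0.326), →arachidonic
  (−0.257); signs follow the report prose (printed magnitudes are unsigned).
  Slopes are calibrated against the *rank* correlation measured on the
  closed scale, because the pipeline's gated correlation routes these skewed
  covariates to Spearman — the published coefficients came from the same
  gated procedure.  The calibration Monte-Carlo draws covariates from the
  same truncated lognormals as generation; the rank-correlation estimand
  depends on the covariate's marginal shape, so using normal covariates in
  calibration would bias recovery by ≈ +0.013.  The bodyweight–Total-SFA
  association (+0.402) is carried by an auxiliary stearic-acid slope
  calibrated directly on the family total: palmitic acid alone propagates
  only ≈0.29 to the total, and a positive stearic association is consistent
  with the reported de-novo-lipogenesis interpretation.  Associations of
  n-6, total PUFA, UI and PI with bodyweight are *not* separately injected;
  they emerge through the compositional coupling (mostly via arachidonic
  acid) and are weaker than the published values — a documented limitation.
- **Raw-data layer.** Each FA gets a true linear response (slope uniform
  50–200 area/(µg/mL), intercept uniform 0–5) and five calibration levels
  spanning one decade centered on the analyte's typical sample concentration
  (geometric-mean total lipid × pooled mean percentage) — trace analytes are
  calibrated near their working range, as in practice.  Standards carry 1%
  multiplicative noise, sample areas 0.5%, both configurable; total lipid
  per sample is uniform on 50–500 µg/mL and a pooled `other` area places
  cluster coverage uniformly in [0.975, 0.995].  The noise-free mode is the
  oracle path: the simulate → quantify → profile round trip is then exact to
  1e-9.

What the synthetic cohorts do **not** emulate: diet/supplementation effects,
disease states, breed structure, batch/instrument drift, retention-time
artifacts, or any between-parameter correlation beyond what the latent
model and closure induce.  Passing tests therefore demonstrate that the
pipeline's arithmetic, gating and calibration behave correctly under the
published cohort's first- and second-moment structure — not that the
generator reproduces every joint property of real canine membranes.

## Problem sizes and numerical choices

Simulation-based checks use 100–200 cohorts of n = 68 (means and injected
correlations), 1000 replicates for type-I calibration, and 500 for
correlation recovery — sizes at which Monte-Carlo error is a small fraction
of each tolerance.  The acceptance script uses 200 cohorts per correlation
target.  Tie-breaking and edge policies: midranks everywhere ties occur;
the exact Mann–Whitney p caps at 1; percentile and median interpolation is
linear; calibration aborts (`infeasible spec`) if a latent scale collapses
or a target correlation cannot be approached within 0.05.

## Known limitations

- The per-sex sd targets are matched on the closed scale by moment
  iteration; extreme user-supplied targets (sd ≫ mean for a dominant
  component) can be infeasible under logistic-normal closure and are
  rejected rather than silently approximated.
- Emergent (non-injected) index correlations undershoot published
  magnitudes, as noted above.
- The exact Mann–Whitney path enumerates up to C(16,8) = 12 870 assignments;
  it is intentionally capped at group sizes of 8.
- Published mean columns are printed at 2 decimals; weighted sums over ten
  inputs (UI, PI) can inherit up to ~0.1 of rounding from such inputs, so
  worked-example agreement beyond that precision is not meaningful.
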