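# Methods

This note documents the models and procedures implemented in `trajdope`,
the defaults and why they were chosen, what the synthetic cohort generator
does and does not emulate, and the package's known limitations.

## Study design and data model

The pipeline targets a two-arm longitudinal administration study: two groups
of 7 male subjects, both receiving micro-dosed EPO, one additionally
micro-dosed rhGH (the EGH arm), sampled at days 0, 4, 11 and 14. Three
assay blocks are measured at every timepoint: a 33-parameter complete blood
count, a 33-analyte urinary steroid panel, and serum IGF-I / P-III-NP. Data
travel as a tidy long-format table (`LongitudinalPanel`): one record per
(subject, arm, day, analyte) with an optional value and a below-LOD flag.

Class labels follow the pooled-timepoint convention: all day-0 samples form
the CONTROL class regardless of arm (they precede any treatment), and
post-treatment samples take their arm label — 14 CONTROL, 21 EPO and 21 EGH
samples out of 56 in the default design. Arms are fixed to exactly two
because this labeling rule is study-specific; a third arm is rejected.

**LOD filter.** Analytes whose fraction of absent-or-censored records
exceeds `max_missing_frac` (default 0.5) are removed entirely; the default
threshold reproduces the study's rule of discarding only analytes that
never reached the limit of detection (5 steroids, leaving 28). Surviving
censored records are imputed at LOD/2, the standard left-censoring
convention. The filter removes columns, never samples, and is idempotent.
One naming caveat: the study's discard list contains a steroid
(17αOH-dihydroprogesterone) with no exact counterpart in the assay
catalogue; the closest catalogue entry, 5α-pregnane-17α-ol-3,20-dione,
stands in for it in the default schema.

## Geometric trajectory analysis

GTA is the package's normalization core:

    g_ijt = (x_ijt − x_ij0) / σ_j ,   σ_j = SD_i(x_ij0), ddof = 1

Subject baselines are subtracted so each trajectory is anchored at its own
pre-treatment state; division by the cross-subject day-0 SD expresses
deviations in a population-scale unit, making blocks with different units
fusable. The scale choice — baseline SD rather than a pooled or robust
spread — is the single most consequential reconstruction decision in the
package: it reproduces the defining behaviors of the method (all
pre-treatment samples map to exactly zero; deviations are reported "in
standard deviations") and makes effect recovery exact under the generator
(below). Degenerate σ = 0 (a constant baseline) is a hard error by
default; an explicit `sd_floor` substitutes a floor for deliberately
degenerate synthetic inputs. Multiple pre-treatment days, common in real
biological-passport data, are averaged into the baseline (at the cost of
the exact-zero property); the default design has a single day 0.

Because day-0 samples precede treatment, fitting σ and the baselines on the
full cohort leaks no outcome information into cross-validation.

Missing post-baseline values propagate as missing into the block matrices,
where they are imputed by the class-blind column mean (NIPALS needs a
complete matrix).

The summary statistic `mean_trajectory_deviation` is the mean over
(analyte, day) cells of |mean_a(g) − mean_b(g)| between two sample groups;
between arms on the default generator it is calibrated to ≈ 0.3 SD (see
below). Being a mean of absolute values of noisy cell means, it carries an
upward bias that vanishes as the number of subjects grows; calibration is
therefore checked at 500 subjects per arm, while at the study's n = 7 the
same statistic reads ≈ 0.4.

## Synthetic cohort generator

The generator exists so that every pipeline stage, and the pipeline's
statistical behavior, can be tested without controlled-substance study
data. Per subject *i*, analyte *j*, day *t*:

    b_ij  = ref_mean_j · exp(ε_ij),   ε_ij ~ N(0, ln(1 + ref_cv_j²))
    x_ijt = b_ij + shift(arm_i, j, t) · σ_j + η_ijt,   η_ijt ~ N(0, (noise_cv_j · ref_mean_j)²)

with truncation at 0 and censoring (value ≤ LOD) applied afterwards.
Between-subject baselines are log-normal (concentrations are positive and
right-skewed); analytical noise is additive. The effect unit σ_j is the
theoretical SD of an observed day-0 value,
`ref_mean·sqrt(ref_cv²(1+ref_cv²) + noise_cv²)`, i.e. exactly the quantity
GTA estimates as its denominator — so an injected shift of s SD is
recovered by GTA as s in expectation, and exactly when noise is zero.
Effects are additive on this SD scale rather than multiplicative for the
same reason: the deviation statistic then recovers effect sizes by
construction.

`ref_mean` / `ref_cv` / `noise_cv` are plausible adult-male
reference-range stand-ins (clinical hematology ranges; urinary steroid
excretion levels with high between-subject CV ≈ 0.5 and analytical
CV ≈ 0.12), shipped as a documented constants table. They are simulation
parameters, not measured study values; downstream analysis is invariant to
the means by GTA's affine invariance, while the CV ratios set the
difficulty of the classification problem.

Default effect trajectories encode the study's reported trend directions:

* both arms: reticulocyte % and count rising from day 4 through day 14,
  with immature-fraction indices and a late hemoglobin/hematocrit rise —
  the EPO response, identical in both arms;
* EGH only: WBC, neutrophil and monocyte levels lowered; eosinophil and
  basophil fractions raised; a broad urinary steroid surge at day 4
  largely mitigated by day 11 (strongest for 5β-androstanedione,
  5α-androstanedione, 5β-androstane-3α,17α-diol and 17β-estradiol, which
  stay elevated); 4-androstenedione lowered; IGF-I and P-III-NP elevated
  with IGF-I the stronger marker.

Magnitudes are a calibration choice (the study reports directions, not
per-analyte effect sizes): they were set once so that the mean between-arm
trajectory deviation is ≈ 0.3 SD (measured 0.30 at 500 subjects/arm) and
then frozen. Five steroids are fully censored (LOD far above the plausible
range), reproducing the 33 → 28 steroid reduction.

Randomness is counter-based: one global seed plus (arm, subject-index,
CRC32 of the analyte name) keys an independent stream per subject-analyte
series. Record order never affects draws, and adding analytes does not
perturb existing ones.

**What the generator does not emulate.** Percentages and their paired
counts (NEUT% vs NEUT/) are drawn independently rather than constrained to
sum to 100 — the classifier treats all 33 CBC parameters as independent
features, so this matches the model's view but not hematology; effect
trajectories are descriptive piecewise shifts, not pharmacokinetic curves;
there are no circadian/exercise confounders, no assay drift, and no
correlated steroid pathway structure. Passing tests therefore certify the
pipeline's statistical machinery under a faithful *design*, not its field
performance on real athletes.

## Fusion and scaling

Blocks are fused by plain column-wise concatenation ("low-level" fusion) of
matrices sharing an identical (subject, day) row ordering; no block
weighting is applied. Columns are autoscaled to unit variance (center 0,
SD 1, ddof 1, constant-column scale floor 1), the default for
discriminant latent-variable modeling of heterogeneous panels; GTA already
removes units but not variance heterogeneity between analytes. The scaler
is refit on the training rows of every cross-validation split and applied
frozen to the held-out rows; a deliberately leaky fit-on-everything variant
exists only so the tests can demonstrate that it changes the result.

## PLS, OPLS-DA and VIP

`PLSNipals` is standard NIPALS with X-deflation; the inner loop starts from
the first response column (deterministic), converges when the score vector
is stable to 1e-10 (relative), and errors with the iteration count after
500 iterations. For a single response the loop is exact after one pass. At
full rank PLS reproduces least-squares fitted values; scores are mutually
orthogonal.

`OPLS` removes `n_orthogonal` response-orthogonal components before one
predictive component: w ∝ Xᵀy normalized; per orthogonal step
p = Xᵀt/(tᵀt), w_o = p − (wᵀp)w normalized, t_o = X w_o, deflate X by
t_o p_oᵀ. New samples are filtered with the training w_o/p_o before
scoring. Training predictions of OPLS(1 predictive + k orthogonal) equal
PLS(k+1) exactly; the test suite uses this equivalence, plus the
orthogonality |corr(t_o, y)| < 1e-8, as internal oracles.

The default is one orthogonal component — the typical published OPLS-DA
structure (1 predictive + 1 orthogonal); it is configurable everywhere.

The multiclass model is a one-vs-rest ensemble: per class an OPLS model on
a centered {1, 0} dummy (equivalent to ±1 coding after centering; fixed
for reproducibility), class assignment by argmax of the predicted dummies,
exact ties resolving to the lexicographically first class. Per-class
predicted scores feed the ROC analysis. A single multi-response PLS2 model
(`strategy="pls2"`, 1 + n_orthogonal components) is available for
comparison. VIP is computed over predictive components only,
`VIP_j = sqrt(K · Σ_a SSY_a w_aj² / Σ_a SSY_a)` — for a single predictive
component simply `sqrt(K)·|w_j|` — which ranks features by
class-discriminating weight; mean(VIP²) = 1 identically. Commercial
implementations sometimes report a "total" VIP including orthogonal
components; only ranking-level agreement with such outputs should be
expected. The shipped biomarker table ranks features by the EGH-vs-rest
model's VIP (the rhGH question); a flag switches the class.

## Monte Carlo cross-validation

Each of `n_reps` (default 100) repetitions draws a stratified random
train/test split (test fraction 1/3 — the common 2:1 choice in the MCCV
literature; the source protocol does not state one), fits scaler and
ensemble on training rows only, and scores the held-out rows. Predictions
are pooled across repetitions before computing per-class AUROC
(Mann–Whitney ranks, ties 1/2), their unweighted mean as the single
"overall" figure, pooled accuracy and the confusion matrix; per-repetition
predictions are retained in the report. Per-repetition RNG streams are
counter-derived from the seed, so raising `n_reps` extends rather than
reshuffles a run. A repetition whose training set lacks a class is redrawn
(up to 50 times, then a hard error).

**Split unit.** The default holds out whole subjects (`split_unit =
"subject"`, stratified by arm). This is deliberate: GTA values of one
subject share the term −η_i0/σ (the subject's day-0 measurement noise
enters every post-baseline deviation), so when a subject's timepoints
straddle the split the model can recognize held-out samples of training
subjects by that shared component and recover their training-set arm
label. Measured on zero-effect cohorts, sample-level splitting inflates
the pooled overall AUROC to ≈ 0.9, while subject-level splitting is
calibrated (≈ 0.5). Sample-level splitting (`split_unit="sample"`),
which mirrors pooled-sample analyses, remains available and its inflation
is demonstrated in a dedicated test; results produced with it estimate
re-identification of known subjects, not generalization to new ones.

The permutation null re-runs the full MCCV with permuted labels and
reports the add-one p-value `(1 + #{null ≥ observed})/(n_perm + 1)`. Under
subject-level splitting the exchangeable units are subjects, so the
per-subject label blocks are permuted (day-0 CONTROL structure preserved);
under sample-level splitting labels are permuted freely.

**Known behavior of the argmax rule.** With strongly scaled effects the
three classes are fully separable (per-class AUROC ≈ 1), yet pooled
accuracy does not reach 1.0: EPO day-4 samples — a reticulocyte-only
signature at intermediate magnitude, lying between CONTROL and the later
clusters on every single discriminant direction — are sometimes assigned
to CONTROL by the argmax over three independent one-component regressions.
This is a geometry limitation of per-class 1-D scoring, not a fitting
defect (training predictions match the PLS equivalence to machine
precision); AUROC, which uses the per-class scores directly, is the more
faithful summary of separability.

## Problem sizes used by tests and the acceptance script

Chosen so Monte Carlo error is small relative to what each check asserts:

* effect recovery and the 0.3-SD calibration: 500 subjects per arm
  (SE of a cell mean ≈ 0.015 SD);
* null calibration band [0.4, 0.6]: 20 seeds × zero-effect cohorts of 50
  subjects per arm — at the study's n = 7 the subject-held-out AUROC is
  unbiased but spreads ± 0.15 across cohorts, which would confound the
  band check with small-cohort variance;
* permutation calibration: 9 study-size null cohorts, 19 permutations,
  30 repetitions each;
* classification summaries: medians over 10 study-size cohorts at the
  default 100 repetitions;
* algorithmic oracles: 50 random OPLS/PLS instances, 100 random AUROC
  score sets.

## Limitations

* The GTA scale reconstruction (baseline SD) is principled but not
  verifiable against the original software; alternative spreads would
  change absolute deviation values, not the invariances.
* One predictive component per one-vs-rest model; no automatic component
  selection or cross-validated n_orth choice.
* The generator's effect magnitudes are calibrated to a single aggregate
  (0.3 SD); per-analyte magnitudes are plausible, not measured.
* No GH-2000 score, no Bayesian adaptive (passport-style) individual
  limits, no sparse PLS variants, no mid/high-level fusion — all outside
  this package's scope.
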