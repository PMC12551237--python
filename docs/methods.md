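# Methods

## Problem setting

After traumatic spinal cord injury (SCI), neurological status is tracked with
the ISNCSCI examination: 20 key-muscle motor scores (0–5), 2×56 sensory scores
(0–2), voluntary anal contraction (VAC), deep anal pressure (DAP), the AIS
severity grade (A–E) and the neurological level of injury (NLI). Clinical
trials in SCI struggle to recruit: the condition is rare and extremely
heterogeneous. `sctrials` implements a synthetic-control workflow for this
setting: a model trained on observational registry data predicts each
patient's recovery-phase segmental motor scores from their acute examination;
the prediction serves as that patient's counterfactual under standard care, so
a trial can run as a single arm with every participant treated.

The package has four parts: (1) the ISNCSCI coordinate system, derived scores
(UEMS/LEMS) and cohort filters; (2) a synthetic cohort generator standing in
for the restricted registries; (3) a benchmark of six prediction
architectures; (4) trial simulation and design sizing built on the fitted
model.

## Cohort rules

An analysis pair (instance) is an early assessment (≤ 98 days after injury,
DAI) and a late assessment (≥ 150 DAI) of one patient; patients with several
qualifying assessments contribute several instances. Excluded: AIS E, NLI at
or below S1, and any pair in which a key muscle loses ≥ 2 points (such
deterioration reflects unrecorded complications that a natural-course model
must not absorb). Trial simulations restrict the baseline to ≤ 40 DAI and use
one instance per patient. The single-arm case-study filter mirrors a cervical
trial protocol: NLI C2–C8, baseline ≤ 28 DAI, follow-up in the closed window
[161, 175] DAI, baseline UEMS < 29 (patients at the 50-point ceiling have no
measurable upper-extremity recovery left). "Cervical" includes C2–C4: high
cervical lesions are cervical injuries even though the first key muscle is C5.

## Synthetic cohort generator

Real SCI registries are available only on request, so the generator emulates
one. Its defaults reproduce the published composition of a large European
registry cohort: AIS mix 43.1/12.5/18.1/26.0% (A/B/C/D), NLI regions
53.8/37.3/9.0% (cervical/thoracic/lumbar, level uniform within region — only
region totals are published), age 46 (SD 18, floor 16) years, 22.1% female,
first assessment 22 (SD 20) DAI in [0, 98], follow-up 216 (SD 91) DAI with a
floor at 150, VAC present in 30.5% and DAP in 52.4% (AIS-conditional
probabilities are a free choice tuned once so these marginals hold under the
default AIS mix). Times and ages are truncated normals whose *location* is
solved so the realized post-truncation mean equals the published mean (naive
truncation would, e.g., inflate mean age by almost two years).

Recovery follows a deterministic backbone plus ordinal noise. For a key
muscle `d` segments caudal to the NLI at time `t`:

    score(t) = baseline + gain(AIS) · exp(−d / λ(AIS)) · s(t),

where `s(t)` is a logistic in time (midpoint ≈ 70–80 DAI, rate ≈ 25 d)
normalized to 0 at the injury date, `gain` is the plateau motor-point gain
just below the level (A 0.6, B 1.6, C 2.6, D 2.0) and `λ` the caudal
e-folding distance of recovery (A 4, B 6, C 10, D 30 segments: complete
injuries recover locally around the lesion, motor-incomplete injuries
diffusely). Baselines are full (5, resp. 2 for sensory) rostral to the NLI and
attenuated exponentially below it by an AIS-dependent fraction (A exactly 0 —
the complete-injury convention — B 0.06, C 0.35, D 0.72). Left/right scores
share a per-level latent (correlation 0.8) so sequence-aware models have
cross-midline signal to exploit, Gaussian noise (SD 0.45 motor points) is
added, and everything is rounded and clipped to the score range. Late scores
are floored one point below baseline, so the generator never produces the
≥ 2-point deteriorations the cohort rules exclude. The registry publishes no
quantitative recovery-curve parameters; these values are this package's own
choices, fixed once to satisfy the qualitative structure (severity-dependent
sigmoidal recovery, mild-injury LEMS gains exceeding complete-injury gains)
and kept in `CohortConfig`, never hard-coded.

What the generator does **not** emulate: secondary complications and
deterioration, site effects and assessment-protocol drift, missing data,
non-monotone recovery, and the heavier tails of real outcome distributions.
Passing tests therefore demonstrate that the machinery is correct and behaves
as designed under a realistic data-generating process — not that any
particular model will achieve a given error on real registry data.

## Feature encoding and prediction models

Each instance is encoded as a (6 × 10) rostro-caudal sequence block — left
and right motor, light-touch and pinprick values aligned at the 10 key-muscle
levels — plus 11 scalars (age/100, sex, early and late DAI/100, AIS one-hot,
VAC, DAP, NLI index/27). Targets are the 20 late motor scores, trained and
evaluated as continuous regression on 0–5 (predictions are clipped, never
rounded). Late scores never enter the encoding.

Six families are benchmarked behind one interface: ridge regression (penalty
per output coordinate by internal CV over 1e-3…1e3), random forest, gradient
boosted trees, and three sequence architectures — a 1-D CNN along the
rostro-caudal axis with the scalars broadcast as channels, a single-head
attention encoder/decoder emitting the output sequence from learned per-level
queries, and a message-passing network on the two-sided myotome chain with
left–right cross edges. The published work does not disclose its exact
architectures or hyperparameters, so these are re-decided here; all three
networks stay under ~50k parameters and train on one CPU in seconds
(Adam, lr 3e-3, batch 64, 60 epochs by default; gradients come from a small
reverse-mode autodiff core that is finite-difference-checked in the tests).
A `carry_forward` reference (late = early) provides the no-recovery null.
Cross-validation folds are split **by patient** so repeated instances of one
patient never straddle a fold. A canonical sort of the training set makes
fitting invariant to input row order; one experiment seed fans out to folds,
initialization and perturbations.

The headline metric is RMSE_bl.NLI — RMSE over key muscles strictly caudal to
the initial NLI, both sides — which makes errors comparable across lesion
levels; its signed companion (mean residual, positive = overestimation)
detects systematic bias. Summaries report medians with empirical (2.5, 97.5)
percentiles (linear interpolation between order statistics), overall and per
AIS grade, over instances. The time profile is the per-day median smoothed by
a centered 7-day rolling mean (minimum one observed day). Prediction
uncertainty is propagated by re-predicting under random ±1 jitters of every
input score (default probability 0.1 per score, an inter-rater-disagreement
scale) and taking per-coordinate 2.5/97.5 percentile bands that always
bracket the unperturbed point. Feature importance uses permutation importance
(increase in endpoint MSE when one feature is shuffled across probe
instances; the backend is recorded in the output), aggregated by signed
segmental distance to the endpoint myotome × laterality × modality.

## Trial simulation

Each replicate draws a control cohort of size `n` with replacement from the
pool (stratified to a requested AIS composition; optionally filtered to
tetra- or paraplegia), then builds a zero-treatment cohort by matching each
control member to a pool individual within age ± 5 years, NLI ± 2 segments,
and with exact sex and AIS grade. Matching is greedy in random order with
nearest-age preference and random tie-breaks, without candidate reuse;
instances drawn into the control cohort are excluded from the matching pool
(no self-matching). If a member's candidates are exhausted, reuse is allowed
with a logged warning — every fallback still satisfies all tolerances. Only
*matchable* individuals (those with at least one within-tolerance counterpart
in the pool) are drawable into control cohorts: a patient with no similar
registry counterpart cannot appear in a matched trial by construction, and
without this rule a small fraction of replicates would abort on rare
covariate cells (e.g. female, AIS B, lumbar NLI) rather than reflect any
property of the control mechanism.

The endpoint is Δ mean LEMS improvement, zero-treatment minus control, with
the zero-treatment group scored either by its observed recovery against the
control group's observed recovery (randomized control) or against its own
predicted recovery (synthetic control). Scenarios repeat 500 times with
seeds derived from one base seed; summaries report medians, quartiles and the
95th percentile of the signed Δ (an absolute-value variant is available via a
flag). Two identities anchor the design: a perfect predictor gives a
synthetic Δ of exactly zero in every replicate, and adding a constant
treatment effect τ to the zero-treatment outcomes shifts both Δs by exactly
τ.

## Design sizing

A single-arm trial with synthetic controls tests within-patient differences
(paired t-test); a parallel-group RCT tests independent groups (two-sample
t-test). Sample sizes are the smallest n whose exact noncentral-t power
reaches the target — normal approximations are off by ±2 patients at these
sizes — with two-sided α throughout (sidedness is not specified in the
protocols this mirrors; two-sided is the conservative standard). The paired
SD is estimated as the SD of (observed − synthetic) outcome per patient; a
systematic offset of the synthetic controls is reported as bias, not folded
into the SD. Uncertainty in both sizes comes from a patient-level bootstrap
(default 1000 resamples; zero-variance resamples are flagged and skipped).

## Numerical and interface choices

Scores live in small integer arrays ordered by the 28-level rostro-caudal
index (level-major, left before right); all "caudal/rostral/± segments"
arithmetic is index arithmetic on that order. The wide CSV (one row per
patient × assessment day) is canonical on disk; a long format is accepted.
Floats are written with `%.17g` and read with round-trip precision so
cohort files reproduce exactly. AIS grade and NLI are consumed as given,
never re-derived from the scores. Pipeline runs record a configuration hash
and seed in a manifest; re-running a configuration reproduces the outputs
byte-identically.

Problem sizes used by the test suite and the acceptance script — 2,000
patients for the benchmark, a 4,000-patient simulation pool, 500 replicates
of 200 per arm, 100,000 Monte-Carlo power repetitions — are the package's
default desk-scale study conditions, chosen to mirror the scale of the
registry cohorts while remaining reproducible on a single CPU.

## Known limitations

- The generator's recovery parameters are plausible but not fitted to real
  registry data; absolute error levels on synthetic cohorts do not transfer
  to real cohorts.
- The three neural architectures are compact re-designs, not reconstructions
  of any published architecture; SHAP-based attribution is replaced by
  permutation importance.
- Synthetic controls inherit every bias of their training distribution; the
  simulation quantifies stochastic behaviour under a matched distribution and
  says nothing about distributional drift, placebo effects or changes in
  standard of care.
- Matching assumes the pool is large relative to the trial; with replacement
  draws and candidate-reuse fallbacks degrade gracefully but are logged, not
  hidden.
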