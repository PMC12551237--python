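# sctrials — synthetic control arms for spinal cord injury trials

`sctrials` is a research toolkit for biostatisticians and trialists working
on spinal cord injury (SCI). Recruiting control patients for SCI trials is
hard — the condition is rare and clinically heterogeneous — and the package
implements the *synthetic control* alternative end to end: a model trained on
observational ISNCSCI registry data predicts, for each enrolled patient, the
segmental motor scores they would reach under standard care; that prediction
is the patient's counterfactual, so a trial can treat every participant and
test outcomes against the predictions instead of a concurrent control arm.

## What it computes

- **Recovery prediction.** From an acute ISNCSCI assessment (20 key-muscle
  motor scores MS ∈ {0..5}, 56 light-touch and 56 pinprick scores ∈ {0..2},
  VAC, DAP, AIS grade, NLI) plus age, sex and assessment times, predict the
  full recovery-phase motor score sequence. Six architectures are
  benchmarked — ridge, random forest, gradient boosted trees, a 1-D CNN
  along the rostro-caudal axis, an attention seq2seq model and a chain-graph
  message-passing network — and scored by **RMSE_bl.NLI**, the RMSE over key
  muscles strictly caudal to the initial neurological level of injury,
  reported as median (2.5th, 97.5th percentile) on patient-level
  cross-validated held-out data.
- **Trial simulation.** Repeated simulated trials draw a control cohort from
  a registry pool, match a "zero-treatment" cohort (age ± 5 y, sex, NLI ± 2
  segments, AIS grade exact) and score the endpoint ΔLEMS_impr — the
  difference in mean lower-extremity motor score improvement, zero-treatment
  minus control — for randomized controls (observed recovery) vs synthetic
  controls (predicted recovery). With no treatment, both should scatter
  around 0; the synthetic arm scatters less.
- **Design sizing.** Exact noncentral-*t* sample sizes for a single-arm
  design (paired *t*-test against the synthetic counterfactual) vs a
  parallel-group RCT (two-sample *t*-test), with the outcome SDs estimated
  from a cohort and bootstrap uncertainty on the sizes.
- **Synthetic registry.** Because the underlying registries (EMSCI, Sygen,
  NISCI) are restricted, a first-class generator emulates an EMSCI-like
  cohort — published AIS/NLI/age/sex/assessment-time composition and a
  severity-dependent sigmoidal segmental recovery process — so the whole
  pipeline runs and is tested without data access. See `docs/methods.md`.

## Worked example

```python
from sctrials import (
    SegmentalRecoveryModel, default_emsci_config, generate_cohort,
    DesignParams, paired_n, two_sample_n,
)

# a synthetic EMSCI-like registry: 1,000 patients for training,
# 2,000 disjoint patients as the trial-simulation pool
train = generate_cohort(default_emsci_config(n_patients=1000, seed=7))
pool = generate_cohort(default_emsci_config(n_patients=2000, seed=8))

model = SegmentalRecoveryModel.from_cohort(train, family="conv_sequence",
                                           hyperparams={"epochs": 40}, seed=0)
res = model.fit_cv(n_folds=5)
print(res.summary())

sim = res.simulate_trials(pool.instances())
trials = sim.repeat(n_trials=200, size=200, seed=1)
print(trials.summary().round(3).to_string(index=False))

p = DesignParams(delta=5.0, sd=10.0, alpha=0.05, power=0.8)
print(f"single-arm n = {paired_n(p)}, RCT total = {2 * two_sample_n(p)}")
```

prints

```
Segmental motor recovery model
==============================================
family:            conv_sequence
seed:              0
instances trained: 1000 (1000 patients)
training loss:     4.3126 -> 0.1665 over 40 epochs
cross-validation:  5-fold, by patient

Held-out RMSE below the NLI
----------------------------------------------
statistic  median   p2.5  p97.5       n
stratum
A           0.410  0.170  0.681   435.0
B           0.526  0.367  0.855   125.0
C           0.605  0.305  0.897   181.0
D           0.567  0.154  0.829   259.0
all         0.501  0.193  0.847  1000.0

control_type  median    q25   q75   p95   mean    sd  n_trials
  randomized   0.030 -0.100 0.161 0.295  0.016 0.194       200
   synthetic  -0.052 -0.151 0.030 0.118 -0.061 0.124       200

single-arm n = 34, RCT total = 128
```

Reading this: the CNN predicts held-out segmental motor scores with a median
error of ~0.5 points below the lesion level on this synthetic cohort. Over
200 simulated null trials of 200 patients per arm, both control mechanisms
center near zero (no treatment exists), but the synthetic-control endpoint
distribution is visibly tighter (SD 0.12 vs 0.19 LEMS points, 95th percentile
0.12 vs 0.30). Detecting a 5-motor-point effect with outcome SD 10 needs 34
patients in a single-arm design against 128 in a two-arm RCT.

A CLI mirrors the library (`sctrials generate | include | train | evaluate |
simulate | power | case-study | run`); `sctrials run --config cfg.yaml`
executes the whole pipeline into a directory with a config-hash-stamped
manifest.

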