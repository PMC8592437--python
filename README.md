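# relapsim

Synthetic leukemia remission cohorts and a benchmark of relapse-prediction
methods.

## The problem

Treatment decisions for acute and chronic myeloid leukemia (AML, CML) are
usually based on markers measured at diagnosis, while the *dynamics* of
molecular monitoring — NPM1-mut/ABL or BCR-ABL1/ABL1 transcript ratios
tracked over months to years on a log10 scale — are rarely exploited.  How
well can relapse after chemotherapy (AML) or molecular recurrence after
TKI cessation (CML) be predicted from such time series, and how much does
prediction suffer as data become noisy, sparse and censored at a detection
limit?

Because real monitoring cohorts are small, `relapsim` studies the question
in silico: mechanistic ODE models generate ground-truth remission courses
for virtual patients, a degradation ladder emulates clinical data quality,
and three predictors are compared under stratified 10-fold
cross-validation:

* **MM** — mechanistic refitting: the generative ODE model's
  patient-specific parameters (2 of 11 for AML, 7 of 13 for CML) are refit
  to each patient's input series by minimising the sum of squared log10
  residuals (SLSQP multistart for AML; a genetic algorithm plus gradient
  polish for CML), and the fitted model is simulated through the horizon.
* **GLM** — logistic regression on hand-crafted kinetic features
  (elimination slope, remission nadir, segmented-regression slopes for
  AML; bi-linear remission approximation, cessation time and pre-stop
  level for CML).
* **NN** — a bidirectional LSTM trained end-to-end on the raw, scaled
  series (a compact numpy implementation with hand-derived,
  gradient-checked backpropagation).

Data-quality variants: **D** (dense, noise-free: weekly for AML, monthly
for CML) → **DN** (log-normal measurement noise) → **SN** (thinned to
clinical frequency: median 4 in-window points for AML, ~25 for CML) →
**AP** (detection limit 0.01 % with censoring) → **AS** (improved schemes:
cycle-aligned AML sampling; a half-dose TKI year before cessation for
CML).  AML predicts relapse within 24 months from the first 9 months; CML
predicts recurrence within 10 years of cessation from everything up to
cessation.  See `docs/methods.md` for the models, parameters and design
choices.

## Worked example

```python
import numpy as np
from relapsim import (CohortConfig, generate_cohort, EvalConfig,
                      run_experiment)

records = generate_cohort(CohortConfig("AML", n_patients=200, seed=42))
print("relapse fraction:", np.mean([r.relapse for r in records]))

cfg = EvalConfig(k=10, seed=1,
                 nn_kwargs=dict(epochs=40, restarts=2, patience=8,
                                batch_size=32))
report = run_experiment(records, cfg)
print(report.summary_frame().round(3).to_string(index=False))
```

Output (about 3.5 minutes on one CPU):

```
relapse fraction: 0.355
disease variant method  mean_accuracy  sd_accuracy
    AML       D     MM          1.000        0.000
    AML       D    GLM          0.995        0.016
    AML       D     NN          0.820        0.095
    AML      DN     MM          0.940        0.046
    AML      DN    GLM          0.930        0.042
    AML      DN     NN          0.780        0.095
    AML      SN     MM          0.835        0.106
    AML      SN    GLM          0.895        0.064
    AML      SN     NN          0.790        0.088
    AML      AP     MM          0.780        0.079
    AML      AP    GLM          0.795        0.086
    AML      AP     NN          0.780        0.082
    AML      AS     MM          0.810        0.102
    AML      AS    GLM          0.800        0.091
    AML      AS     NN          0.775        0.082
```

Reading it: on dense noise-free data the mechanistic model identifies the
generating process essentially perfectly (accuracy 1.0 — it *is* the
generator refit to its own output) and the feature-based GLM is close
behind.  Accuracy declines for every method as noise, sparsity and the
detection limit are added; with a median of only 4 in-window measurements
per patient, the sparse variants (SN, AP) cost the model-informed methods
15-20 points.  The improved measurement scheme (AS) — the same number of
points, placed on the first day of each chemotherapy cycle and six-weekly
afterwards — buys the mechanistic model back 3 points over AP without any
extra measurements (it does not help the LSTM at this cohort size; see
`docs/methods.md`).  Fold-to-fold SDs of ~0.1 at n = 200 mean individual
cells carry that uncertainty.

The same pipeline runs from the shell:

```bash
relapsim generate --disease AML --n 120 --seed 42 --out runs/aml/cohort
relapsim run-all --seed 42 --out runs/aml
relapsim report --run-dir runs/aml --out runs/aml/accuracy.png
```

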