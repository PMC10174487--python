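# ehgterm

Predicting preterm birth from electrohysterogram (EHG) recordings and
clinical covariates, as a tested, fully reproducible pipeline.

Preterm birth — delivery before 259 days (37 weeks) of gestation — is
the leading cause of infant mortality, and no reliable early predictor
is in routine use. The EHG, a surface-electrode recording of the
uterus's electrical activity taken during a regular check-up, carries
candidate predictive signal. This package implements an end-to-end
analysis of that idea:

* **signal conditioning** — drop the first minute, zero-phase 4th-order
  Butterworth band-pass 0.05–4 Hz, decimate 20 → 10 Hz;
* **spectral featurization** — short-time Fourier transform with 60 s
  Hamming windows at 75% overlap; a 30-minute trace becomes a 301×113
  log-magnitude frequency×time matrix;
* **models** — a bidirectional-LSTM sequence classifier/regressor over
  the STFT columns (implemented in pure numpy with verified analytic
  gradients), trained with class-weighted cross-entropy
  `w_i = 2·S_{1-i}/(S₀+S₁)` to handle the ~19% preterm imbalance; an
  L1-penalized logistic model on the clinical covariates; and a
  combined model that concatenates the network's 2-unit fully connected
  activations with the clinical features;
* **leakage-safe evaluation** — stratified 5-fold cross-validation
  repeated 20 times with imputation, scaling, penalty selection, and
  training all scoped to the training fold; pooled per-repeat AUCs with
  t-based CIs; sensitivity/PPV/NPV at fixed specificities; a
  label-noise AUC ceiling from gestational-age dating error;
* **perturbation experiments** — frequency-band ablation, STFT-column
  shuffling, and recording cropping, to localize the predictive signal;
* **synthetic cohorts** — a generator producing signals, covariates
  (with realistic missingness), and outcomes with controllable class
  effects, so the whole pipeline runs and is tested without any data
  download.

See [docs/methods.md](docs/methods.md) for the statistical details and
design rationale.

## Quick start

Everything is driven by the `ehgterm` command (or
`python -m ehgterm.cli`). Generate a synthetic cohort of 60 mothers
with a strong spectral class effect and evaluate the EHG classifier at
reduced settings:

```sh
$ ehgterm simulate --n 60 --prevalence 0.3 --spectral-effect 1.5 \
      --clinical-effect 4 --seed 7 --out cohort
$ ehgterm evaluate --cohort cohort --mode ehg --repeats 5 \
      --epochs 10 --hidden 16 --seed 7 --out eval_ehg
ehg/cls: AUC 0.932 (95% CI 0.895-0.970)
$ ehgterm report --cohort cohort --seed 7 --out report
noisy-label AUC ceiling: 0.995 (95% CI 0.992-0.998)
```

Each stage writes CSV/JSON results plus a `manifest.json` recording the
configuration and derived seeds, so any run is exactly reproducible
from its master `--seed`. `eval_ehg/auc.json` from the run above:

```json
{
  "mode": "ehg",
  "head": "cls",
  "auc_mean": 0.9321022727272729,
  "auc_ci": [0.8946796539736432, 0.9695248914809025],
  "per_repeat_aucs": [0.9517, 0.8934, 0.9687, 0.9119, 0.9346]
}
```

Other subcommands: `import` (read WFDB-style records into a cohort),
`featurize` (write the STFT matrices), `perturb` (band/shuffle/crop
experiments), `run` (end-to-end from a YAML config). `--mode` selects
`clinical`, `ehg`, or `combined`; `--head` selects classification
(`cls`) or gestational-age regression (`reg`).

## Library use

```python
import numpy as np
from ehgterm import CohortSpec, generate_cohort
from ehgterm.models import EhgRecipe, NetworkSpec, TrainConfig, prepare_cohort
from ehgterm.evaluation import RepeatPlan, repeated_cv

_, cohort = generate_cohort(CohortSpec(n_mothers=60, spectral_effect=1.5, seed=7))
data = prepare_cohort(cohort)           # condition + STFT, computed once
recipe = EhgRecipe(net_spec=NetworkSpec(bilstm_hidden=16),
                   train_cfg=TrainConfig(epochs=10))
result = repeated_cv(data, recipe, RepeatPlan(n_repeats=5, k=5, master_seed=7))
print(result.auc_mean, result.auc_ci)
print(result.operating_table)           # sensitivity/PPV/NPV at 50/70/90% spec.
```

## Repository layout

```
src/ehgterm/
  synthetic_cohort.py   cohort generator (signals, covariates, outcomes)
  data_io.py            WFDB-style record I/O, cohort selection rules, containers
  signal_spectral.py    conditioning filter and STFT featurization
  clinical_preprocess.py fold-scoped imputation and scaling
  models.py             numpy BiLSTM, lasso-logistic, OLS, combined recipes
  evaluation.py         repeated stratified CV, AUC/CI, operating points
  perturbation.py       band ablation, column shuffle, cropping experiments
  cli.py                command-line orchestration
docs/methods.md         statistical methods and design rationale
scripts/acceptance.py   headline-quantity computation
tests/                  unit, property, and acceptance tests
```
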