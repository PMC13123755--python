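# surgdur — pediatric-urology surgical duration prediction

`surgdur` is a research toolkit for predicting how long a pediatric
urological operation will occupy the operating room — the interval from
anesthesia induction until the patient leaves the room — from the data
available *before* surgery: patient demographics (age, weight), the primary
procedure, surgeon attributes (identity, years of practice, annual case
volume), multilabel preoperative diagnoses, messy free-text surgical plans,
and free-text preoperative narratives. Accurate per-case estimates of this
interval are the input every OR scheduling system needs; the naive
alternative (booking every case at the historical mean) misallocates an hour
or more of room time per day.

It is aimed at clinical-informatics researchers who want to reproduce,
stress-test or extend this class of models without access to protected EMR
data: a seeded synthetic-cohort simulator generates realistic raw records
(including the messy plan strings and narrative text) with known ground
truth, so the entire pipeline is testable end to end.

## The model

Heterogeneous features are processed in two blocks:

* **tabular** — standardized numerics, one-hot primary procedure (4
  categories), multilabel diagnoses (vocabulary of labels occurring ≥ 10
  times plus a "rare type" bucket) and multilabel surgical-plan categories.
  Raw plan strings are split on heterogeneous delimiters ("+", ",",
  "simultaneously perform"), synonym-normalized, left/right collapsed to
  "unilateral" (bilateral kept distinct), and consolidated into 23
  standardized procedure categories;
* **text** — four structured narrative fields (prepuce / testicular /
  scrotal / penile characteristics) extracted from the preoperative note
  with evidence spans, each embedded to a fixed 256-d vector
  (4 × 256 = 1024; missing text → null vector).

The regressor is a **multihead MLP**: each block passes through its own
Dense(256)→ReLU→Dropout(0.3)→Dense(128)→ReLU→Dropout(0.3) subnetwork; the
two 128-d representations are concatenated and fused through
Dense(64)→ReLU→Dropout(0.3)→Dense(1). Training minimizes

```
MSE = (1/n) Σᵢ (yᵢ − ŷᵢ)²
```

on the standardized duration with Adam (lr 0.001, batch 32, ≤ 200 epochs,
early stopping on validation loss). Splitting the heads prevents the 1024-d
text block from drowning the 4-d procedure vector, the failure mode of a
single concatenated input. Evaluation uses MAE and RMSE in minutes and
R² = 1 − RSS/TSS. Feature influence is measured by grouped permutation
importance: all columns of one logical feature (a one-hot block, a
multilabel block, one 256-d embedding) are shuffled jointly and the MAE
degradation recorded.

Also included: ridge / decision-tree / SVR / random-forest / gradient-
boosting baselines, a naive training-mean predictor, and an LSTM + mixture-
density-network comparator (token embeddings → LSTM → Gaussian mixture
α, μ, σ; point prediction Σ αμ).

## Worked example

```python
import numpy as np
from surgdur import (CohortFeaturizer, MultiheadMLPRegressor,
                     default_spec, generate_cohort, split_dataset,
                     compute_metrics)

cohort = generate_cohort(default_spec(seed=42))       # 4526 synthetic cases
split = split_dataset(len(cohort.records), 0.15, 0)   # 3168 / 679 / 679

feat = CohortFeaturizer().fit([cohort.records[i] for i in split.train])
train = feat.transform([cohort.records[i] for i in split.train])
val = feat.transform([cohort.records[i] for i in split.validation])
test = feat.transform([cohort.records[i] for i in split.test])

model = MultiheadMLPRegressor(seed=0)
model.fit((train.tabular, train.text), train.y_min,
          validation=((val.tabular, val.text), val.y_min))

pred = model.predict((test.tabular, test.text))
print(compute_metrics(test.y_min, pred))
base = np.full(test.n, np.concatenate([train.y_min, val.y_min]).mean())
print(compute_metrics(test.y_min, base))
```

Output:

```
Metrics(mae=11.68..., rmse=17.13..., r2=0.549..., n=679)
Metrics(mae=19.39..., rmse=25.50..., r2=-0.000..., n=679)
```

The fusion model's average error is 11.7 minutes against 19.4 minutes for
the mean predictor — a ~40 % reduction, worth roughly 38–61 minutes of
recovered schedule per room per day at 5–8 cases/day. Grouped permutation
importance (`surgdur.evaluation.permutation_importance`) ranks the primary
procedure as the dominant predictor, matching the simulator's ground-truth
duration model.

The same chain is available from the shell:

```bash
surgdur simulate  -c config.yaml
surgdur featurize -c config.yaml
surgdur train     -c config.yaml
surgdur evaluate  -c config.yaml
# also: crossval, importance, ablate, compare-embeddings,
#       compare-baselines, extract, score-extraction
```

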