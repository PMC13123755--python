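# Methods

This note documents the generative model behind the synthetic cohort, the
feature-engineering rules, the model architectures and training procedure,
the evaluation design, and the numerical/design choices made where the
problem was genuinely open. Nothing here reports a number the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohort model

Real pediatric-urology EMR data cannot be redistributed, so the package
ships a simulator whose draws reproduce the marginal statistics of the
emulated reference cohort (N = 4526): four primary procedures — penile
lengthening 45.7 %, laparoscopic high ligation of the processus vaginalis
25.6 %, orchidopexy 20.7 %, circumcision 8.0 % — durations averaging
38.6 min (SD 24.9), ages 5.3 y (SD 3.7, range 0–17), weights 24.6 kg
(SD 14.6, range 5–140), and a roster of 31 surgeons including "unknown".

**Duration.** Surgery time is log-normal within strata:

```
log d = β₀ + β_proc(p) + β_bil·1[any bilateral plan]
        + β_extra·(n_planned − 1) + β_exp·z_exp + ε,   ε ~ N(0, σ_log)
```

with procedure effects (relative to penile lengthening) high ligation
+0.52, orchidopexy +0.90, circumcision −0.62; bilaterality +0.40; +0.15 per
additional planned procedure; −0.08 per SD of surgeon experience. β₀ =
3.07786 and σ_log = 0.35863 were solved numerically (from the exact
moment identities for a log-normal around the simulated systematic part)
so the marginal mean/SD equal 38.6/24.9 min; the population mean was
verified at 38.64 ± 0.04 on 5 × 10⁵ draws. The procedure effect carries
most of the explainable variance by construction, so the true importance
ranking (procedure ≫ plan attributes > surgeon experience) is known and
recoverable. The experience effect is centered and scaled on the realized
roster rather than on the sampling distribution: with only 30 named
surgeons a roster-mean fluctuation would otherwise shift every cohort's
duration mean by up to ~0.6 min.

**Primary-procedure mix.** The emulated cohort is a census with fixed
per-procedure counts, so the mix is assigned as exact stratified counts
(largest-remainder rounding, then shuffled), not an i.i.d. multinomial
draw; shares are exact up to rounding at any cohort size.

**Age and weight.** Age is a log-normal truncated to [0, 17] y with
μ = 1.52572, σ = 0.86481, solved so the truncated mean/SD equal 5.3/3.7.
Weight follows a quadratic growth curve 8.2017 + 2.7·a + 0.05·a² kg with
multiplicative log-normal noise (s = 0.25593, mean-one), clipped to
[5, 140]; the intercept and noise scale were solved from the truncated age
moments so the marginal mean/SD equal 24.6/14.6 kg. The curve is slightly
heavier than reference growth charts at the oldest ages — the cost of
matching both the age mixture and the weight marginals with a two-parameter
noise model.

**Raw-record messiness.** Plans are rendered with a randomly chosen
delimiter style ("+", ",", "，", "simultaneously perform"), synonym
variants ("orchiopexy", "circumcision (stapler)", …) and laterality wording
("right-sided …", "bilateral …"); the canonical plan list is recorded in
the truth table, so normalization can be tested as an exact inverse. Four
narrative fields (prepuce/testicular/scrotal/penile) are rendered from a
catalog of attribute sentences whose distribution depends on the case's
procedure and laterality (so text genuinely carries duration signal;
`narrative_signal=False` severs that link for ablation tests). The note
adds an admission sentence carrying the age (the imputation fallback
source) and one neutral boilerplate sentence. Per-field missingness
defaults: age text 2 %, weight 2 %, surgeon metrics 3 %, narratives
15–25 %.

**What the simulator does not model.** Within-stratum correlations beyond
the stated duration model (e.g. age–procedure dependence, surgeon–procedure
specialization), seasonal or scheduling effects, free-text style drift, and
any language other than English. Passing tests therefore demonstrate that
the pipeline recovers a known generative structure of this family — not
clinical performance on real EMR text.

## Feature engineering

* Age "Y years M months" → Y + M/12; unparseable → the age extracted from
  the note; else the training mean (with a warning).
* Weight outside [5, 140] kg (the observed plausible range) is treated as
  missing and imputed by the mean weight of the same integer-year age bin,
  fitted on training rows, nearest populated bin as fallback.
* Numerics (age, weight, surgeon years/volume) standardized with
  training-only statistics; missing surgeon numerics take the training
  column mean.
* Diagnoses split on commas; labels with ≥ 10 training occurrences form the
  vocabulary (first-appearance order), the rest collapse to "rare type".
  The threshold is applied to training rows only, to keep the schema free
  of test-set information.
* Plans: delimiter split → synonym map → laterality pooling (left/right →
  "(unilateral)"; "(bilateral)" kept) → consolidation into 23 standardized
  categories (unmapped → "other surgical procedures") → multilabel encoding
  with the residual category as the rare bucket.
* Text: the rule backend extracts the four structured fields with verbatim
  evidence spans; each field is embedded to 256 dimensions, concatenated in
  fixed order (prepuce, testicular, scrotal, penile); missing fields are
  null vectors. Two surgeon configurations: identity one-hot ("name") or
  years + volume ("metrics", the default — it generalizes to unseen
  surgeons). Unseen one-hot categories at transform time encode as all-zero
  rows with a warning.
* Target: plain standardization of raw minutes (mean 0, SD 1) on training
  rows; a log-then-standardize switch exists but is off by default, since
  the standardized-minutes formulation is the primary contract and the
  log-normality of durations is already captured by the generator.

The offline embedder hashes character 3–5-grams into 256 signed buckets and
scales to unit norm. It is deterministic across platforms, needs no weights
or network, and treats "text → fixed 256-d vector" as the swappable
contract it is; a remote-service client with length validation sits behind
the same interface (responses passed through unnormalized, since a hosted
model's geometry should not be silently rescaled).

## Extraction scoring

Consistency is scored per case on 0–100: any populated field whose evidence
span is not a verbatim substring of the source note, whose value
contradicts the reference, or which has no counterpart in the reference, is
a fabrication and zeroes the case; otherwise the score is 100 × (correct
fields)/(reference fields). One "information unit" per reference field is
the simplest auditable reading of proportional scoring. A per-field mode
(zeroing only the fabricated field) is available behind a switch.

## Models and training

All neural models are implemented directly on NumPy via a small in-package
reverse-mode autodiff core (`_autograd.py`), keeping the package
dependency-light and bit-reproducible for a fixed seed on one platform.
Dense layers use Glorot-uniform initialization; optimization is Adam
(lr 0.001), batch 32, MSE loss, ≤ 200 epochs with early stopping
(patience 10 on validation loss, best weights restored — patience is a
conventional default; the cap is the stated 200). Targets are standardized
internally with training statistics; predictions return in minutes.

* Multihead: Dense(256)→ReLU→Drop(0.3)→Dense(128)→ReLU→Drop(0.3) per
  block; fused 128+128 → Dense(64)→ReLU→Drop(0.3) → Dense(1, linear).
* Single-head variants share the same widths (256→128→64→1) on the
  selected block(s), the natural reading of the dimension-imbalance
  argument.
* ML-MDN comparator: whitespace/punctuation tokenizer (pad 0, unknown 1,
  sequences padded/truncated to 64), 64-d learned token embeddings, a
  64-unit LSTM whose final state joins the structured features, a dense
  layer, and a 3K-output mixture head: α by softmax, σ by softplus + 10⁻⁴
  floor, trained by the mixture negative log-likelihood; the point
  prediction is Σ αμ. K = 3 components by default (the "three parameters"
  are α/μ/σ, not a component count; K is configurable). LSTM/embedding/
  sequence sizes of 64 keep the comparator desk-scale.
* Classical baselines use scikit-learn defaults (seeded where stochastic)
  on the same concatenated feature matrix as the neural models; "mean"
  predicts the training mean.

In the text-embedding comparison, the token+LSTM strategy reuses the
ML-MDN text path with K = 1 (a single-Gaussian likelihood, equivalent to a
heteroscedastic MSE regressor), so all three strategies differ only in
their text representation.

## Evaluation design

* **Split**: test = round(0.15 n); validation = the same count drawn from
  the remainder; rest training. The printed reference counts
  (679/679/3168 of 4526) conflict with a nominal 85:15 second-stage ratio
  (679 of 3847 is 17.65 %); the printed counts win.
* **Cross-validation** refits the schema, target statistics and model
  inside every fold.
* **Permutation importance** shuffles logical groups jointly (per-column
  shuffling of one-hot or embedding blocks would fabricate rows that lie
  off the data manifold); 10 repeats by default, seeded; MAE is the
  reported criterion.
* Scatter data (true vs predicted) is exported as CSV; plotting is left to
  the caller.

## Problem sizes in the test suite

The full-scale checks (multihead vs mean baseline, importance recovery) run
on the complete 4526-case default cohort. The architecture-comparison
experiments (ablation ordering, no-text-signal equivalence, embedding
strategies) run on 1000–1200-case cohorts with a 60-epoch cap, sizes at
which the relevant orderings are already stable; their MAE comparisons
carry a 2-minute a-priori tolerance because small-sample MAEs of two
stochastic learners differ by noise. Unit tests use 200–500-case cohorts.

## Known limitations

* The rule-based extraction backend shares its sentence catalog with the
  narrative renderer; its perfect score certifies the scoring machinery and
  the pipeline plumbing, not free-text robustness.
* The hashing embedder captures lexical, not semantic, similarity;
  conclusions about embedding-model quality do not transfer.
* Determinism is per-platform (BLAS reduction order may differ across
  builds); seeds reproduce results exactly only on one platform.
* The MDN's density estimates are used only through their expectation; no
  calibration of the predictive distribution is attempted.
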