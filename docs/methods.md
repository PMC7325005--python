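# Methods

## Problem and model

`ssirisk` predicts the risk of surgical site infection (SSI) for an
inpatient *before* the operation, from two modalities that routine EMR
systems already contain: a vector of structured preoperative features
(demographics, lab panels, admission flags, preoperative length of stay)
and the free text of the preoperative note.  The outcome is binary and
rare (on the order of 1% of operations), so every model is trained with
a class-weighted cross-entropy in which each positive case carries
weight w⁺ = N₋/N₊.

Five model families are implemented:

* **L1-penalised logistic regression**, **random forest** and
  **gradient-boosted trees** (via scikit-learn and XGBoost) on the
  structured design matrix, optionally concatenated with a 128-dim text
  vector obtained by **column-wise max-pooling** of the note's embedding
  matrix T = [t₁ … tₙ] (tᵢ the i-th token's embedding);
* a **convolutional text network**: channels cⱼᵢ = GELU(wⱼ·tᵢ:ᵢ₊ₕ₋₁ + b)
  for filter windows h ∈ {3,4,5}, max-pooled per channel, concatenated
  with the structured vector, then a GELU dense layer and a sigmoid
  output.  GELU is the exact Gaussian-CDF form x·Φ(x);
* a **Bi-LSTM self-attention network**: hidden states H (n × 2m) from
  forward/backward LSTMs; attention A = softmax(W₁·tanh(W₂·Hᵀ)) with
  bias-free W₁, W₂, each of the d₂ attention rows a distribution over
  token positions; sentence embedding M = A·H flattened (d₂·2m values),
  fused with the structured vector through the same dense/sigmoid head.

Both deep networks and their training loop (AdamW with decoupled weight
decay, mini-batches, dropout, optional early stopping on validation
AUROC with patience 3) are implemented directly in NumPy with
hand-written backward passes; the analytic gradients are verified
against central finite differences in the test suite, and the forward
passes against independent straight-line loop implementations.

## Word embeddings

Token vectors come from a subword-aware skipgram model trained with
negative sampling.  A word is represented by the character n-grams
(sizes 2–5) of its boundary-marked form `<word>` plus a whole-word
vector; the word's vector is the mean of its subword-gram vectors plus
the whole-word vector, so out-of-vocabulary words can be composed from
their grams (unknown grams contribute nothing; a word with no known
grams maps to the zero vector).  Gram vectors live in a hashed bucket
table (2×10⁵ buckets by default) for bounded memory; an exact-gram mode
exists for composition tests.  Training details that matter:

* pairs are (center, context) within a per-token random window r ≤ 5,
  with 5 negatives drawn from the unigram^0.75 distribution; negatives
  that collide with the center or the true context are skipped;
* updates are applied in small vectorized batches (256 pairs); gradients
  hitting the same embedding row within a batch are **averaged**, not
  summed, which keeps the per-row step bounded when the vocabulary is
  small relative to the batch — without this the optimisation diverges
  on the small synthetic corpora the tests use;
* learning rate 0.1 decaying linearly to ~0; optional frequent-word
  subsampling (off by default — the synthetic corpora have no extreme
  frequency skew);
* fully deterministic under a fixed seed (single-threaded NumPy).

Sequence inputs to the deep networks are left-zero-padded (or
left-truncated) to a fixed length n_pad = ⌈Q3 + 1.5·IQR⌉ of the
development-split note-length distribution, with linear-interpolation
quantiles.  Padding positions are masked out of the convolutional
max-pooling (a window participates if it touches ≥ 1 real token) and out
of the attention softmax, so left padding can never attract attention
mass; this masking is a deliberate design choice where a naive reading
would let pads participate.

## Preprocessing

All statistics are estimated on the development split only and frozen.

1. **Outlier screen** (continuous features): two-stage adjusted-residual
   procedure.  Stage 1 regresses the feature on age and sex, divides
   residuals by a robust SD (1.4826 × MAD, so outliers cannot inflate
   their own yardstick), and excludes cells with |r| > 5; stage 2 refits
   on the retained rows and flags cells with |r| > 5 under the refit.
   Flags are reported, never auto-applied; `apply_outlier_flags`
   converts them to missing, emulating the treatment of values that fail
   chart review.  The adjustment is a single-site fixed-effects
   regression — with one hospital there is no grouping factor for a
   random-effects formulation, so the fixed-effects fit preserves the
   screen's intent.
2. **Missing-value indicators** — one binary `<feature>__missing` column
   per feature with at least one missing development cell — are added
   *before* imputation so the missingness pattern survives it.  At
   inference the indicators are recomputed from the raw missingness.
3. **Imputation**: mean for continuous, mode for binary/categorical.
4. **Encoding/normalization**: one-hot over development categories
   (categories unseen in development map to an all-zero block with a
   warning); continuous features z-scored with development moments.
   Whether indicator/one-hot columns should also be normalized is
   ambiguous in the source protocol; the default normalizes continuous
   features only, with `normalize_all=True` available.

## Validation protocol

* **Internal**: 100-iteration out-of-bag bootstrap.  Each iteration
  draws n records with replacement, refits the *entire* pipeline
  (indicators, imputation, normalization, pooling, model) on the
  resample, and scores the out-of-bag records.  Refitting preprocessing
  inside each iteration is the leakage-safe reading of the protocol.
  The AUROC vector is summarised by its mean and a t-interval
  (percentile interval by flag); families are compared by paired-sample
  t-tests across iteration-aligned vectors.  Bootstrap resamples
  overlap, so these tests violate independence; they are implemented as
  the protocol prescribes and should be read descriptively.
* **External**: the model trained on the full development split scores
  the held-out test split once; the operating point maximises Youden's
  J = sensitivity + specificity − 1 over all distinct scores
  (score ≥ t ⇒ positive; ties resolve to the lowest threshold).  An
  NNIS risk-index column, when present, is evaluated as baseline.
* AUROC is the Mann–Whitney U statistic divided by N₊N₋ with half
  credit for ties.

## Explanation

* Population level: ranked nonzero coefficients of the without-text L1
  logistic model on the normalized design matrix (indicators included).
* Case level: a local surrogate.  With structured features fixed, each
  of 10,000 perturbations keeps every token independently with
  probability 0.5; the black-box model scores the perturbed (re-padded)
  notes; an L1 regression (penalty 0.01) of scores on token-presence
  indicators gives per-position coefficients.  Presence coding (1 =
  kept) makes a positive coefficient a risk-increasing word, matching
  the red/green heatmap semantics; the alternative removal coding only
  flips signs.  For an exactly additive scorer the surrogate recovers
  the true weights (within 10% at weak penalty); the default 0.01
  penalty shrinks small contributions toward zero, which is intended.

## Synthetic data

Real preoperative EMR extracts are private, so the package ships a
generator that emulates the statistical structure the pipeline assumes,
and all tests run against it:

* 47 structured features (age, sex, anthropometrics, blood routine,
  coagulation, liver/kidney panel, electrolytes, admission flags,
  anesthesia type, preoperative LOS) with realistic means/SDs, mild age
  and sex loadings (so the adjusted-residual screen has something to
  adjust for), and per-feature missing rates from 0% to 73%;
* notes are whitespace-tokenizable token sequences, length ~N(120, 60)
  truncated at 5, over a Zipf-weighted background vocabulary; planted
  risk/protective keywords appear independently per note (default
  prevalence 0.2) — whitespace tokens keep the pipeline testable without
  a Chinese word segmenter, which is an injected interface, not an
  algorithmic step;
* labels follow logit(p) = b + Σβⱼzⱼ + Σγₖ·1[keyword k], with the
  intercept calibrated by bisection to the target prevalence (default
  1.13%, matching the study setting); default structured effects are
  moderate (|β| 0.25–0.5 per SD) and default keyword effects are ±1.0
  to 1.5 log-odds;
* an optional MNAR mode makes a feature's missingness depend on the
  label; outliers can be injected at known positions with a truth mask;
  an NNIS-like 0–3 column is derived from a noise-degraded version of
  the true logit, giving the baseline a deliberately mediocre AUROC;
* the split is 80/20 by generation order, standing in for a temporal
  split.

What the generator does **not** emulate: real clinical prose and
segmentation ambiguity, inter-feature lab correlations, temporal drift
between development and test periods, ICD-10 case mix.  Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
it recovers signal it is pointed at — not that the reported clinical
discriminations would reproduce on hospital data.

## Desk-scale experiment sizes

The replication experiments (and the reproduction script) run on one
CPU, so they use reduced sizes chosen as the package's own desk-scale
operating points: cohorts of n = 8,000 at 5% prevalence (≈ 400
positives; at the study's 1.1% a single held-out split would contain
~18 positives and the AUROC estimate would be too unstable for
seed-replication checks), 32-dim embeddings trained on a synthetic
co-occurrence corpus built around the planted keywords, a CNN with 8
channels per window and 5 epochs, and an attention network with m = 16,
d₁ = 32, d₂ = 4 and early stopping.  Learning rates are larger than the
full-scale defaults (2×10⁻³ / 5×10⁻³ instead of 10⁻⁴) because the
reduced runs take two orders of magnitude fewer optimisation steps.

Under these conditions the Bayes-optimal AUROC of the generating model
is ≈ 0.89 (measured by scoring the held-out split with the true
logits).  Across ten seeded replicates the conventional families with
pooled text embeddings reach ≈ 0.81–0.90; both deep networks land at
≈ 0.77–0.85 — always clearly above every structured-only model, but
short of the ceiling.  The gap is a training-budget effect: five epochs
at these sizes amount to a few hundred gradient steps, and the
attention network in particular overfits the ~320 development positives
before its attention learns to focus sharply (train AUROC 0.88 against
held-out 0.79 on a probe seed; the explored grid covered hidden size
8–32, learning rate 10⁻³–2×10⁻², dropout 0–0.5, weight decay 0.03–0.3,
up to 15 epochs, frozen or fine-tuned embeddings).  This mirrors the
known data-hunger of recurrent-attention encoders relative to
convolutional ones on small corpora; the package reports the deep
models' desk-scale AUROCs as measured rather than tuning the generator
until the numbers look better.

## Numerical choices and degenerate inputs

* Probabilities are clamped to [10⁻⁷, 1−10⁻⁷] in the loss; training
  aborts with diagnostics if the loss becomes non-finite.
* Zero-variance continuous features are dropped with a warning;
  features with < 30 observed values are skipped by the outlier screen.
* A note whose tokens are all out-of-vocabulary (or removed by
  perturbation) contributes a zero text block; the CNN pools only
  windows touching real tokens, the attention softmax returns all-zero
  rows when no real position exists.
* Bootstrap iterations whose resample or out-of-bag set is single-class
  are redrawn (at most 10 times, logged).
* Paired t-tests on zero-variance differences use p = 1 (zero mean) or
  p = 0 (nonzero mean) by convention.
* Percentages are rounded half-up to 2 decimals, the convention of the
  reported cohort tables.

## Known limitations

* The deep models are CPU-bound NumPy implementations; full-scale
  settings (256 channels / 256 hidden units, 18–19 epochs, n ≈ 17,600)
  are supported but slow — they are meant for overnight runs, not the
  test suite.
* The L1 "penalty" maps to scikit-learn's `C` as C = 1/penalty; other
  parametrizations of the same model rescale this constant.
* No model-based or multiple imputation; no calibration metrics; no
  transformer encoders.
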