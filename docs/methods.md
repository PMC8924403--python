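# Methods

## Task and data model

The unit of classification is one (report, organ) pair: does the target
CT report describe metastatic disease in that organ? Reports follow a
structured template of 13 organ-specific "Findings" paragraphs plus an
"Impression". Three organs are modeled (lungs, liver, adrenal glands);
labels are binary (Yes → 1, No → 0), with unannotated reports excluded
from training and evaluation but still labeled at map-building time.

Model input is the target organ's findings section only. The impression
can mention any organ, so including it would leak cross-organ signal
into a single-organ classifier; a flag (`include_impression`) appends it
for users who want the fuller context.

## Preprocessing

Two regex substitutions run before any tokenization, measurement first,
then dates:

* measurements — a decimal number, optionally `x`-joined with up to two
  more, followed by `mm`/`cm` (case-insensitive, optional space) →
  literal token `measurement`;
* dates — numeric d/m/y with `/` or `-` separators (2- or 4-digit
  years), ISO y-m-d, and month-name forms ("March 26, 2021") → literal
  token `date`.

The substitution shrinks the vocabulary and preserves the higher-level
concept: *that* a lesion was measured is strong evidence of reported
disease; its size is noise at this task's granularity. Both tokens are
digit-free, so normalization is idempotent.

The *history document* for target exam t concatenates the normalized
organ findings of exams 0..t, oldest to newest, joined by single
newlines; the document for exam t is therefore a prefix of the one for
exam t+1. The single-report baseline uses the t-th findings text alone.

### Split

Reports are split 70/15/15 (train/test/validation) by seeded uniform
shuffle with holdout = ⌈0.30·N⌉, test = ⌈holdout/2⌉, validation =
holdout − test. This ceil arithmetic reproduces the published per-organ
split sizes exactly for N = 7,733 / 2,777 / 4,107 (plain rounding does
not). The split unit is the report, matching those published counts, so
one patient's reports can straddle splits; `patient_of` switches to
whole-patient assignment (approximate counts) when leakage control
matters more than fidelity.

## Single-report baseline

TF-IDF (sklearn dialect: smoothed idf, L2 normalization, vocabulary from
the training split only) feeds four base models: logistic regression
(inverse-regularization C = 15.0 — the parameterization commonly exposed
by LR implementations, recorded here as an interpretation of
"regularization strength 15.0" — balanced class weights, Newton-CG),
a linear SVM whose probabilities come from Platt-style sigmoid
calibration on training folds, a random forest (2,000 trees, bootstrap,
√p features per split), and gradient-boosted trees at library defaults.

Soft voting: per-model score s_m = (accuracy + precision + recall)/3 on
the training split, weight w_m = s_m / Σ s_k (the simplest ranked
weighting consistent with comparing those three metrics), ensemble
confidence Σ w_m p_m, label 1 iff confidence ≥ 0.5. The exact tie
resolves positive: in metastasis detection a false negative costs more
than a false positive. Weights are fitted per organ.

## Multi-report networks

Implemented directly in numpy (forward, analytic backward, Adam with
lr 10⁻³, β = 0.9/0.999), giving bit-reproducible training under a seed
on any platform. Gradient correctness is property-tested against central
differences for every parameter block.

* **Tokenization (CNNs):** lowercase, punctuation stripped, indices by
  descending training frequency from 1; unknown words are dropped.
  Sequence length is the 95th percentile of training-document token
  counts; longer documents are truncated from the *front* so the newest
  report — the one carrying the label — is always retained; padding
  index 0.
* **Simple CNN:** embedding dim 50 → 1-D convolution, 64 filters,
  kernel 3, ReLU (3·50·64 + 64 = 9,664 parameters, asserted in tests) →
  global max pooling → dense 10 ReLU → dense 1 sigmoid; binary
  cross-entropy.
* **Local self-attention (Augmented CNN):** after the convolution,
  multiplicative scores e_{t,s} = σ(h_tᵀ W h_s + b) over the window
  |s−t| ≤ ⌊width/2⌋, default width 1. In the default normalized mode the
  window scores are divided by their window sum, so at width 1
  a_{t,t} = 1 and the layer is an exact identity — the sigmoid score
  then shapes training only through the un-normalized mode
  (`normalize=False`, o_t = e_{t,t}·h_t), which is provided because the
  normalization semantics of sigmoid-activated attention are genuinely
  ambiguous; both modes are tested and the identity limit is asserted
  against the Simple CNN.
* **Bi-LSTM:** alphabetical vocabulary with indices from 2 (0 = padding,
  1 = unknown; unknowns are *kept*, unlike the CNN tokenizer); per-batch
  right-padding to the batch maximum with masked carry-through, so a
  sequence's output is invariant to its batch partners (tested at
  1e-5). Standard gates (input/forget/candidate/output; σ recurrent
  activation, tanh cell activation; forget bias init 1), 32 units per
  direction concatenated to a 64-dim representation — the stated
  combined output dimension 64 read as 32 per direction; the 64-per-
  direction alternative is selectable via `BilstmSpec` — then dense 64
  ReLU and a single output with no activation, trained with from-logits
  cross-entropy; gradient clipping at global norm 5.

Training defaults: 30 epochs, batch 32, early stopping patience 5 on
validation loss with best-checkpoint restore. The acceptance-scale
comparisons use 12 epochs / patience 3, which the separable synthetic
corpora saturate comfortably; these sizes are the package's reproducible
experiment defaults.

## Synthetic corpus generator

The simulator emulates exactly the structure the method exploits and
nothing more:

* **Trajectories.** Per organ, a Markov chain starting negative with
  per-exam onset hazard and (default 0) resolution probability —
  metastases persist once reported. Exams per patient: 1 + Geometric
  (p = 0.5) capped at 12 (mean ≈ 3 serial CTs, a realistic oncologic
  follow-up cadence; the cap keeps timelines plausible).
* **Rendering.** New positives draw an organ-specific phrase with an
  embedded measurement string and, with probability 0.3, an in-text date
  mention; persisting positives use measurement-free "stable/no change"
  wording with probability q_stable (default 0.7), else a re-measured
  phrase; negatives draw negative wording, and *follow-up* negatives may
  use the same stable wording verbatim — the deliberate ambiguity that
  makes single-report labeling of follow-ups impossible. Negative lung
  sections mention a measured benign nodule at rate 0.05 (granulomas and
  other incidental measured findings), the confounder that costs
  measurement-token precision specifically in the lungs. The impression
  names currently positive organs.
* **Calibration.** Report-level prevalence targets (0.166 lungs, 0.305
  liver, 0.071 adrenals) are hit by bisection on the onset hazard with
  Monte-Carlo evaluation over 10⁴ simulated timelines using common
  random numbers, making the objective exactly monotone.
* **Determinism.** One `numpy` Generator seeded from the config drives
  everything; identical (config, params, seed) produce byte-identical
  JSONL.

What the simulator does *not* model: real lexical variety, negation
scope, misspellings, cross-organ correlation of disease, treatment
response dynamics, inter-exam timing signal. Passing tests therefore
demonstrate that the pipeline recovers longitudinal signal of this
specific shape, not clinical-grade performance; on real text the lexical
separation between phrase banks would be far weaker and absolute scores
correspondingly lower.

## Evaluation and maps

Metrics come from confusion counts: accuracy, precision, recall
(defined as 0 and flagged when their denominators vanish), and F1 (the
harmonic mean). Published accuracy cells carry ± margins reproduced by
the 95% Wald binomial half-width 1.96·√(p(1−p)/n) with n the split size
(verified against four distinct printed cells); precision/recall margins
use the predicted-positive and actual-positive counts as n. Comparison
tables render one row per model/metric and one column per organ/split,
with per-column best flags (ties flagged jointly), as TSV or markdown.

`build_metastases_map` labels every report × organ of a corpus through
each organ's fitted classifier (history documents for the multi-report
models, target-report text for the baseline), yielding a patient × organ
× exam-date table with confidences and derived first-positive dates;
exports are TSV and per-patient JSON. With a ground-truth oracle in
place of a classifier, the map reproduces the simulator's trajectories
exactly — the machinery adds no distortion.

## Numerical and design notes

* Same-day exams order by report_id, making timeline order total and
  deterministic.
* Dates are stored ISO-8601 internally; in-text date strings are
  normalization fodder only.
* Baseline text receives the same date/measurement normalization as the
  neural models', keeping the feature space comparison fair; whether the
  original single-report system normalized identically is not
  documented, so this is recorded as an assumption.
* Empty encoded sequences at prediction time (all-unknown text under the
  CNN tokenizer) are padded to a single padding index and flagged in the
  returned `Predictions.empty_input`.
* The acceptance-scale experiment sizes — 5,000 patients for
  calibration, 3,000 patients × 5 seeds for the headline comparison in
  the test suite, 1,500 patients × 3 seeds in the acceptance script,
  1,000 patients for map equivalence — are the package's chosen
  reproducible problem sizes.

## Known limitations

* The numpy networks are CPU-only and single-threaded; they are sized
  for the architectures above, not a general deep-learning substrate.
* Width-1 normalized attention is an exact identity; the augmented CNN
  differs from the simple CNN under the default configuration only
  through initialization-stream effects unless `normalize=False`.
* The per-report split mirrors the published counts but allows patient
  leakage across splits; synthetic-corpus scores are therefore
  optimistic relative to a grouped split.
* Template parsing assumes well-formed heading lines; heavily deviating
  real-world reports would need the (out-of-scope) exclusion heuristics
  of a production ingest.
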