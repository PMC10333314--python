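# Methods

## Problem and model

voxdep assesses depression from speech through speaker-identity embeddings:
fixed-length vectors (x-vector 512-d, ECAPA-TDNN 256-d, d-vector 192-d, or
synthetic) extracted per 5–6 s segment of participant speech.  Two tasks are
supported, both operating on *context windows* of C contiguous segments:

* **detection** — binary classification against the clinical threshold
  (PHQ-8 ≥ 10 or MADRS ≥ 10), reported as per-class F1 and balanced
  accuracy; a recording's label is the majority vote over its window
  decisions, with ties resolved to "depressed" (in screening, a false
  negative is the costlier error);
* **severity estimation** — regression of the PHQ-8 (0–24) or MADRS (0–60)
  score, reported as RMSE; a recording's score is the mean of its window
  scores, clipped to the scale.

Four network families share a common recipe (Adam with β₁ = 0.9, β₂ = 0.99,
learning rate 5·10⁻⁴, batch size 128, 50 epochs, no early stopping;
weighted negative log-likelihood for detection, MSE for severity;
inverse-frequency class weights normalised to mean 1):

* **MK-CNN** — three parallel full-width convolution branches with kernel
  heights 3, 4, 5 (50 channels, stride 1, valid padding), each followed by a
  kernel-4 temporal convolution (50 channels), ReLU throughout; flattened
  branch outputs are concatenated (dropout 0.3), passed through a 100-unit
  FC layer (ReLU, dropout 0.3) and the output head.  The flattened size is
  50·Σ_k (C−k−2), requiring C ≥ 8.
* **LSTM** — two 128-unit LSTM layers (standard sigmoid/tanh gating,
  dropout 0.4 between layers); the last-timestep state feeds the 100-unit FC
  layer and head.
* **DNN baseline** — a 128-64-128 ReLU stack on single segment vectors
  (optionally on mean-pooled windows), straight to the head.
* **CE fusion** — two branches (MK-CNN or LSTM block plus 100-unit FC each),
  one per feature stream, combined by the elementwise product of the two
  100-d FC outputs before the head.  A literal scalar dot product would feed
  the head a single number and make the detection softmax nearly degenerate;
  it remains available as `fusion="scalar"` for comparison.  Branch FC
  biases are initialised at +1: the product of two mostly-active ReLU
  vectors behaves quasi-additively early in training, which avoids the
  dead-unit gradient silencing that multiplicative fusion otherwise suffers
  from at small data scales.  Dropout in the fusion families is applied
  inside the blocks only, not a second time per branch FC — stacking two
  independent dropout masks before a product silences about half the fused
  units per step and measurably destabilised training.

The networks are implemented in a small numpy forward/backward core
(`voxdep._nn`) with uniform fan-in initialisation under the run seed;
training is bit-reproducible given the seed.  Severity targets are z-scored
internally during training and predictions mapped back to the scale
(`standardize_targets=True`), which keeps the fixed learning rate
appropriate across scales.

## Evaluation protocol

Cross-validation is 5-fold, speaker-disjoint and label-stratified: speakers
are shuffled within label strata under the seed and dealt round-robin to
folds through a single position counter, so fold sizes stay balanced and
per-fold class proportions are within one speaker of the global proportion.
A speaker whose label changes across longitudinal visits is stratified by
the first visit's label.  Per fold, the feature scaler (per-dimension
z-scoring with a 10⁻⁸ std floor), the class weights and the model are
fitted on training folds only.  Pooled metrics concatenate all held-out
recording-level predictions; per-fold metrics are reported alongside.

Severity predictions can be binned into the clinical PHQ-8 groups
(None ≤ 8, Mild 9–12, Moderate 13–16, Severe 17–24; predictions rounded
half-to-even first) to form a 4×4 confusion matrix over clinical levels,
and compared with a no-information baseline (constant majority class /
constant training-mean score).

## Transcript handling

Transcripts are tab-separated with `start_time`, `stop_time`, `speaker`,
`value` columns; timestamps are half-open `[start, stop)` seconds and are
trusted (no audio decoding or diarization).  Participant-tagged rows are
retained, intervals separated by less than 0.05 s merged, and the retained
speech concatenated before tiling into 6 s windows; a trailing remainder is
kept iff ≥ 5 s, otherwise discarded (the range 5–6 s admits several tiling
policies; fixed-6 with a guarded remainder is the simplest that satisfies
it, and conservation — kept + discarded = retained, discarded < 5 s — is
property-tested).  Every segment inherits the recording's label.
Recordings shorter than one context yield a single cyclically padded
window, flagged `padded`.

## Synthetic cohorts

The generator (`voxdep.synthgen`) emulates the statistical structure the
analyses assume, so the pipeline is testable without clinical corpora:

* **Speaker identity**: each speaker has a unit base vector u_s, sampled in
  the orthogonal complement of the global depression direction v.  Keeping
  identity out of the severity direction makes severity identifiable from a
  single recording; if bases carried a random component along v (std 1/√L),
  that component would alias with the severity shift and impose an
  irreducible severity-estimation error of order y_max/√L — about 1.5
  PHQ-8 points at L = 64 — on any estimator whatsoever.
* **Severity shift**: segment embeddings are
  normalize(u_s + α·(y/y_max)·v_⊥ + σ·ε_t), with v_⊥ the depression
  direction re-orthogonalised against u_s (a no-op under the orthogonal
  sampling, kept for generality) and ε_t isotropic standard normal.  The
  shift changes the embedding's *angle*, never just its norm.
* **Severity scores**: a two-component truncated-normal mixture per scale —
  sub-threshold (mean 4, sd 3 on [0, 9]) and supra-threshold (PHQ-8:
  mean 14, sd 4 on [10, 24]; MADRS: mean 20, sd 8 on [10, 60]) — mixed by
  the configured depressed fraction (default 0.3), rounded to integers.
  This reproduces the heavy sub-threshold skew of clinical samples (overall
  mean ≈ 7, sd ≈ 6 on PHQ-8).
* **Acoustic stream**: a_t = acoustic_effect·(y/y_max)·w + m_s + σ·η_t with
  a fixed severity direction w, per-speaker nuisance m_s and isotropic
  noise whose component along w is √(1−ρ)·(ε_t·v_⊥) + √ρ·ξ_t: a fraction ρ
  of the acoustic severity channel's noise variance is independent of the
  embedding stream's, so at ρ > 0 fusing the streams averages partially
  independent errors and can beat either stream; at ρ = 0 the acoustic
  severity channel misreads severity exactly as the embedding does and adds
  nothing.
* **Longitudinal mode**: the speaker base is reused across visits and each
  visit draws a fresh severity from the mixture — the premise of the
  longitudinal analysis is precisely that severity changes between visits,
  and independent draws span the ΔMADRS axis.
* **Reproducibility**: random streams are split hierarchically from
  (seed, speaker-index), so a cohort is bit-identical under its seed and
  adding speakers never perturbs earlier speakers.

What the generator does **not** emulate: session/channel effects,
demographic covariance (age/sex are not linked to severity), non-isotropic
embedding noise, ASR or timestamp errors, and any nonlinearity in how
severity displaces embeddings.  Passing tests therefore demonstrate that
the pipeline recovers the planted linear-shift structure, not that the
method reaches any particular accuracy on clinical recordings.

## Longitudinal analysis

Each recording is summarised by the length-normalised mean of its segment
embeddings (median pooling available).  Genuine trials are all
within-speaker visit pairs, carrying |Δseverity|; impostor trials are
cross-speaker pairs subsampled to 10× the genuine count under the seed.
ΔMADRS bins have width 5 starting at 0; a bin contributes when it holds at
least 5 genuine trials.  The per-bin EER uses that bin's genuine
similarities against the *shared* impostor set, so only the genuine
population varies across bins.  The EER itself sweeps thresholds over the
pooled scores (FRR = fraction of genuine below t, FAR = fraction of
impostor at or above t) and linearly interpolates at the FRR/FAR crossing;
an exhaustive O(n·m) sweep is the test oracle.

Flatness of the no-effect control curve is judged by comparing the range of
bin means against twice the pooled SEM, where pooled SEM is the root-sum of
per-bin squared SEMs.  A per-bin 2-SEM bound would be mis-calibrated: under
perfect flatness the expected range of ~7 bin means already exceeds two
per-bin standard errors, so the aggregate bound is used; it accepts flat
curves reliably while rejecting every effect curve we generated.

The speaker probe draws 25 train / 15 test segments per speaker (speakers
with fewer than 40 segments are excluded and logged), fits a multinomial
logistic regression on the embeddings, and scores verification-style: the
true speaker's posterior on a test segment is a genuine score, every other
speaker's posterior an impostor score; the EER is reported in percent.

## Scaled-down experiment sizes

The acceptance-level experiments run the full pipeline at desk scale, with
sizes chosen as the smallest at which each effect is reliably measurable:

* **Signal recovery**: 100 speakers × 40 segments, 64-d embeddings, α = 2,
  σ = 0.1, context 8, stride 2, batch 32, 15 epochs, seeds 0–2.  Both
  window networks reach pooled BAc ≥ 0.9 and RMSE well under 0.3× the score
  spread; the constant-mean baseline's RMSE equals the score spread.
* **Fusion**: 150 speakers × 12 segments, 48-d streams, α = acoustic_effect
  = 1, σ = 0.5, ρ = 0.5, same training protocol, seeds 0–4.  The noise
  level puts single streams well off ceiling (BAc ≈ 0.72–0.78), where the
  fused model's averaging of partially independent errors is visible; with
  many recordings and few segments each, recording-level evaluation noise
  is kept small relative to the fusion margin.
* **Longitudinal**: 65 speakers × 4 visits, α = 2, σ = 0.05, 20 seeds, with
  an α = 0 control.

## Known limitations

* The numpy training core is CPU-only and single-threaded beyond BLAS; it
  is sized for desk-scale experiments, not corpus-scale training.
* The fusion families inherit the multiplicative bottleneck of the
  elementwise-product design; at small data scales their advantage over the
  best single stream is a few points of balanced accuracy and statistically
  thin per seed (means over seeds are compared).
* Real-embedding and OpenSMILE extraction are out of scope; the manifest
  and feature-matrix file formats are the adapter boundary for real data.
* The "GM" summary statistic reported alongside demographic baselines in
  some of the literature is not implemented (its definition is ambiguous).
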