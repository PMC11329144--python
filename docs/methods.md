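# Methods

`bruitnet` implements a screening pipeline for arteriovenous-graft (AVG)
stenosis from blood-flow sounds (bruit): weak labeling of recordings from
angioplasty (PTA) timelines, log-mel spectrogram features, a CNN14
classifier, and contrastive self-supervised pre-training on the unlabeled
majority of the corpus. This note documents the models, the parameters that
matter, the synthetic data the pipeline is exercised on, and the numerical
choices made where the design was genuinely open.

## Weak labeling from PTA timelines

A PTA is a balloon intervention that reopens a stenosed access, so the
intervention date itself carries label information: shortly before a PTA the
access was demonstrably stenotic, shortly after it was demonstrably patent.
`labeling.assign_labels` turns this into per-recording labels with three
windows (days):

| parameter          | default | meaning |
|--------------------|---------|---------|
| `pre_window_days`  | 7       | recordings within this many days *before* a PTA are **abnormal** |
| `post_start_days`  | 4       | the normal window opens this many days *after* the PTA |
| `post_window_days` | 21      | length of the **normal** window |

Everything else is **unlabeled**. The pre-window default is one weekly visit;
the normal window opens at day 4 (the access needs a few days to settle after
the intervention) and spans three further weekly visits, which makes the
default synthetic corpus reproduce the roughly 3:1 normal:abnormal imbalance
of the cohort the pipeline is designed for (~85 normal, ~26 abnormal, ~560
unlabeled recordings from 45 patients). If a recording falls in both windows
(two PTAs in close succession) it resolves to abnormal — the conservative
choice for a screening tool — and a warning is logged. Labels are derived
from timestamps and event dates only, never from simulator ground truth.

## Features

Recordings are nominally one minute; only the middle 20 seconds are used
(the head and tail carry probe-handling noise). The model input is a
`frames x 64` log-mel spectrogram: Hann-windowed STFT power, an HTK-scale
(`2595·log10(1 + f/700)`) triangular filterbank with unit-peak (unnormalized)
filters, and `10·log10` with a floor at −100 dB. Framing pads the signal
reflectively by half a window and takes `floor(len/hop)` frames, so a 10-s
clip at the default 100 frames/s is exactly 1000×64. Two exact invariants
follow from this construction and are tested: multiplying the waveform by 10
raises every unfloored cell by exactly 20 dB, and shifting the input by one
hop shifts interior frames by one.

The source recordings never state an acquisition sample rate or STFT
parameters, so these are declared defaults (4 kHz sample rate, 64 ms window,
10 ms hop, 20 Hz–Nyquist band), not inferred ones.

## Model

The backbone is CNN14: six convolution blocks, each two (3×3 conv →
batch-norm → ReLU) layers followed by 2×2 max-pooling, with channel widths
64→128→256→512→1024→2048; then global pooling, a 2048-unit fully connected
embedding layer with ReLU, and a 2-unit sigmoid head (normal, abnormal). The
abnormal-class sigmoid score drives the ROC; the predicted label is the
argmax of the two scores with ties resolved to normal. Choices the
architecture table leaves open:

* **Global pooling** is the average of the time–frequency mean and max of
  each channel map. It makes the network length-invariant: 5-s crops
  (~500 frames) and 20-s segments share one set of weights. Any input with
  ≥ 64 frames (the minimum that survives six poolings) is valid.
* **Projection head.** During contrastive pre-training embeddings pass
  through a SimCLR-style 2048→512→128 MLP that is discarded before
  fine-tuning; the head is a flag (`projection_head`, default on) and the
  no-head path is also supported.
* **`width_scale`** divides all channel counts (and the embedding and
  projection dims) without changing the layer structure, for CPU-scale
  experiments; parameter counts in the conv blocks shrink by ≈ `width_scale²`.

The training stack (reverse-mode autodiff over numpy arrays with fused
conv/pool/batch-norm primitives, Adam) lives in `bruitnet.nn`; every
primitive's backward pass is verified against central-difference numerical
gradients in the test suite. All tensors are float32; batch-norm uses biased
batch variance with momentum 0.1 running buffers.

## Contrastive pre-training

For a minibatch of N unlabeled recordings, each recording's middle-20-s
segment is randomly cropped twice (audio domain, uniform starts, default 5-s
crops), giving 2N spectrograms ordered so positions (2k, 2k+1) are the two
crops of recording k. Embeddings are L2-normalized — making the similarity
exactly the cosine — and the InfoNCE loss

    l(i,j) = −log [ exp(sim(z_i,z_j)/τ) / Σ_{k≠i} exp(sim(z_i,z_k)/τ) ]
    L = (1/2N) Σ_k [ l(2k,2k+1) + l(2k+1,2k) ]

is minimized with Adam. Closed forms used as oracles: L = 0 at N = 1 (the
denominator's only term is the numerator) and L = log(2N−1) for 2N identical
embeddings; both hold for the implementation to 1e-9.

Protocol defaults follow the study design: 200 epochs, batch 64, learning
rate 1e-4, a checkpoint every 10 epochs. The temperature τ is never stated
by the protocol; the default is 0.5 (the common SimCLR choice) and it is
exposed in config and logged. Two further choices the protocol leaves open:
the last incomplete minibatch is dropped (the loss assumes exactly N pairs),
and since no rule is given for which of the 20 checkpoints to fine-tune,
checkpoints are scored by InfoNCE loss on a held-out unlabeled split (10%,
fixed crops) and the best is selected. Crops are taken from the middle 20 s,
not the raw recording, consistent with the noise-avoidance rationale for the
middle-segment rule.

Supervised training (all three arms) uses one-hot binary cross-entropy over
the two sigmoids on middle-20-s segments with **no** augmentation, batch 16,
Adam 1e-4; 40 epochs from scratch, 20 epochs from any pre-trained
initialization. These epoch counts are defaults resolved from the
initialization mode; an explicit `epochs` value overrides them (the desk
benchmark needs far fewer). The external-checkpoint arm accepts a backbone
checkpoint in the external `conv_blockN.*`/`fc1.*` naming convention via a
key-mapping table (torch-style `(out, in)` linear weights are transposed on
import); the classification head always starts fresh.

## Evaluation

Stratified 5-fold cross-validation over the labeled recordings (per-fold
class proportions within one recording of the global proportion; recording-
level stratification, with patient-level grouping out of scope). "Evaluating
each held-out recording individually" is implemented as per-recording scoring
of the held-out fold without retraining per recording — retraining would
produce the same predictions at ~100× the cost. Metrics (accuracy, precision,
recall, F1, with abnormal as the positive class) are computed on the pooled
confusion matrix; ratios with zero denominators are NaN with a warning, never
silently 0. AUC is the trapezoidal ROC integral with tie groups swept
together, which equals the Mann–Whitney pair statistic (ties ½) to 1e-9 —
tested against exhaustive pair counting and scikit-learn. Arms are compared
with the exact McNemar test on paired per-recording correctness (the paired
design makes McNemar the natural choice; the original comparison does not
name its test).

### Auditing printed results tables

`reconstruct_confusion` inverts printed 4-decimal metrics back to integer
confusion matrices by exhaustive search over TP and FP given the class
sizes (85 normal / 26 abnormal). A candidate matches a printed value if it
renders to it by round-half-up *or* truncation — published tables
demonstrably use both (one row's printed recall 0.8461 is the truncation of
22/26 = 0.84615…). The audit finds unique matrices for the train-from-scratch,
externally-pre-trained, and first human-evaluator rows, whose implied F1
scores match the printed ones; the contrastive row's printed
accuracy/precision/recall admit *no* integer matrix, and the audit reports
that inconsistency rather than resolving it.

## Synthetic corpus

No AVG bruit dataset is public, so `bruit_synth` generates one with the
statistical structure the pipeline assumes. Each recording is

    pulse + gain · envelope · bandpass-noise + white noise

* **pulse** — a cardiac-cycle harmonic series (default 1.2 Hz, ~72 bpm)
  with exponentially decaying harmonic amplitudes truncated at 160 Hz, peak
  0.5; strictly band-limited below 200 Hz.
* **murmur** — Gaussian noise band-passed to 300–800 Hz (4th-order
  Butterworth, zero-phase), amplitude-modulated by the cardiac envelope
  (turbulent flow is loudest in systole). Its gain is 0.35 for a stenotic
  access and 0.25× that for a patent one, with per-recording log-normal
  intensity jitter (σ = 0.15) so each class is a distribution rather than a
  fixed waveform family.
* **white noise** — sensor noise, σ = 0.01; peak amplitude is normalized to
  ≤ 0.9 full scale and audio is written as 16-bit PCM mono WAV.

Timelines: 45 patients by default, weekly recordings, 15 visits. A seeded
`round(n_patients × stenosis_fraction)` subset (default fraction 0.55)
develops one episode of three stenotic weeks; the PTA falls two days after
the last stenotic recording and the access is patent afterwards, so every
PTA has stenotic recordings before it and patent ones after. The entire
corpus — audio, manifest, events — is a pure function of `SynthConfig`
including its seed.

**What the simulator does and does not emulate.** It reproduces the cohort
shape (label counts, mostly-unlabeled corpus, weekly cadence) and a
spectrally separable stenotic/patent contrast — verified by an oracle outside
the neural pipeline: a single threshold on the Welch murmur-band/pulse-band
energy ratio separates the truth states with ≥ 90% accuracy, so the learning
task is solvable by construction. It does *not* attempt hemodynamic realism:
no flow-dependent murmur spectra, no probe-placement variability, no
arterial/venous acoustic differences, no inter-patient anatomy. Passing
pipeline tests therefore demonstrates that the machinery (labeling, features,
training, evaluation) behaves correctly on a task with the assumed structure
— not that the clinical accuracies are reproduced.

## The desk benchmark

`benchmark.run_desk_benchmark` runs the full pipeline — simulate → label →
pre-train → 5-fold CV of the scratch and contrastive arms — at CPU scale.
Problem sizes, chosen once as the package's desk-scale study conditions: 30
patients × 15 weekly recordings of 24 s (~390 unlabeled + ~60 labeled),
16 mel frames/s (20-s segments are 320×64, 5-s crops 80×64),
`width_scale 16`, pre-training for 2 epochs at batch 32, supervised epochs
6 (scratch) vs 3 (fine-tune) preserving the protocol's 2:1 ratio, learning
rate 1e-3 for all desk arms, three seeds. The claim checked is the
*ordering* — median CV accuracy of the contrastive arm ≥ scratch — not the
clinical magnitudes, which belong to a private dataset and are covered by
the printed-table audit instead.

## Known limitations

* The clinical headline metrics are not reproducible without the private
  recordings; only their internal arithmetic is audited.
* The numpy training stack is single-threaded and CPU-oriented; it is not a
  general deep-learning framework and supports exactly the ops this model
  needs.
* Weak labels inherit the windows' assumptions; recordings between windows
  are discarded as unlabeled rather than modeled (no severity grades).
* The simulator's acoustic model is deliberately minimal (see above);
  results on it bound pipeline correctness, not clinical performance.
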