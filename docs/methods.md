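# Methods

This note documents the models, algorithms, numerical choices, and known
limitations of the package, in the spirit of a model-documentation page.

## Front-end signal conditioning

Skin-contact microphones pick up blood-flow vibration; a high-pass filter
with a 100 Hz cutoff removes it. The filter is realized as a 4th-order
Butterworth applied forward-backward (zero phase): chew clicks are
30–50 ms transients whose timing is scored against 0.05 s collars, so a
causal filter's group delay would bias event timing. Recordings at
44.1 kHz are downsampled to the 16 kHz working rate by a polyphase rational
resampler (160/441). Multi-channel recordings are summed to one channel
(plain addition, then one peak normalization); waveforms are
peak-normalized to max |x| = 1, with silent clips passed through
unchanged. These choices — filter order/type, normalization flavor, and
sum-then-normalize order — were open design points and are recorded here
as the package's own decisions.

## Labels

Strong labels are (start, end, token) intervals stored as Audacity-style
TSV (`start<TAB>end<TAB>symbol`, 6-decimal seconds), the minimal
interoperable timed-label format. Weak labels are the token sequence with
times removed; they are the only training supervision. Reserved symbols:
blank `_` (CTC), chew `#`, swallow `$` (the swallow mark is a package
convention, configurable in the vocabulary file), and a space token that
delimits two concatenated speech utterances inside one synthetic mixture.
CER strips event marks and whitespace and applies Unicode NFKC before
comparison.

## Augmentation

Three seeded, deterministic waveform augmentations: speed perturbation by
the sampling-rate trick (factors {0.9, 1.0, 1.1}; strong-label times scale
by 1/factor), time-domain dropout (one interval, length uniform in
[0, max]), and frequency-domain dropout (1–2 bands up to 1 kHz wide,
zeroed in the rFFT domain). Counts and widths were unspecified design
points; one interval / one band is the minimal recipe in the
spectrogram-masking family. LISA (label-initiated segment augmentation)
produces one window per label onset, up to 10 s, excluding labels cut by
the right edge; it counteracts the dominance of long chew runs.

## Synthetic mixture generation

Fixed-length 10 s examples are built from preprocessed source clips
(≤ 10 s each):

* **≥ 7 s**: padded with white noise split uniformly at random across both
  ends — varying the event position inside the window is what lets the
  model learn timing at arbitrary positions.
* **< 7 s**: concatenated with a partner whose *domain* is chosen to
  reduce the cumulative |speech − eating| duration gap; within that
  domain, the item whose duration is closest to the current gap is taken.
  Additional clips are appended while they fit; white noise fills the gaps
  before, between and after.

Primaries are drawn deficit-first so neither domain's material accumulates
uncompensated. A final balancing pass appends mixtures of reused
trailing-domain clips (same-domain mixtures are a permitted outcome) until
the corpus-level duration ratio is within 5% of target, well inside the
10% contract — without this pass, pools whose padded (≥ 7 s) items are
duration-imbalanced can exceed 10% with no concatenation opportunities to
compensate. White-noise level is 30 dB below the pool-median RMS: audible
padding that never masks events. Balance is measured in seconds of
material, not clip counts, because event density differs wildly between
domains. Source waveforms are embedded bit-exactly; weak labels are the
ordered concatenation of source sequences; eating strong labels are
offset-shifted into mixture time.

## Model

The recognizer is a frame encoder plus a fully connected head emitting
per-frame log-probabilities at a fixed 20 ms stride (the evaluator depends
on it). Full-scale configuration: pretrained self-supervised waveform
encoder with the convolutional feature extractor frozen; head of 4 FC
layers, width 1024, leaky-rectifier activations, batch normalization
(computed over the pooled batch × time axis; evaluation uses running
statistics), dropout 0.15. The head's final projection is interpreted as 4
hidden FC blocks *plus* a separate linear projection to the vocabulary.

The shipped **surrogate encoder** preserves the frame rate and the
freeze semantics at CPU scale: frames of 2× the hop are projected onto
windowed cosine/sine pairs at log-spaced center frequencies, converted to
log magnitude-energy (phase-invariant), passed through a per-channel
affine, stacked with a few frames of context on each side (default ±2),
and projected with one leaky-rectified layer. All of its parameters form the "frontend" group and
are frozen by default; gradients are implemented so the group can be
unfrozen and trained with the encoder optimizer. Untrained posteriors are
near-uniform (row entropy ≥ 0.9·log V).

When the vocabulary grows between training stages (event tokens entering a
speech-trained model), new output columns get small random weights and a
bias of −2: low enough that the stage-1 output distribution is essentially
undisturbed at the start of fine-tuning, high enough that the rare new
tokens are reachable within a short fine-tuning budget. How event tokens
enter the stage-2 output layer was an open design point.

The output projection is initialized at 0.3× the He scale — a deliberate
compromise: a full-scale init violates the near-uniform-start contract,
while a near-zero init puts optimization on an all-blank plateau where the
annealing rule fires spuriously and training can stall. After every
training epoch, batch-norm running statistics are recalibrated to exact
population moments over the training set; with small batches the
momentum-averaged statistics drift far from the population, which makes
evaluation-mode outputs (and minimum-validation-loss checkpoint selection)
erratic.

All network code (layers, batch-norm, dropout, the adaptive-delta and
adaptive-moment optimizers, backpropagation) is implemented in numpy; the
analytic gradient of the full model, including the CTC loss, matches
central finite differences to 1e-5 on small instances (tested).

## CTC loss and decoding

The loss is the exact forward algorithm over the extended target (blanks
interleaved), in log space; unalignable targets return infinity, which the
trainer skips (distinct from numeric overflow). The training gradient with
respect to logits is `softmax − γ`, where γ is the forward-backward
alignment posterior; β is computed by running the forward recursion on the
time-reversed problem.

Best-path decoding applies the collapse rule to the per-frame argmax,
with ties broken toward the lowest token index for determinism; the
emission time of a token is the first frame of its run. Prefix beam search
tracks blank/non-blank endings per collapsed prefix; "history pruning" is
implemented as the standard merge of beams sharing a collapsed prefix
(log-sum-exp of scores) — this interpretation of a toolkit-specific knob
is flagged as such. The log-probability pruning threshold (−12.0) drops
beams trailing the best by more; token pruning (−1.2) expands only tokens
at or above the threshold. With pruning disabled and a saturating beam the
search provably returns the exact maximum-probability labeling (tested
against enumeration). Decoded chew/swallow tokens become single-frame
(20 ms) event intervals; event timing uses best-path decoding by default,
the beam being available for transcripts.

## Training

Two optimizer groups: adaptive-delta (lr 1.0, ρ 0.95, ε 1e−8) for the
head, adaptive-moment (lr 1e−4) for the encoder when unfrozen. Gradients
are clipped per group to a global L2 norm of 5 (configurable) — CTC
gradients spike when an alignment hypothesis collapses, and unclipped
steps occasionally threw small-corpus runs into unrecoverable basins.
After each epoch, if the relative validation-loss improvement is below
0.25% (0.0025), the head lr is multiplied by 0.8 and the encoder lr by
0.9. The returned checkpoint is the epoch with minimum validation loss. Corpora are
split 9:1 into train/validation. Protocols: A1 (speech only), A2 (eating
only), B1 (pooled speech+eating), B2 (synthetic), and the two-stage C1/C2/
C3 (stage 1 speech; stage 2 eating / pooled / synthetic, resuming from the
stage-1 best checkpoint with vocabulary and frame rate preserved —
asserted at resume).

## The toy world and the desk-scale benchmark

The toy world emulates the two corpora with no downloads: "speech" is a
fixed vocabulary of 8 tone bursts at distinct log-spaced carriers
(120 ms tone, 60 ms gap), giving variable-length transcripts a CTC model
must align; "eating" clips contain quasi-periodic broadband chew clicks
(30 ms at 1.5 Hz, ±10% jitter) and 400 ms band-limited (300–700 Hz)
swallow bursts, with exact strong labels. Carriers sit above the 100 Hz
cutoff, so front-end conditioning is harmless. A hand-coded
bandpass-energy detector reaches ≥ 0.99 event F1 on clean toy clips,
establishing that the task is solvable and the labels correct. Test clips
come from disjoint seed groups, emulating held-out subjects.

Toy runs use a 4 kHz sample rate, pools of 24 speech / 24 eating clips
(each tripled by ±10% speed perturbation, which weak labels are invariant
under — the same augmentation family the full-scale pipeline applies to
both corpora), a 2-layer width-96 head over a 64-dimensional surrogate
encoder with ±3 frames of context, batch size 2, 60 stage-1 / 30 stage-2
epochs, and a synthetic corpus capped at 52 mixtures — sizes chosen so the
whole four-protocol comparison runs in a few minutes per seed on one CPU
core. Because a small-corpus CTC run occasionally never escapes the
all-blank plateau (which the no-improvement annealing rule then makes
terminal), the benchmark probes each run at epoch 12: if the validation
loss has not halved, the attempt is aborted and training restarts from a
re-derived initialization seed — up to three deterministic attempts,
keeping the best-validation one.
Two deliberate departures from the full-scale optimization recipe, both
scale-driven:

* the head uses the adaptive-moment optimizer (lr 2e−3) rather than
  adaptive-delta — the adaptive-delta accumulators need tens of thousands
  of steps to warm up, far more than a 24-clip corpus provides in any
  reasonable epoch budget;
* per-epoch anneal factors are 0.97/0.98 rather than 0.8/0.9 — a toy
  epoch sees roughly two orders of magnitude less data than a full-scale
  epoch, and applying the full per-epoch decay at toy scale collapses the
  learning rate long before CTC output peaks sharpen (observable as
  swallow recall going to zero).

The full-scale defaults remain the package defaults in
`OptimGroupConfig`; the toy values live in `ToyRunConfig`. Dropout is 0 at
toy scale for the same sharpening reason.

**What the toy benchmark does and does not show.** It demonstrates the
*mechanisms* — catastrophic forgetting under eating-only fine-tuning, and
its prevention by synthetic mixtures — on a task whose acoustics are
trivially separable. It does not estimate real-world CER or F1: real
speech has phonetic variability, real chews vary with food texture, and
real corpora are three orders of magnitude larger. Absolute toy metrics
are not comparable to full-scale numbers.

## Numerical choices and degenerate inputs

* Log-space throughout CTC; −inf is the additive identity and NaNs from
  (−inf) − (−inf) are mapped back to −inf before exponentiation.
* Argmax and partner-selection ties are broken deterministically (lowest
  index / first minimum).
* Empty weak sequences are valid (pure-noise mixtures); empty CER
  references raise.
* Silent clips skip peak normalization; mono channel summation is the
  identity up to normalization.
* All randomness flows from explicit integer seeds; derived seeds use
  crc32, never Python's salted `hash`.

## Known limitations

* Overlapping (simultaneous) speech-plus-chewing is not modeled — the
  generator produces sequential mixtures only.
* Greedy chronological one-to-one event matching is the scoring contract;
  an optimal bipartite matcher can differ on pathological prediction
  patterns (the count identities tp+fn and tp+fp always hold).
* The pretrained-encoder adapter is an interface seam; no pretrained
  weights ship with the package.
* Japanese text normalization beyond NFKC (punctuation policy) is
  unspecified upstream and left to the caller.
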