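# Methods notes

## Scope and data model

The toolkit studies frame-level detection of four adventitious respiratory
sound classes — wheeze, rhonchus, fine crackle, coarse crackle — in chest
auscultation audio. All time-indexed structures share one grid: frame `i`
covers the half-open interval `[10·i, 10·(i+1)) ms`, 0-based; a signal of
`n` samples at 8 kHz yields exactly `⌊n/80⌋` frames. Ground truth,
spectrogram, probability raster, and boolean activations all have this
frame count by construction, so frame-level scoring never needs
resampling or alignment heuristics.

Class definitions enforced throughout (simulator validation, event
decoding, corpus statistics):

| class | character | fundamental | minimum duration |
| --- | --- | --- | --- |
| wheeze | continuous, tonal | 100 Hz – 1 kHz | 80 ms |
| rhonchus | continuous, periodic, snoring-like | < 300 Hz | 100 ms |
| fine crackle | explosive transient | broadband, emphasis ≳ 500 Hz | ~5 ms nominal |
| coarse crackle | explosive transient | broadband, emphasis ≲ 700 Hz | ~15 ms nominal |

## Simulator

`generate_breath_track` synthesizes normal respiratory sound as Gaussian
noise shaped in the frequency domain: flat inside the 50–2500 Hz band with
10 Hz raised-cosine tapers lying just inside the band and zero outside, so
out-of-band power is far more than 30 dB below in-band power by
periodogram. The amplitude envelope alternates inspiration (default 40% of
a 3 s cycle, 0 dB) and expiration (60%, −12 dB), smoothed with ~80 ms
ramps; only the qualitative relations (expiration longer and quieter) are
established facts, the concrete values are this package's choices.

Events, all unit-RMS and amplitude-windowed against clicks:

* **wheeze** — harmonic tone (3 partials, 1 : 0.30 : 0.12) with 0.2%
  vibrato at 3 Hz; the depth is deliberately below one FFT bin so an
  independent FFT-argmax oracle recovers the fundamental to ±1 bin.
* **rhonchus** — harmonically rich buzz (partial amplitudes `h^-1/2` up to
  2 kHz) with 10–20 Hz amplitude modulation, the "snoring" quality.
* **crackles** — exponentially damped sinusoids, time constant duration/4,
  center frequency 500–1500 Hz (fine, 5 ms) or 200–700 Hz (coarse, 15 ms);
  ≥ 90% of energy falls within 10 ms of onset.

`compose_recording` mixes breath + events at a default event-to-breath SNR
of 10 dB (configurable; the literature gives no levels), plus optional
speech-band (100–3000 Hz) amplitude-modulated interference bursts
emulating crying/talking/stethoscope handling. Frame truth is derived
exactly from event intervals at microsecond resolution.

`generate_corpus` draws recording-level labels independently per class at
the prevalences observed in a 522-recording pediatric clinical set
(wheeze 124/522, rhonchus 113/522, fine crackle 112/522, coarse crackle
66/522) — multilabel, so a recording may carry several pathologies or
none. Positive recordings receive 1–3 tonal events or 3–12 crackles
(crackles occur in bursts across breaths). Metadata (age 1–18 years, sex,
auscultation point 1–12) is sampled uniformly and carried through the
manifest. Every output is a pure function of configuration and seed.

**What the simulator does *not* emulate**: airway physiology,
age-dependent acoustics, stethoscope transfer functions, heart sounds,
breathing-phase coupling of events, and the acoustic ambiguity between
classes that makes real rhonchi/coarse crackles hard for human readers.
Passing label-recovery tests therefore shows that the detector pipeline
learns and localizes the *defined* signatures; it is not evidence of
clinical-grade performance on real patients.

## Frontend

32 ms (256-sample) Hann window, 10 ms (80-sample) hop, reflection padding
of (256−80)/2 samples so frame `i` is centered on raster frame `i`; 64
triangular mel bands over 30–4000 Hz (linear axis available via
`n_mels=None`); power floored at 1e-10 before `10·log10`. The window
resolves 31.25 Hz, enough to separate low-fundamental rhonchi from breath
noise; 4 kHz covers the stated content of chest-wall recordings.
Per-frequency-bin standardization uses training-corpus statistics only;
zero-variance bins get a unit divisor with a warning.

## Detector

Stacked conv blocks (3×3 kernels, ReLU, 2× max-pool over frequency only)
→ one bidirectional GRU (32 units per direction) → per-frame dense sigmoid
head. `time_pool` must be 1; configurations that would downsample time are
rejected, keeping the raster contract exact. Dropout 0.25 after the conv
stack and the GRU.

Implementation is pure NumPy (im2col convolutions, explicit BPTT through
the GRU, Adam) in float32; gradients are verified against central finite
differences in float64 in the test suite. Training samples fixed-length
256-frame chunks from each recording per epoch; binary cross-entropy is
averaged over frames and classes with per-class positive weights
`clip(√(n₋/n₊), 1, 8)`. The square root alone leaves weights of 17–30 for
crackle classes (positive-frame fraction ~0.1–0.3%), which floods those
classes with false alarms at threshold 0.5; the cap at 8 was selected by
validation-split macro F1 on synthetic data and is the package default.
When validation data is supplied, the epoch with the lowest validation
loss provides the final weights. NaN loss aborts with a diagnostic; an
absent class merely warns. Inference processes each recording
independently (batch composition can never change a raster); a batched
internal path is used for speed during training-time evaluation and
matches the per-recording path to float32 round-off.

Checkpoints are single `.npz` files embedding weights, model and frontend
configuration, and class order, with a SHA-256 config hash verified on
load. A fifth "noise" output class (trained from interference annotations)
is supported via `n_classes=5` but off by default.

## Post-processing

Thresholding uses the ≥ convention (a probability exactly at the threshold
counts as active); thresholds live strictly inside (0, 1) and may be set
per class. Runs of active frames separated by at most 30 ms are merged for
the tonal classes (brief amplitude dips should not split a continuous
sound); crackles are individual transients and never merge. Minimum
durations reuse the definitional bounds; crackles keep a one-frame minimum
because 5–15 ms is below the grid. The merge-then-filter decoder is
idempotent, monotone in the thresholds, and reproduces recording-level
ground truth exactly when fed perfect rasters.

## Reference-standard adjudication

Each recording carries one description and two independent verifications.
Routing is deterministic: double-positive verification accepts the
description outright; *any* other pair (split or double-negative) goes to
an acoustician; "clear" accepts the description, "disputable" makes the
consilium labels final and terminal. Two points are deliberate package
policy where practice varies: double negatives are arbitrated like splits
(the conservative reading — only double positives qualify automatically),
and an acoustician "clear" verdict resolves to the original description
(minimal intervention). Records with fields inconsistent with their path
(e.g. consilium labels on a double-positive record) raise rather than
being silently ignored.

## Metrics and statistics

Confusion counts are recording-level per class; metrics are computed as
exact `Fraction`s and only rounded (half-up, one decimal) for display. An
undefined metric (zero denominator) is reported as undefined, never as 0;
F1 at precision = recall = 0 is defined as 0. Summary ("Mean") rows
average the *printed* one-decimal per-class values, matching how such rows
are derived in published tables. Rater comparison uses the chi-square test
(α = 0.05) on the 2×2 table of rater × (correct vs incorrect w.r.t. the
reference), without continuity correction by default (correction
available and always reported); degenerate tables return statistic 0 and
p = 1, and expected counts below 1 attach a warning. Which 2×2
construction a given published analysis used is often unstated; the
correct/incorrect construction is this package's documented choice.
Multiple readers can be pooled by per-class majority vote (ties positive)
as an explicitly-marked convenience.

## Benchmark arithmetic

`benchmark.py` carries the printed percentages and positive counts of a
published 522-recording pediatricians-vs-detector comparison as input
data. Six of its eight F1 cells are exactly the harmonic mean of their
printed recall/precision pair; the other two differ by one unit in the
last printed digit (an artifact of the table's own rounding), and the
package reproduces exactly the six self-consistent ones. Integer confusion
tables are reconstructed per rater and class by exhaustive search over
(TP, FP) with all three printed metrics required to round back exactly;
the solution is unique in all eight cases, which makes the derived
chi-square tests well defined.

## Label-recovery experiment

The standard desk-scale configuration (`experiment.DESK_SCALE`): 200
recordings of 15 s (about 50 minutes of audio), split 140 train / 20
validation / 40 held-out test; detector with (8, 16, 32) conv channels,
batch 16, 3 chunks per recording per epoch, 20 epochs — sizes chosen so a
complete run with both controls finishes in minutes on a single CPU while
leaving a comfortable margin over the 0.60 macro-F1 bar. Scoring is
frame-level per-class F1 over all concatenated held-out frames at
threshold 0.5, macro-averaged over the four classes. Controls: the
freshly initialized (untrained) network, and a network trained after
permuting the frame-truth matrices across training recordings, which
preserves label statistics while destroying the audio–label association.
A measured run (seed 1): trained 0.77 macro F1 (tonal classes ≈ 0.97–0.99,
crackles ≈ 0.51–0.60), untrained 0.01, label-shuffled 0.02; a second seed
gave 0.69. Crackle F1 is
intrinsically lower at frame level: a 5 ms transient occupies 1–2 frames,
so a single frame of temporal disagreement halves the score.

## Known limitations

* The detector is CPU-scale; no claim is made that its architecture or
  capacity matches any production clinical system.
* The simulator's class signatures are cleanly separable by design;
  real-world inter-class ambiguity (rhonchus vs coarse crackle, silent
  wheezes under louder sounds) is not modeled.
* Breathing-phase attribution (inspiratory vs expiratory events) is out of
  scope; events are detected, not phase-labeled.
* Frame-level crackle scores are sensitive to single-frame localization;
  event-level tolerance-based scoring would be kinder but is not the
  evaluation used here.
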