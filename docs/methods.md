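# Methods

## Problem and scope

`mozznet` implements, end to end and at desk scale, an acoustic
mosquito-detection and repellent-control pipeline of the kind deployed on
TinyML hardware: a microphone stream is classified continuously for
mosquito wingbeat sound, and a chemical vaporizer is powered only when a
mosquito is confidently present, cutting both energy use and insecticide
exposure.  The package reproduces the software substance of such a
system — feature extraction, the tiny CNN, quantized score thresholds,
the false-positive-suppressing power controller, and the energy model —
and exercises it on synthetic audio, since the original field corpora
(crowd-sourced wingbeat recordings, ambient household noise) are not
redistributable here.

## Signal chain

**Framing.** Audio is mono, 16 kHz, amplitudes in [-1, 1].  The stream
is cut into 30 ms slices with a 20 ms stride; every 330 ms segment
yields one classification decision, computed from the segment's first
four slices only (three decisions per second, matching the duty cycle a
small MCU can sustain).

**Features.** Each 480-sample slice is analysed with two overlapping
256-point Hann-windowed FFTs (block starts at samples 0 and 224, so the
slice is fully covered); their power spectra are averaged and passed
through a 40-filter triangular mel bank spanning 125–7500 Hz (HTK mel
scale, unit-peak filters).  The range covers both wingbeat bands
(females 400–500 Hz, males 700–800 Hz, plus harmonics) and the
200–4000 Hz passband of an inexpensive electret microphone, with margin;
it is a configuration knob.  Band energies are compressed as
`log(E + 1e-6)` and affinely quantized to 0..255 between fixed log
bounds (`log 1e-6` ≈ −13.8 to `log 2e4` ≈ 9.9, ≈0.1 nats ≈ 0.4 dB per
level).  The fixed bounds make rows comparable across time and make an
all-zero slice map exactly to the 0 floor.

One second of stream is therefore a 49×40 image (49 slices × 40 mel
bins).  A single 30 ms slice cannot fill 49 time frames; classification
runs on the *rolling* one-second image ending at the newest slice, kept
as a ring buffer that is warm-started with floor rows so the pipeline
can classify from the very first slice.  Streaming and batch
computation of the image agree exactly, which is tested.

## Classifier

Three valid 5×4 convolutions with 8 channels and ReLU, 2×2 max-pooling
after the first two, a 64-unit ReLU layer, and a 3-way output (Silence,
Noise, Mosquito).  Two conventions reproduce the deployed accounting of
18,363 parameters exactly:

* the first convolution's 45×37 output is cropped by one trailing
  column to 45×36 (equivalently, the last mel bin never reaches C1's
  output); every downstream tensor size and count then matches;
* max pooling uses ceil semantics, padding odd edges with −inf
  (45→23, 19→10, 15→8); floor semantics cannot produce these sizes.

The closed-form accounting (conv: `kh·kw·c_in·c_out` weights + `c_out`
biases; dense: `n_in·n_out + n_out`) gives 18,272 weights + 91 biases.

**Quantized scores.** Logits pass through a softmax, are scaled by 256
and rounded by largest remainder, so the three integer class scores are
non-negative and sum to exactly 256 — the deployed 8-bit score
convention.  Argmax ties resolve toward the earlier class, i.e. away
from Mosquito, the conservative direction for false positives.

**Training.** Plain SGD on softmax cross-entropy with dropout 0.5 on
the three convolution outputs (training only; inference is
deterministic and repeatable bit for bit).  The presentation budget is
24,000 randomly drawn samples.  Within that fixed budget the package
defaults to mini-batches of 32 for 750 steps: in a sweep over seeds,
smaller batches with more steps converged markedly more reliably than
100×240, which intermittently left the Noise/Silence boundary unlearned.
The learning rate (0.02) and fan-in-scaled truncated-normal
initialization (std `sqrt(2/fan_in)`, resampled beyond 2σ) were chosen
the same way; a fixed tiny-std initialization leaves a three-layer ReLU
stack with near-zero signal and does not train within this budget.
Because a single short plain-SGD run still occasionally lands in a poor
solution, the end-to-end workflows train three restart candidates
(derived seeds) and keep the one with the best validation accuracy —
ordinary model selection on the held-out split, emulating the manual
development loop; `train` itself stays a single deterministic run.
Input images are normalized by the fixed affine map `(q − 60)/35`,
which roughly centers typical log-mel images.  All randomness
(initialization, batch sampling, dropout) derives from one config seed.

## Decision rule and power control

A segment is positive iff Mosquito wins the argmax of the four-slice
mean score *and* that mean strictly exceeds θ = 210 (of 256).  A mean of
exactly 210 is rejected.  θ is deliberately high: with per-segment false
positive rates of a fraction of a percent, a lone threshold would still
fire every few minutes, and each firing costs an hour of vaporization.

The controller therefore requires a pattern before actuating: the first
positive anchors a 10 s watch window (`T_mos`, set one slice before the
decision instant); positives within the next `X_fp = 2` segment slots
coalesce with the anchor; the first positive after the coalescing
interval but inside the window triggers.  This realises "≥ 3 consecutive
positives, or ≥ 2 non-consecutive positives, within 10 s": a run of
three triggers on its third segment, an isolated positive or a lone pair
of consecutive positives never triggers, and two positives separated by
a gap trigger on the second.  If nothing triggers within the window the
watch state expires at the next evaluated segment (the printed control
loop leaves this reset implicit; without it an isolated positive would
poison all later detections).  On triggering, the vaporizer runs for a
fixed `L_power = 1 h` — enough for a pyrethroid plume to clear a room —
positives during vaporization never re-trigger, and by default sensing
pauses entirely until power-off (`sense_during_vape = False`, the mode
the energy accounting assumes; the always-sensing variant is also
implemented).  The power-off check runs at the end of each control
iteration, as in the deployed loop, so the first decision slot after the
hour elapses is still skipped.

A flat, line-by-line transcription of the control loop lives in the test
suite and is held equivalent to the production state machine on 10,000
random decision streams.

**Field-week replay.** The package ships the run-length profiles of a
week of overnight monitoring (no mosquito sound played): 43 maximal runs
of positive segments over seven 8 h nights.  Replaying each night with
runs separated widely — wider than both the watch window and the
vaporization hour, so each run is judged independently — except the
night-6 pair (a run of 4 followed by a run of 3 inside one window, which
the ON-state lockout collapses into a single actuation) yields exactly 8
power-on decisions, the published outcome.  The wide separation matters:
with runs merely a window apart, the lockout would swallow later
qualifying runs and the count would be unreachable.

## Energy model

Sensing + classification draws 17.69 mW; vaporizing draws 4020 mW
(804 mA × 5 V).  The sensing figure is kept at the printed 17.69 rather
than the 5.4 mA × 3.3 V = 17.82 product because the published table's
arithmetic reproduces only from 17.69.  Session energy over 8 h with
`k` vaporizing hours is `4020·k + 17.69·(8−k)` mWh; the reduction factor
versus an always-on device is `4020·8 /` that, i.e. 227 at `k = 0` and
within 5% of `8/k` for `k ≥ 1`.  Mean time between false positives is
`L_seg / FPR` (0.33 s / rate).

## Synthetic audio

The generator defines the study conditions and is first-class, tested
code.

* **Wingbeats** are harmonic series (4 partials, 6 dB/harmonic rolloff)
  on a fundamental drawn in the sex band, with 5–10 Hz flight amplitude
  modulation (depth 0.3) and a slow ±5 Hz fundamental drift.  Over 90%
  of their energy falls inside the 200–4000 Hz microphone band.
* **Noises** are stylized caricatures, not recordings: white/pink
  background "silence"; a 1 Hz tick train (clock); syllabic-modulated
  speech-band noise (conversation); 0.4 Hz low-band bursts (snoring);
  high-band hiss with crackle (sizzling pan); 60 Hz hum + harmonics
  (refrigerator); shaped broadband with impulses (water, rain); hum +
  swishing broadband (dishwasher).
* **Levels.**  Nominal dB values map linearly to digital RMS with
  30 dB ≡ RMS 1.5e-3, so only relative levels (SNR) carry meaning; each
  noise kind draws its level from its measured household range (e.g.
  clock 30–40 dB, sizzling pan 55–75 dB).
* **Corpus composition** matches the development corpus: 1000 mosquito /
  350 living-noise / 350 silence one-second clips split 1370/165/165
  (806/282/282, 97/34/34, 97/34/34 per class).  Training wingbeat levels
  span 15–45 dB with a 15–25 dB background floor mixed in, emulating
  recordings from loud-and-close to faint-and-far.
* **Distance.**  The received signal at distance `d` is the source
  scaled by the free-field `9/d` law (source calibrated 30–33 dB at
  9 cm) plus a 20 dB quiet-bedroom noise floor.  Room acoustics are
  ignored; only the monotone SNR-distance relationship is claimed.

What passing tests therefore show: the pipeline detects harmonic tones
of the right band at realistic SNRs and rejects the stylized noise
suite.  What they do not show: performance on real room audio — real
wingbeats are nonstationary and real noise is richer, so the published
field FPR/FNR tables are surrogate targets only, reproduced in shape
(FNR monotone in distance, suppression and window-length orderings),
not in their measured values.  With the defaults the synthetic pipeline
detects every 10 s clip at ≤ 50 cm and rejects ≥ 99.8% of noise
segments, consistent with the published near-field behaviour (FNR 0% at
biting distances; in the synthetic sweep the FNR transition happens
between 70 and 100 cm, versus the reported ~70% FNR at 100 cm).

## Numerical and degenerate-input choices

* Trailing partial slices and segments are discarded; clips shorter
  than one slice (or segment) raise.
* WAV I/O quantizes with `round(x·32768)` clipped to int16, giving
  round-trip error ≤ 2⁻¹⁵; out-of-range samples are clipped with a
  warning on write; other rates/channels are polyphase-resampled and
  channel-averaged on read.
* Controller time comparisons use a 1e-9 epsilon; with the 0.33 s
  segment grid and the one-slice anchor offset no comparison lands on a
  boundary.
* Score quantization breaks remainder ties by stable order (earlier
  class first); symmetric logits give (86, 85, 85).
* `evaluate`'s per-clip confusion matrix scores each clip's whole-clip
  image (the clip-level aggregation of the development bookkeeping is
  not specified anywhere authoritative; this choice avoids contaminating
  1 s clips with the ring buffer's warm-up rows).

## Known limitations

* The CNN is numpy-only and CPU-bound; training the default corpus
  takes on the order of a minute.  There is no GPU path and none is
  needed at this size.
* The flat-file model format (`.npz` with a JSON config header) and the
  byte-array export document content layout only; no on-device tooling
  is provided.
* Absolute SPL calibration is impossible without the original hardware;
  all dB values are nominal anchors.
* Synthetic noise caricatures are easier to reject than real household
  audio; absolute FPR values here understate real-world rates.
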