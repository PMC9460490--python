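# mozznet

Acoustic mosquito detection and repellent power control, at desk scale.

Electric liquid mosquito repellents vaporize a pyrethroid continuously,
whether or not a mosquito is in the room — wasting electricity (the
vaporizer draws ~4 W against ~18 mW for an idle sensing circuit) and
exposing sleepers to insecticide all night.  A smarter device listens:
mosquito wingbeats are narrowband tones (females ~400–500 Hz, males
~700–800 Hz, plus harmonics) that a very small CNN can pick out of a
spectrogram, so the vaporizer need only run for an hour after a
confident detection.

`mozznet` implements that whole pipeline as a reproducible Python
library with a thin CLI, exercised end to end on synthetically generated
audio (the original wingbeat/noise corpora are not required):

* **audio** — WAV I/O; 30 ms slices at a 20 ms stride over a 16 kHz
  mono stream (`mozznet.audio_io`);
* **features** — 40-bin log-mel rows from paired 256-point FFTs, rolled
  into a 49×40 uint8 image, streaming ≡ batch (`mozznet.features`);
* **classifier** — a 3-conv + FC network with exactly 18,363
  parameters, hand-rolled forward/backward on numpy, plain-SGD training
  with dropout 0.5, and quantized class scores that always sum to 256
  (`mozznet.cnn`);
* **detector** — one decision per 330 ms segment: the mean of the first
  four slice score vectors must put Mosquito on top *and* strictly above
  θ = 210/256 (`mozznet.detector`);
* **controller** — false-positive suppression: ≥3 consecutive or ≥2
  non-consecutive positive segments within a 10 s window trigger one
  hour of vaporization; isolated positives and lone pairs are ignored
  (`mozznet.controller`);
* **metrics / energy** — confusion matrices, weighted accuracy, FPR/FNR,
  mean time to false positive, and the 8 h session energy model
  `4020·k + 17.69·(8−k)` mWh (`mozznet.metrics`);
* **synthesis** — seeded wingbeat, household-noise and background
  generators, the corpus composition (1000/350/350 one-second clips),
  and a 1/r distance model calibrated at 30–33 dB @ 9 cm
  (`mozznet.synth`, `mozznet.pipeline`).

See `docs/methods.md` for the model, its assumptions, and every
numerical convention; `examples/` holds one short narrative script per
capability.

## Worked example

`python examples/04_detection_and_power_control.py` trains the
classifier on the synthetic corpus and runs the full chain (output from
that script):

```
held-out validation accuracy: 1.000

10 s wingbeat at 40 cm: 30 segments, 24 positive
power-on events: 1 (first at t=2.64 s, consecutive-run)

field-week replay (no mosquito sound played):
  night1:  2 positive runs -> 1 vaporizer decisions
  night2:  6 positive runs -> 0 vaporizer decisions
  night3: 10 positive runs -> 2 vaporizer decisions
  night4:  5 positive runs -> 1 vaporizer decisions
  night5:  5 positive runs -> 0 vaporizer decisions
  night6:  5 positive runs -> 2 vaporizer decisions
  night7: 10 positive runs -> 2 vaporizer decisions
  total: 43 runs -> 8 decisions (isolated positives and lone pairs are suppressed)
```

A faint wingbeat 40 cm away yields positive segment decisions almost
immediately; the controller fires once (three consecutive positives) and
would hold the vaporizer on for an hour.  The replay shows the
suppression arithmetic on a week of real-world-style positives: of 43
bursts only 8 patterns qualify, the rest — single segments and lone
330/660 ms pairs too short to be a real mosquito pass — are ignored.

The CLI wraps the same workflows:

```sh
mozznet generate --seed 0 --out fixtures/        # WAV corpus + manifest
mozznet train --seed 0 --model-out model.npz     # prints the 18,363-parameter accounting
mozznet detect --model model.npz --out run/ fixtures/test/mosquito/*.wav
mozznet report --out report/ run/session.json    # energy table + summaries
```

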