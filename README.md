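# phasestim

Closed-loop, EEG-phase-gated vibrotactile stimulation as a testable Python
library: streaming alpha-phase forecasting, phase-interval stimulus
scheduling, and the full offline evaluation stack (phase-locking-value
validation, ERSP/ERD time-frequency analysis, FBCSP+LDA classification) —
exercised end to end on synthetic EEG sessions.

## What it does

- **`phasestim.synth`** — reproducible synthetic EEG sessions: 27-channel
  10/20 montage (C3/C4 included) at 1000 Hz, back-to-back 11 s trials with a
  5–9 s task window, 1/f background noise mixed through a fixed full-rank
  random matrix, and narrowband ~10 Hz alpha (random-walk phase jitter, slow
  envelope drift) over sensorimotor channels. Motor-imagery trials attenuate
  the contralateral (C4-peaked) alpha envelope by `1 - erd_depth`.
- **`phasestim.tracker`** — streaming phase estimation: every 40 ms the latest
  300 ms of the target channel are causally bandpassed (10th-order elliptic
  IIR, 8–12 Hz), the dominant FFT component located (zero-padding + parabolic
  peak interpolation), its phase referenced to the window end, and a pure-sine
  forecast extrapolated 40 ms ahead. Phase convention: 0 at the ascending
  zero crossing, wrapped to [-pi, pi).
- **`phasestim.scheduler`** — gates 20 ms / 200 Hz pulses on phase intervals
  (rising `[-pi/6, pi/3]` or falling `[5pi/6, 4pi/3]`) with a ≥100 ms
  refractory and the tic-tic-toc amplitude pattern (every third pulse 1.5x);
  also synthesizes the pulse burst and the continuous 23 Hz-modulated 200 Hz
  open-loop waveform.
- **`phasestim.evaluate`** — offline ground truth (zero-phase bandpass +
  Hilbert analytic phase), PLV, realized stimulus phases with rose-histogram
  counts, and mis-stimulated trial rejection.
- **`phasestim.spectral`** — trial-averaged ERSP (200 ms Hann STFT, dB,
  [3, 4] s baseline subtraction), alpha/beta band-ERD summaries, sliding
  band-energy curves (1 s window every 200 ms, 8–30 Hz), and common average
  referencing.
- **`phasestim.classify`** — FBCSP (six 4 Hz sub-bands over 8–32 Hz, CSP by
  generalized eigendecomposition, log normalized variances of 3 filter pairs
  per band) + Fisher LDA, evaluated by 10x10-fold stratified CV with
  everything refitted per training fold.
- **`phasestim.io_cli`** — EDF and `.npz` recording containers, delimited
  event/estimate/report tables (each stamped with the config hash and seed),
  YAML run configuration, pipeline orchestration, and the CLI.

## CLI

```sh
phasestim simulate --seed 1 --n-trials 40 --out session.npz
phasestim track session.npz --channel C4 --out estimates.tsv
phasestim schedule estimates.tsv --interval falling --out stim.tsv
phasestim evaluate session.npz estimates.tsv --out plv.json
phasestim ersp session.npz --channel C4 --out ersp.tsv
phasestim classify session.npz --out cv.json
phasestim run --seed 1 --condition FPS --outdir results/run1   # full loop
```

`phasestim run` executes simulate → track → schedule → evaluate → ERSP →
classify and writes every report (PLV, rose histogram, trial flags, ERSP
maps, band-energy curves, CV accuracies) into the output directory. The four
conditions are PMI (no stimulation), CVS (continuous open-loop), and RPS/FPS
(closed-loop rising/falling phase gating).

## Notes

- Synthetic-data defaults (alpha SNR, phase jitter, envelope drift) are
  stated generator parameters, documented in `SynthConfig`; they are not
  estimates of any particular dataset.
- All outputs are deterministic given the master seed; identical config +
  seed reproduce byte-identical reports.
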