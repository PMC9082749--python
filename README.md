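# midecode

Motor-imagery EEG decoding built from scratch in numpy/scipy:

* **synthetic** — a paradigm-faithful simulator of 4-class motor-imagery
  sessions (6 runs x 48 balanced trials, 2-s epochs on C3/Cz/C4 at 250 Hz)
  with class-dependent µ/β ERD and controllable session/subject covariate
  shift, so the whole pipeline is testable offline.
* **preprocess** — zero-phase 50 Hz notch and 7–30 Hz Butterworth band-pass,
  canonical channel selection, bit-exact epoching.
* **spectrogram** — per-trial 90x90 time–frequency–electrode power images
  (Hann STFT, window 50 / hop 5, zero-padded to 0.5 Hz bins; 16 µ + 14 β
  columns per electrode, 91 frames cropped to 90).
* **networks** — a Bi-LSTM branch over the raw 500x3 sequence in parallel
  with a CNN branch over the 90x90 image (C1 25@7x7 → P1 2x3 → C2 50@5x5 →
  P2 2x4 → 5700 → 60), fused by a two-stage stacked sparse autoencoder,
  with 4-class task and domain heads.  Implemented on a small reverse-mode
  autodiff engine (`midecode.autodiff`) with hand-written adjoints for the
  LSTM recurrence, valid convolution, max-pooling and batch-norm, all
  verified against finite differences and naive oracles.
* **adversarial** — the domain-adversarial min–max objective realized by a
  gradient-reversal layer between the fusion encoder and the domain head,
  plus greedy SSAE pretraining and a pretraining-based calibration protocol.
* **evaluation** — stratified 4-fold CV, semi/full session-transfer splits,
  leave-one-subject-out plans, and confusion-matrix reports with per-class
  sensitivity and precision.

## CLI

```bash
midecode simulate   --subjects 1 --sessions 2 --seed 1 --out raw.h5
midecode preprocess --in raw.h5 --offset 0.5 --out pre.h5
midecode featurize  --in pre.h5 --window 50 --hop 5 --out feat.h5
midecode train      --data feat.h5 --lambda 1.0 --epochs 100 --seed 0 --out model.h5
midecode evaluate   --data feat.h5 --ckpt model.h5 --out report.json
midecode report     --report report.json --plot confusion.png
```

Sessions are stored in an HDF5 container (`signals`, `labels`, `run`,
`domain_id`, optional `images`) with a CSV event manifest; checkpoints are a
single HDF5 file with a JSON manifest attribute.

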