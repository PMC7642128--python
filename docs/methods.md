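# Methods

This note records the models, parameter choices and numerical conventions
behind `mieeg`, and what the synthetic benchmark does and does not
establish.

## Synthetic sessions

A session is a labelled stack of `[trial, channel, sample]` epochs in
microvolts, cut on a window of [−2.0, +3.5) s around the imagery cue
(550 samples at 100 Hz). Two presets pin the acquisition geometry:
`comp118` (118 electrodes, 100 Hz, 140 trials per class) and `lab32`
(32 electrodes, 250 Hz). Montage labels and 3-D positions come from the
standard 10-05 layout (via MNE), with a curated 32-label core (C3 and C4
first) extended in montage order for larger caps.

Each trial is the sum of:

* **Rhythms.** Two scalp sources at C3 and C4, each a mu sinusoid
  (default 10 Hz, 10 µV peak) plus a beta sinusoid (20 Hz, 5 µV peak)
  with per-trial random phases. Electrode gains fall off with scalp
  distance as `exp(−d²/2λ²)`, λ = 4 cm.
* **The effect.** After the cue the *contralateral* source's power is
  multiplied by `1 − erd_depth` and the ipsilateral source's by
  `1 + ers_gain` (defaults 0.4 and 0.1), joined by a 250 ms raised-cosine
  ramp so the transition adds no spectral splatter. Amplitudes scale as
  the square root of the power factor, making the expected ERD/ERS
  percentage exactly `−100·erd_depth` — parameter recovery has a closed
  form. Only C3 and C4 carry the modulated sources; all other electrodes
  receive *unmodulated* copies of the same rhythms (same phases, scaled by
  distance), so the rest of the montage is realistic but carries no class
  information.
* **Noise.** Independent per-channel 1/f^α noise (α = 1), spectrally flat
  below 0.5 Hz, scaled so that the rhythm-to-background power ratio at
  C3/C4 equals `snr_db` (default 10 dB; ∞ disables noise).
* **Artifacts (optional).** Poisson blink transients (100 µV Gaussian
  bumps, σ = 100 ms ⇒ ≤ 4 Hz bandwidth) sourced at Fpz and spatially
  weighted like the rhythms, and a common-mode mains sinusoid (2 µV) at
  `line_freq`; a line frequency at or above Nyquist is rejected.

Determinism: one `numpy` Generator seeded from the config drives the whole
session, so identical config + seed reproduces the array bit for bit.

**What the generator does not emulate:** volume-conducted broadband
activity shared across electrodes, non-stationary rhythm amplitude
(waxing/waning spindles), EMG, electrode drift/pops, subject variability,
or any temporal structure in the class signal beyond the post-cue power
step. Consequences: classification on this benchmark is *easier* than on
real EEG (the CNN reaches near-ceiling accuracy), and the LSTM baseline is
expected to sit at chance here even though it demonstrably learns temporal
structure when it exists (verified by a drift-classification test).
Passing tests establish the pipeline's internal correctness and the
qualitative CNN-over-LSTM ordering, not real-data accuracy levels.

## Wavelet band reconstruction

The DWT is a 3-level Mallat pyramid with the standard 12-tap db6 filter
pair; the filter table is hardcoded and checked for orthogonality
(Σh = √2, double-shift orthonormality) at import, and the transform is
executed by PyWavelets behind this module's surface. At 100 Hz the bands
are exactly dyadic: D1 [25, 50), D2 [12.5, 25), D3 [6.25, 12.5),
A3 [0, 6.25) Hz. A printed band edge of "6.5 Hz" in common descriptions
of this scheme is treated as a rounding of 6.25 Hz — a dyadic filter bank
cannot realize 6.5 Hz.

Boundary handling: `symmetric` (default; half-point symmetric extension,
minimal edge artifacts on 5.5 s epochs) or `periodic` (periodized
coefficients, ceil(L/2) per level, exact coefficient-energy conservation).
Perfect reconstruction holds in both modes to better than 1e-8 relative.
Tests verify the analysis cascade against an independent brute-force
circular-convolution filter bank (phase offset = half the filter length).

Denoising keeps D2+D3. Because db6 has a wide transition band, selectivity
is not brick-wall: a 10 Hz tone retains 99.4% of its energy, a 16 Hz tone
97.5%, but a 20 Hz tone only 85.9% (= |H(0.2)|² of the level-1 lowpass),
while a 2 Hz drift retains 0.01%. This is the filter's physics, reported
as-is. Inputs not at 100 Hz are polyphase-resampled (anti-aliased) to
100 Hz first, because the 3-level band semantics are defined on that grid;
the cue index is rescaled and rounded.

## Periodogram and band power

`P[k] = |DFT(x)[k]|²/(N·fs)`, one-sided with interior bins doubled
(boxcar window, no detrending), so Parseval's identity is exact; an
optional flag averages non-overlapping segments (Welch) for variance
reduction. Band power integrates `P·Δf` over half-open `[f_lo, f_hi)`
bins; an upper edge at Nyquist includes the Nyquist bin so that bands
tiling [0, fs/2] sum to the total power. Brute-force O(N²) DFT agreement
is tested to 1e-10.

## ERD/ERS

`ERD/ERS % = 100·(E − R)/R`, negative = desynchronization. Band energy of
a window is periodogram band power times window duration (µV²·s); the
estimator requires at least 4 cycles of the band's lower edge. In session
maps, E and R are averaged across trials *before* the ratio (the standard
low-variance estimator), and each is divided by its window duration so
that unequal reference/event windows compare mean power, not raw energy —
otherwise the default windows ([−1.5, −0.5) vs [+0.5, +2.5) s, both clear
of the cue ramp) would bias the percentage by the duration ratio.

Known small bias: the additive in-band noise floor shrinks measured ERD
magnitude toward zero by a factor `S/(S + N_band)`. At the default 10 dB
SNR this is ≈ 2 points; at 5 dB the beta band (smaller rhythm power) reads
≈ −40% for an injected −50%. The ±8-point recovery tolerance used in the
tests covers it at the default settings.

## Classifiers

Both networks are plain numpy (float32 for speed; float64 in
gradient-check tests), single-threaded and fully seeded, so training is
bit-reproducible. Gradients are derived by hand and validated against
central finite differences.

* **Shallow spectral-spatial CNN** — temporal convolution (kernel 11
  samples ≈ 110 ms, 8 filters, shared across channels) → spatial
  convolution over the full montage (16 filters) → square →
  average-pool (factor 4) → dense softmax. Squaring + pooling computes
  windowed band power, i.e. exactly the ERD feature family. The two
  stacked linear convolutions are evaluated as one combined space-time
  kernel (im2col + GEMM) with gradients propagated through the
  factorization — an algebraic identity, not an approximation.
* **LSTM baseline** — channels as per-timestep features, average-pooled
  in time by 5 (550 → 110 steps) to keep backprop-through-time tractable
  on one CPU, single layer of 64 units, mean hidden state over time →
  dense softmax.

**Normalization.** Per-channel z-scoring followed by ZCA spatial
whitening, both estimated on the training partition only and stored with
the model. The whitening matters: with ~100–200 trials and a 118-channel
montage, the power of a randomly-projected channel mixture carries ~1% of
the class effect, and the spatial filters are effectively unlearnable from
the raw montage (measured: fold accuracies 0.45–0.6 across optimizer
settings); after sphering the background is isotropic, the modulated
source direction dominates the quadratic-feature gradients, and the same
network reaches fold accuracy 1.0.

**Optimization.** Adam, learning rate 3e-3, batch size 8, L2 penalty 0.1
on weight matrices, at most 60 epochs with early stopping (patience 10) on
the loss of a stratified 20% validation split, restoring the best
snapshot. Training shows a characteristic plateau (several hundred steps
while the spatial filters align) followed by a sharp transition, so early
stopping is suspended for the first 40 epochs; small batches shorten the
plateau markedly (the transition lands near epoch 20 at batch 8 versus
epoch 70–90 at batch 32). Rarely an initialization never escapes the
plateau within the budget, so training re-initializes up to 3 times with
derived seeds (the data split and normalization stay fixed), stops as
soon as an attempt reaches 0.8 validation accuracy, and keeps the best
attempt; cross-validation additionally offsets the training seed per fold
so one bad draw cannot affect every fold. All of it is a deterministic
function of the configured seed. These defaults were fixed from that
measured behaviour.

**Evaluation.** Stratified seeded k-fold CV (k = 5 by default);
architecture comparisons reuse identical fold assignments and report
paired per-fold differences. A per-subject versus pooled-training harness
reports both regimes without asserting a direction. Leakage guards are
tested: fold assignment, normalization and whitening derive from training
partitions only, and shuffling test labels cannot change predictions.

## Pipeline and reproducibility

`run_all` executes simulate → denoise → PSD → ERD → CV from a single
config. One master seed fans out to stage seeds via
`SeedSequence(master, spawn_key=(stage_index,)) mod 2³¹` (0 = generate,
1 = classify). The run report contains only seed-determined quantities
(timings go to logs, not the report), is written atomically, and is
bit-identical across reruns of the same config.

Problem sizes used by the shipped checks: the separability benchmark runs
the 118-channel, 100 Hz geometry at 100 trials per class; parameter
recovery uses 140 trials per class on an 8-channel montage; null-effect
controls use 50 trials per class on 16 channels; the determinism check
uses a 24-trials-per-class, 8-channel configuration. These sizes keep the
full study at a few CPU-minutes while leaving every statistical tolerance
intact.

## Formats

* Continuous EEG: EDF (read via MNE; written by a minimal built-in EDF
  writer — 1 s records, int16 over each channel's physical range, zero
  padding to whole records) or CSV with a JSON sidecar carrying `fs`.
* Events: CSV with `onset_sample,label`, 0-based, strictly increasing.
* Epochs container: a little-endian float32 blob of the trial-major array
  plus a JSON sidecar (shape, fs, labels, channels, cue index, provenance,
  SHA-256 checksum). All indices 0-based; all windows half-open.

## Known limitations

* The generator's class signal is purely spectral-spatial; conclusions
  about temporal models (the LSTM) on real data cannot be drawn from it.
* db6 band selectivity caps beta-band energy retention at ~86% near 20 Hz.
* The EDF writer targets this package's round-trip needs (uV, integer
  sampling rates), not the full EDF+ specification.
* GDF (competition-native) input is not implemented; external real-data
  benchmarks require user-supplied recordings in EDF/CSV.
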