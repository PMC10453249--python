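# Methods

## Problem and signal model

A nasalance-style device records speech on two channels: a microphone in
front of the nasal cavity and one in front of the oral cavity, separated by
a baffle, sampled at `fs = 11,025 Hz`. With velopharyngeal insufficiency
(VPI), part of the airflow and acoustic energy that should exit orally leaks
through the open velopharyngeal port into the nasal tract. The package
detects this leak from two complementary phoneme classes:

* **Unvoiced (aspirated) consonants** `/p t k q c h x sh f/` — frication is
  generated independently in each cavity, so the two radiated signals are
  uncorrelated. Nasal air emission shows up as nasal-channel energy where a
  healthy speaker has essentially none.
* **Nonnasalized vowels** `/a e i u/` — one glottal source is filtered by
  the oral tract and, when the port leaks, additionally by the nasal tract.
  Hypernasality shows up as a changed nasal-channel spectrum (a strong low
  nasal resonance) relative to the oral channel.

Each microphone also picks up a linearly attenuated copy of the opposite
cavity (`x_o = o + α·n`, `x_n = α·o + n`, with the two attenuations taken
equal). Since `α` is small (~0.1 for a baffled headset), `α²` terms are
dropped, and the PSD of each recorded channel stands in for the PSD of its
own cavity's radiation.

## Consonant pipeline

1. **Framing** — 20 ms frames, 6 ms shift, both in samples via
   `floor(ms·fs/1000)` (220 and 66 samples). Frames are plain signal slices.
2. **Per-frame PSD ratio** — one-sided periodogram `|FFT_256(x)|²/L_f` per
   channel, then `R[k] = (P_n[k] + ε/2)/(P_n[k] + P_o[k] + ε)`. The
   periodogram is mathematically the DFT of the biased autocorrelation
   (Wiener–Khinchin; the suite checks the identity to 1e-9) but is
   guaranteed nonnegative in floating point. The symmetric ε placement
   (default `1e-12 ×` the largest total bin power, floored at `1e-20`)
   keeps `R ∈ (0,1)`, makes a channel swap map `R → 1−R` to machine
   precision, and turns zero-power bins into the uninformative value 0.5.
3. **Analysis taper** — `psdr_matrix` applies a Hann window to each frame
   before the PSD. The identical taper on both channels cancels in the
   in-band ratio; what it buys is sidelobe suppression: with a rectangular
   window, a band-limited nasal source leaks a leakage-proportional energy
   floor across the whole spectrum, inflating R̄ in subbands the source
   never excited and distorting the subband-area features. `window="rect"`
   restores the untapered estimator.
4. **Robust average** — per frequency bin, the frame values are sorted
   ascending and averaged over the 1-based order statistics
   `ceil(Nf/4) … ceil(3Nf/4)` (round-up brackets; a single frame averages to
   itself). This drops the outlier quartiles caused by transient noise.
5. **Features** — DC is excluded everywhere, leaving 128 bins that split
   evenly into `Nh = 4` subbands of 32 bins (top band from
   `3fs/8 = 4134.375 Hz` to `fs/2`). RPFD takes the maximum of R̄ and of its
   first forward difference plus their frequencies (ties break toward the
   lowest frequency; the difference location reports the lower bin of the
   pair). RFD is each subband's share of the total area under R̄ (sums to 1
   by construction). Feature order: `[MR, locMR, MDR, locMDR, RFD_1..RFD_4]`,
   locations in Hz.
6. **Classifier** — standardization + SVM (RBF kernel, `C = 1`,
   `gamma = "scale"`); LDA and AdaBoost are config alternatives. The
   pipeline stores the training-set standardization inside the model.

## Vowel pipeline (CARS-Net)

* **Input layer** — each channel of a vowel segment becomes a 64×64
  log-magnitude spectrogram: 128-sample Hann-windowed frames (≈11.6 ms, so
  the frame length equals the FFT length and the frequency axis has exactly
  64 non-DC bins), hop chosen so at least 64 frames exist, `log(1+|S|)`
  compression, time axis linearly resampled to 64 columns, and *joint*
  min–max normalization over the two channels — per-channel normalization
  would erase the inter-channel level difference that carries the
  diagnosis.
* **Difference feature extractor** — two weight-shared residual branches.
  Default preset mirrors an 18-layer residual network (7×7 stride-2 stem +
  3×3 stride-2 max pool, widths 64/128/256/512, two blocks per stage,
  stage strides 1/2/2/2; 64×64 input → 2×2×512 final maps). Each block's
  cross-attention coupling concatenates the two branch inputs along
  channels, global-average-pools, applies one shared affine map + rectifier
  to produce a channel weight vector of the block's output width, and
  scales **both** branches' conv-path outputs with it before the skip
  addition (`F_{i+1} = skip(F_i) + W_i ⊙ conv(F_i)`). Blocks that change
  shape use the standard 1×1 stride-matched skip projection. No
  normalization layers: the residual sum is used as written, and plain
  conv + ReLU with He initialization trains stably at this scale.
* **Classifier and loss** — softmax affine head on the flattened difference
  of the final maps. Training loss is binary cross-entropy (probabilities
  clipped to `[1e-12, 1-1e-12]`) plus a nonnegative contrastive term
  `y·d² + (1−y)·max(margin−d, 0)²` with `margin = 2` and `y = 1` for VPI,
  where `d` is the Euclidean distance between the flattened branch outputs.
  VPI pairs are pulled together and control pairs pushed beyond the margin;
  the classifier reads the difference map, so this orientation is a
  convention, not a constraint.
* **Optimization** — Adam (`lr = 0.001`, framework-default betas), batch 64,
  100 epochs by default. Everything is numpy with hand-derived gradients;
  the suite checks them against central differences to 1e-3 relative. All
  randomness (He init, shuffling) derives from the config seed, so reruns
  are bit-identical.
* **Small preset** — for desk-scale runs: 3×3 stride-1 stem + 2×2 stride-2
  pool, widths 8/16/32/64, one block per stage, all stage strides 2
  (64×64 input → 2×2×64; 32×32 → 1×1×64). Used by the scaled-down
  evaluation below.

`use_ca=False` removes the attention coupling (plain Siamese residual net);
`use_contrastive=False` trains on cross-entropy alone. Both flags exist to
reproduce the corresponding ablations structurally.

## Subject fusion and metrics

A subject is VPI iff strictly more than half of their phoneme predictions
are VPI; a tie (possible only for even counts — the full 13-phoneme
inventory cannot tie) resolves to control. Consonant and vowel predictions
carry equal weight. Metrics are the standard confusion-matrix set
(accuracy, precision, recall, F1, TNR, FPR), reported as percentages to two
decimals; undefined ratios are NaN with a warning.

Cross-validation is label-stratified and, by default, grouped by subject
(no speaker appears on both sides of a fold). The grouped assignment is a
seeded round-robin per class — deterministic across library versions. An
ungrouped, phoneme-level stratified protocol is available via
`--no-group-folds`.

## Synthetic cohort generator

The generator reproduces the statistical structure the method assumes, not
perceptual speech:

* **Consonants** — two independent noise sources. The nasal source is
  band-limited to 200–1300 Hz (inside the lowest feature subband); the oral
  source is 90% band noise at 4200–5400 Hz (inside the top subband, where
  oral frication concentrates) plus a 10% broadband floor — real frication
  is high-band-emphasized, not brickwall-limited, and the floor lets the
  low-band ratio grow smoothly with leakage instead of saturating
  instantly. Band shaping is an exact FFT-domain bandpass. Sources are
  RMS-normalized, scaled by `sqrt(λ)` (nasal) and `sqrt(1−λ)` (oral) so the
  leakage fraction λ is exactly the nasal share of source energy, then
  crosstalk-mixed.
* **Vowels** — a jittered impulse train at f0 (drawn 100–220 Hz per
  subject) shaped by a 1 ms decaying pulse, with 5% shimmer. The oral
  branch cascades two-pole resonators at per-vowel formant presets
  (standard-phonetics-style values, fully overridable); the nasal branch is
  a single 300 Hz resonance. Branch outputs are RMS-normalized and scaled
  by `(1−λ)` and `λ`, then crosstalk-mixed.
* **Cohort structure** — λ is drawn once per subject (VPI: U(0.30, 0.70);
  control: U(0.00, 0.05); `--hard` narrows the gap to U(0.15, 0.45) vs
  U(0.00, 0.12)) and shared across that subject's 13 phonemes, so
  subject-level voting is genuinely subject-structured. Crosstalk
  `α = 0.1` — small enough that the `α² ≈ 0` approximation holds to 1%,
  large enough to exercise the crosstalk path. Regeneration from the same
  spec is byte-identical (float32 WAVs, all seeds derived from the cohort
  seed).

**What passing tests do and do not show.** The generator has no
reverberation, no background noise, no coarticulation, no vocal-tract age
or sex structure, and its class separation (λ gap) is a design choice, not
a clinical estimate. Passing the end-to-end benchmark shows the pipeline
correctly extracts and fuses the leakage signal it is designed for; it says
nothing about accuracy on clinical recordings.

## Problem sizes and numerical choices

The scaled-down evaluation (tests and `scripts/acceptance.py`) uses 30
subjects (15 VPI / 15 control) × 13 phonemes, subject-grouped 5-fold
cross-validation, and the small network preset trained 10 epochs with batch
16 — chosen so a full run completes in about a minute on one CPU while
leaving the pipeline structurally identical to the full-size configuration.

Degenerate inputs: empty segments, mono files without an oral path, unequal
channel lengths, sub-frame segments, single-class training sets, and empty
subjects all raise immediately with specific messages. Argmax ties break
toward the lowest frequency. Frames longer than the FFT length are
truncated with a logged warning; shorter frames are zero-padded. The
contrastive gradient at `d = 0` uses the zero subgradient.

## Known limitations

* The crosstalk attenuation is never deconvolved; `estimate_crosstalk` is a
  diagnostic (median `sqrt(E_n/E_o)` over oral-only recordings), not part
  of the ratio estimator.
* Phoneme segmentation is external: the manifest supplies segment bounds.
* No resampling: signals are processed at their native rate, which enters
  every frequency formula.
* The vowel network is CPU-scale numpy; the default (18-layer) preset
  trains slowly compared to GPU frameworks and is intended for structural
  fidelity, not throughput.
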