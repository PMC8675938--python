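# Methods

`cardiomech` scores the risk of coronary artery disease (CAD, ≥50 %
stenosis in at least one coronary artery) from chest-vibration
recordings taken at rest: a sternal accelerometer gives the
seismocardiogram (SCG, linear acceleration in x/y/z, in g) and a
co-located gyroscope the gyrocardiogram (GCG, angular velocity in
x/y/z, in °/s), time-synchronised with a single-lead reference ECG at
1 kHz. This note records the model, the numerical choices, and what
the synthetic experiments do and do not demonstrate.

## Pipeline

1. **Preprocessing.** Each channel is high-pass filtered with a
   zero-phase (forward–backward) order-5 Butterworth at 0.5 Hz to
   remove baseline wander, demeaned and scaled to [−1, 1], then
   decimated 1 kHz → 250 Hz through a zero-phase order-8 Chebyshev-I
   low-pass (0.05 dB ripple, cut-off at 0.8 × the output Nyquist —
   `scipy.signal.decimate`). The order is filter → normalise →
   downsample; because decimation slightly perturbs the mean and peak,
   a final demean/rescale restores the [−1, 1] contract at 250 Hz.
   Zero-phase filtering uses reflect padding of 3 × (order + 1)
   samples. The ECG receives identical treatment; only its timing is
   used downstream, which normalisation cannot affect.

2. **Segmentation.** R peaks come from the Pan–Tompkins detector
   (band-pass 5–15 Hz, five-point derivative, squaring, 150 ms
   moving-window integration, dual adaptive thresholds with a
   1.66 × RR search-back), refined to the local ECG maximum within
   ±50 ms. The QRS onset (Q) is defined morphologically as the ECG
   minimum in the 60 ms window ending just before R. Beats implying
   Q-to-Q intervals outside [0.3, 2.0] s are discarded as physiologic
   gating against missed or false detections. Cycles are half-open
   Q-to-Q slices (so concatenating raw cycles reconstructs the spanned
   signal exactly), linearly resampled to 250 points with endpoints
   preserved, and grouped into non-overlapping runs of 10 consecutive
   cycles → 2,500-sample series; a trailing remainder of fewer than 10
   cycles is dropped. Non-overlapping grouping avoids counting any
   cycle twice in evaluation.

3. **Features.** Each series is transformed with a synchrosqueezing
   wavelet transform: an analytic Morlet CWT (centre frequency μ = 6)
   evaluated on a geometric frequency grid, sharpened by reallocating
   every coefficient above a 10⁻⁸-relative magnitude floor to the grid
   row nearest its instantaneous frequency Im(∂ₜW/W)/2π. The grid
   places exactly 150 rows in [0.5, 40] Hz and continues geometrically
   to Nyquist (178 rows in total by default), so discarding rows above
   40 Hz always leaves a 150 × 2,500 band regardless of transform
   settings; a transform run on a foreign grid is re-gridded by linear
   interpolation along frequency. The plane is split at the known
   cycle boundaries into ten 150 × 250 planes, block-averaged with
   non-overlapping 5-row × 10-column windows to 30 × 25 (the only
   reading of "moving windows of 5 and 10 samples" consistent with the
   150→30 and 250→25 reduction), min-max rescaled **per cycle image**
   to [0, 1] (an all-constant plane maps to zero), and flattened
   row-major into 750-element vectors. Per-image scaling also removes
   between-subject amplitude confounds; it is the most consequential
   of the unstated normalisation choices and is therefore isolated in
   one function.

4. **Classifier.** One 1-D CNN per channel, input length 750: three
   convolutional blocks (32, 16, 16 filters, kernel 10, "same"
   padding, ReLU, max-pool 2), batch normalisation after the ReLU of
   block 1, dropout (rate 0.25) in blocks 2 and 3; two fully connected
   layers of 1,000 units with ReLU and dropout 0.5; a 2-unit softmax.
   Training: Adam (learning rate 10⁻³) on cross-entropy (equivalent to
   binary cross-entropy for the two-unit softmax) for a fixed number
   of epochs — 100 by default — recording validation accuracy after
   each epoch and keeping the weights of the best epoch (earliest on
   ties). "Same" padding lets 750 divide cleanly through three
   pool-by-2 stages (750 → 375 → 187 → 93; flatten = 1,488). The
   network is implemented directly in numpy (float32, im2col/GEMM
   convolutions, manual backpropagation); all randomness — weight
   init, shuffling, dropout — derives from one integer seed, so
   training histories are bit-reproducible. The default batch size is
   128: training sets here are a few hundred vectors per fold, and on
   a single CPU larger batches cut optimiser-step overhead without
   affecting the epoch-selection rule; it is exposed in the
   configuration alongside the learning rate and the conv dropout rate
   (the fully connected rate 0.5 is part of the architecture). No
   class reweighting is applied by default.

5. **Evaluation.** Leave-one-subject-out: for each of N subjects the
   six channel classifiers are trained on the other N−1 subjects'
   cycles, with an inner 80/20 train/validation split drawn at the
   *subject* level (stratified by class), so no subject's cycles
   appear on both sides of the inner split and the held-out subject's
   cycles appear nowhere. A subject's per-channel risk is the
   arithmetic mean of its per-cycle CAD probabilities (the
   maximum-entropy aggregation, consistent with the averaging-based
   fusion); fused risks average all six channels, the three SCG
   channels, and the three GCG channels. Metrics per model (9 models):
   AUC with a DeLong asymptotic 95 % CI, and — at the fixed 0.5
   decision threshold — sensitivity, specificity, PPV and NPV with
   Wilson 95 % CIs, F1 = 2·PPV·sens/(PPV + sens), and the
   discrimination slope (mean risk of the CAD group minus mean risk of
   the non-CAD group). Model AUCs are compared with the paired DeLong
   test. Two leakage guards are built in: identical recordings under
   different ids abort the run (SHA-256 of the raw samples), and every
   fold asserts that the held-out subject's feature matrix hash does
   not occur in that fold's training or validation data.

## Synthetic cohorts

The clinical recordings the pipeline targets are not publicly
available, so the generator fabricates cohorts with the statistical
structure the pipeline assumes, and nothing more:

* beats at 60 ± 5 bpm (inter-beat intervals i.i.d. Gaussian,
  truncated at ±3 SD — the simplest HRV model that exercises the
  cycle-length interpolation);
* an ECG with a P wave, a Q dip exactly 30 ms before each R spike
  (ground truth for Q-localisation tests), S dip and T wave;
* SCG/GCG cycle templates built from three Gabor atoms (Gaussian-
  windowed cosines at 14, 22 and 9 Hz) at fixed latencies after the
  cycle onset, with per-channel amplitude/latency flavour and 10 %
  per-cycle amplitude jitter. The CAD class shifts the mid-systolic
  atom by +8 Hz and +40 % amplitude (scaled by a `separation`
  parameter in [0, 1.5]); both class templates live entirely below
  the 40 Hz analysis ceiling by construction;
* sinusoidal baseline wander at 0.2 Hz with amplitude 0.5 (safely
  below the 0.5 Hz high-pass) and white sensor noise at 5 % of the
  template amplitude.

The defaults above are the study conditions of every test. What
passing shows: the pipeline recovers a genuine below-40 Hz
time-frequency class difference end-to-end through segmentation,
synchrosqueezing, reduction, training and subject-level fusion, and
reports chance-level AUC with honest confidence intervals when no
difference exists. What it does not show: anything about real CAD
physiology — the synthetic separation is a free parameter, not a
claim about disease; the generator has no SCG fiducial morphology
(MC/AO/AC/MO), no respiration modulation, and no between-site
variability.

## Problem sizes

The end-to-end experiments use 8 subjects per class, 30 s recordings
(the pipeline-eligibility minimum — two 10-cycle series per subject)
and 10 training epochs for the separated cohort; 6 per class and 5
epochs for the zero-separation control. These sizes were chosen once
as the smallest cohorts on which subject-level AUC has useful
resolution (1/64 granularity) while keeping a pure-CPU run of 96
trained networks comfortably short; the AUC ≥ 0.95 recovery bar and
the null CI-coverage check do not depend on them.

## Numerical notes and edge cases

* Normalising an all-zero channel returns it unchanged; a constant
  reduced image maps to all-zero intensity.
* The SST of an all-zero series is an all-zero plane; non-finite
  samples are rejected.
* Reassignment drops coefficients whose instantaneous-frequency
  estimate is non-positive, non-finite, or outside the geometric bin
  edges of the grid.
* A cycle shorter than 2 samples cannot be interpolated and is an
  error; beats whose 60 ms Q window would leave the signal are
  dropped.
* Validation-accuracy ties during training resolve to the earliest
  epoch; fused risks are exact arithmetic means (tested to 10⁻¹²).
* DeLong variance of a perfectly separating score set is zero: the CI
  collapses to the point estimate, and the paired test returns p = 1
  for identical scores, p = 0 for different scores with zero variance.
* EDF and WFDB writers quantise to 16 bits; round-trips are exact to
  one quantisation step. CSV round-trips at 9 significant digits.

## Known limitations

* Clinical-scale performance figures (hundreds of angiography-
  validated subjects) are out of reach by construction: no such
  cohort is publicly released, and no synthetic cohort can stand in
  for one. The LOSO experiments here validate the machinery, not any
  clinical claim.
* Pan–Tompkins is tuned for the generator's clean morphology plus
  white noise; pathological ECG (bundle-branch block, atrial
  fibrillation) was not in scope.
* The SST row count above the 40 Hz band (178 total) is a default,
  not a contract; only the 150-row band enters the features.
* Training the numpy CNN is CPU-bound; at clinical scale (hundreds of
  subjects, 100 epochs) a GPU framework would be the practical choice.
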