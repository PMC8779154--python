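# Methods

`emgsleeve` implements the signal path of a forearm-sleeve myoelectric
control system in software: synthetic surface-EMG (sEMG) session
generation, hardware-equivalent band-limiting, time-domain feature binning,
a small feedforward neural classifier emitting a 3-bit gesture code, online
streaming control, and the signal-quality metrics used to compare
electrodes. This note records the models, the parameters that matter, and
the design decisions taken where the problem was genuinely open.

## Gesture taxonomy and state vectors

Eight classes: Rest plus seven finger-flexion poses (Index, Middle,
Ring/Pinky, Index+Middle, Middle+Ring/Pinky, Index+Ring/Pinky, All
Fingers). Each maps one-to-one onto a 3-bit state vector `(a, b, c)`; the
eight codes exhaust all bit patterns, so decoding a thresholded network
output is total — every possible output is some gesture, with the all-zero
code meaning Rest. Bit `c` flags index involvement, `b` middle, `a`
ring/pinky; compound poses OR the bits.

## Synthetic session model

A session is: `calibration_s` (10 s) of rest, then for each pose in
sequence `hold_s` (5 s) of activity followed by `rest_s` (10 s) of rest —
115 s at the default 7 poses. Ten sessions form one subject, the first five
for training and five for testing. Sampling is 1 kHz on 7 channels.

Per channel the signal is

    x(t) = a_g,c · e(t) · n_band(t) + n_base(t) [+ artifact + powerline]

* `n_band`: Gaussian white noise band-passed to 20–450 Hz (4th-order
  Butterworth, zero-phase) and rescaled to unit RMS — the standard
  interference-pattern surrogate for sEMG. Amplitude-domain features
  (WAMP/WL/RMS) depend on burst energy, not motor-unit waveshape, so no
  MUAP-template convolution is attempted.
* `a_g,c`: the activation matrix entry for gesture `g`, channel `c`
  (arbitrary units emulating µV). No published per-gesture activation map
  exists for this electrode layout, so the default matrix is a constructed,
  clearly synthetic one: channel pairs act as finger-group flexors (ch1–2
  index, ch3–4 middle, ch5–6 ring/pinky; primaries burst at 30, neighbours
  get 20% crosstalk) and ch7 emulates a shared digit flexor whose drive
  grows with the number of active groups (10 per group). With baseline
  noise SD 2.0 this puts hold-to-rest RMS ratios near 15, the same order as
  SNRs reported for real forearm recordings with comparable hardware.
* `e(t)`: raised-cosine onset/offset ramps (100 ms) instead of
  instantaneous steps, so filter ringing does not dominate boundary bins.
* Optional deterministic sinusoids model sub-19 Hz motion artifact and
  60 Hz powerline pickup; both default to zero and exist to exercise the
  high-pass stage.

Session `i` of a subject uses seed `master_seed + i`: reproducible but
statistically distinct datasets. The label timeline is a function of the
protocol alone, never of the noise seed.

What this generator deliberately does **not** emulate: electrode shift,
impedance drift, fatigue, co-contraction variability, or inter-subject
anatomy. Passing tests therefore demonstrate that the pipeline recovers the
structure its own signal model encodes — a parameter-recovery result, not a
claim about classification accuracy on real limbs.

## Band-limiting chain

The analog front end being emulated is a 19 Hz second-order Butterworth
high-pass cascaded with a 500 Hz third-order Bessel low-pass. Both stages
are discretized by the bilinear transform with frequency pre-warping
(scipy's designs), which preserves the analog −3 dB frequency exactly: the
measured high-pass cutoff, located by scanning the discrete magnitude
response on a 0.01 Hz grid, is 19.00 Hz. The Bessel stage uses magnitude
(−3 dB) normalization — the conventional reading of "cutoff frequency";
delay-normalized Bessel conventions exist but would put the −3 dB point
elsewhere.

Application is causal (forward-only, zero initial conditions) by default:
hardware ahead of the ADC cannot see the future, and neither can the online
controller. Tests evaluate steady-state windows past the startup transient.

Degenerate corner: at fs = 1 kHz the 500 Hz low-pass edge coincides with
Nyquist, where no discrete low-pass exists. Since the sampled signal is
already Nyquist-limited, the low-pass stage reduces to the identity in
exactly that case; a cutoff strictly above Nyquist raises a design error.
The Bessel stage's response is tested at sampling rates where it is a real
filter (e.g. 4 kHz).

## Feature layer

Bins are non-overlapping windows of `floor(bin_ms/1000 · fs)` samples —
270 samples at the defaults, mirroring firmware that stores exactly one bin
at a time; the trailing partial window is discarded. Per channel and bin:

* WAMP = #{i : |x_i − x_{i−1}| > ε}, strict inequality;
* WL = Σ |x_i − x_{i−1}|;
* RMS = sqrt(mean x_i²).

These satisfy WL ≥ ε·WAMP, scale equivariance of WL/RMS, and monotonicity
of WAMP in ε — all enforced as property tests. Vectors are channel-major,
(WAMP, WL, RMS) within channel: 21 values for 7 channels.

ε is "some arbitrary threshold" in the source formulation, so it is made
data-driven to survive amplitude-scale changes: ε = 3 × the median across
channels of the RMS of first differences over the initial calibration rest
(band-limited). It is fitted once per subject, used for every session, and
serialized with the model so online streaming reproduces training-time
features bit for bit.

Bin labels are the strict majority of per-sample labels; ties and
no-majority bins fall back to Rest (conservative at pose transitions).
Feature normalization divides each dimension by its training-set maximum
absolute value (zero-max dimensions pass through); the constants are stored
in the model file.

## Classifier

A 21-3-3 feedforward network, logistic sigmoid on hidden and output layers,
trained by back-propagation with mini-batch gradient descent at learning
rate 1e-4, batch size 5, 6000 epochs. Outputs are three soft bits;
`bit = 1 iff activation > 0.5` (strict, so the degenerate all-0.5 output
fails safe to Rest), decoded through the state-vector table. Rest
participates in training as the explicit target (0,0,0), using the
calibration and inter-pose rest bins.

Formulation choices, all genuinely open and decided here:

* **Objective and gradient convention.** Per-sample loss ½‖a − t‖² with
  mini-batch gradients *summed* over the batch — the classical backprop
  formulation for networks of this vintage and size. The alternative
  (averaging over batch and output bits) scales every step down 7.5× and,
  at the fixed schedule above, leaves the network stuck predicting the
  majority Rest class; summing makes the per-sample step size independent
  of batch geometry and trains to convergence at the same schedule. Loss
  histories report the per-sample MSE, mean((a−t)²), as a monitoring
  metric.
* **Initialization.** Glorot-uniform weights (r = sqrt(6/(fan_in+fan_out))),
  zero biases, seeded; scale-robust for a 21-3-3 net.
* **Shuffling.** Epoch-wise reshuffling with a seeded generator before
  batching; identical seeds give bitwise-identical loss histories.
* **Oracle.** A central-finite-difference gradient checker (step 1e-5) over
  every parameter is the module's correctness oracle; analytic gradients
  agree to max relative error below 1e-6 on random instances, and the
  checker flags a deliberately perturbed gradient (negative control).

MSE on independent sigmoid bits (rather than softmax cross-entropy) is
deliberate: the output is a 3-bit code whose bits have independent
anatomical meaning, not a categorical distribution.

## Online control loop

Streaming classification applies the identical code path as offline
evaluation: causal band-limiting, consecutive 270 ms bins, features with
the stored ε, stored normalization, forward pass, threshold, decode — one
decision per bin, no debouncing. Online and offline per-bin decisions are
asserted identical in tests. Decisions map to six boolean servo flags
(five finger flexions plus thumb abduction); each pose flexes exactly the
fingers it names, All Fingers flexes all five, and thumb abduction stays
false for every trained pose.

Trial scoring: one verdict per pose hold — the modal non-rest decision
inside the hold's bin window with one bin trimmed at each edge (transition
bins), ties broken by earliest occurrence, no non-rest decision at all
scored as a missed (Rest) trial. This emulates a human rater judging the
dominant hand pose over a hold.

## Signal-quality metrics

* **Activity detection**: active where the moving-RMS envelope (100 ms
  centered window — a conventional sEMG envelope scale; the 6×SD rule's
  source statement fixes only the multiplier) exceeds 6 × SD of the raw
  baseline samples (the first 10 s rest). Scale-invariant by construction.
  "SD of the baseline" is read literally as the SD of raw baseline samples
  (≈ baseline RMS for zero-mean signals); SD of the moving-RMS would be an
  alternative reading.
* **SNR**: linear ratio RMS(active)/RMS(inactive) — reported linear, not
  dB, following the ratio definition.
* **Welch PSD**: one-sided, 1 s Hann segments, 50% overlap, constant
  detrend — the method's canonical parameters, all configurable. The
  trapezoid-integrated density reproduces signal variance within 5%
  (Parseval check).
* **PSD correlation**: Pearson correlation of two densities over the
  filtered band (19–500 Hz by default), with the second estimate
  interpolated onto the first's grid; scale-invariant.

## Numerical and degenerate-input choices

Sigmoid evaluated in a sign-split form to avoid overflow at extreme logits.
Filters checked for poles strictly inside the unit circle at design time.
Zero-max normalization dimensions pass through undivided. Empty recordings,
sub-bin recordings, degenerate masks (all active/inactive), baselines
longer than the signal, and malformed config/model files raise distinct,
described errors. All randomness flows through `numpy.random.default_rng`
seeded from a single configured integer.

## Problem sizes

The test suite exercises the full study conditions once: one synthetic
subject (10 × 115 s sessions, 5/5 split), trained at lr 1e-4 / batch 5 /
6000 epochs on ~2100 labeled bins (a few minutes on one CPU), reaching
≥ 99% offline accuracy and identical online/offline decisions; compressed
protocols (2 s holds, hundreds of epochs) cover the remaining behavioral
tests. `scripts/acceptance.py` recomputes the measured high-pass −3 dB
cutoff from a fresh filter design.

## Known limitations

The classifier, features and filters are faithful to the emulated system,
but accuracy numbers obtained here characterize the synthetic signal model,
which is easier than real forearm sEMG (no electrode shift, no fatigue, no
inter-session variability, well-separated activation patterns). The 3-bit
output code cannot represent uncertainty between poses sharing bits; the
modal trial-scoring rule is one reasonable formalization of video-based
judgment, not a reconstruction of it.
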