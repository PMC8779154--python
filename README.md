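# emgsleeve

A surface-EMG (sEMG) gesture-recognition pipeline for myoelectric
prosthesis control, built as a tested software counterpart of a
textile-sleeve EMG system: 7-channel recordings at 1 kHz are band-limited
to 19–500 Hz, chopped into 270 ms bins, reduced to three time-domain
features per channel, classified by a small feedforward neural network into
rest plus seven finger-flexion poses, and decoded into prosthetic-hand
servo commands — with the signal-quality metrics (burst detection, SNR,
Welch power spectra) used to compare electrodes.

It is aimed at researchers prototyping myoelectric control loops and at
anyone who wants a reproducible, synthetic-data test bed for the classic
WAMP/WL/RMS + small-ANN gesture pipeline.

## The model

Each 270 ms bin (N = 270 samples at 1 kHz) yields, per channel:

* Willison amplitude — WAMP = Σᵢ f(|xᵢ − xᵢ₋₁|), f(u) = 1 if u > ε else 0
* waveform length — WL = Σᵢ |xᵢ − xᵢ₋₁|
* root mean square — RMS = √(1/N · Σᵢ xᵢ²)

giving 21 features for 7 channels. A 21-3-3 feedforward network with
logistic-sigmoid activations is trained by back-propagation with mini-batch
gradient descent (learning rate 1e-4, batch size 5, 6000 epochs) against
the pose's 3-bit state vector; thresholding the three outputs at 0.5 and
decoding through the state-vector table

| gesture | a b c | | gesture | a b c |
|---|---|---|---|---|
| Rest | 0 0 0 | | Index+Middle | 0 1 1 |
| Index | 0 0 1 | | Middle+Ring/Pinky | 1 1 0 |
| Middle | 0 1 0 | | Index+Ring/Pinky | 1 0 1 |
| Ring/Pinky | 1 0 0 | | All Fingers | 1 1 1 |

maps every possible output to exactly one gesture. Since no public
recordings exist for this protocol, a first-class synthetic generator
emulates the session structure (10 s calibration rest, then 7 poses ×
[5 s hold + 10 s rest]; 10 sessions per subject, 5 train / 5 test) with
band-limited noise bursts whose per-gesture, per-channel RMS follows a
documented activation matrix.

## Worked example

`examples/03_train_and_evaluate.py` trains on a compressed protocol (2 s
holds, 2 training + 2 test sessions, 600 epochs) for a fast demonstration:

```
trained 21-3-3 network, final epoch MSE 0.0221
offline accuracy on held-out sessions: 99.3% (296 bins)
per-class diagonal (row-normalized %):
  Rest             100.0%
  Index            100.0%
  Middle           100.0%
  RingPinky        100.0%
  IndexMiddle      100.0%
  MiddleRingPinky  100.0%
  IndexRingPinky    87.5%
  AllFingers       100.0%
```

The accuracy is the fraction of held-out 270 ms bins whose decoded gesture
matches the protocol label; the per-class rows are the confusion-matrix
diagonal. Off-diagonal mass concentrates on poses sharing state-vector
bits. At the full study conditions (115 s sessions, 5/5 split, 6000 epochs
— exercised in `tests/test_acceptance.py`) offline accuracy is ≥ 99% and
the streamed online decisions are bin-for-bin identical to offline
evaluation. The other example scripts cover simulation, filtering and
feature extraction, signal-quality metrics, and the streaming control loop.

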