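"""Generate one labeled synthetic sEMG session and inspect its structure.

A default session is 115 s at 1 kHz on 7 channels: 10 s calibration rest,
then each of the 7 finger-flexion poses held 5 s with 10 s rest between.
"""

import numpy as np

import emgsleeve as es

protocol = es.SessionProtocol()
cfg = es.SynthConfig()
rec = es.generate_session(protocol, cfg, fs=1000.0, seed=1)

print(f"duration: {rec.duration_s:.0f} s, {rec.n_samples} samples, "
      f"{rec.n_channels} channels")

# per-gesture sample counts follow the protocol timing exactly
counts = {}
for g in rec.labels:
    counts[g.name] = counts.get(g.name, 0) + 1
for name, n in counts.items():
    print(f"  {name:<16} {n:>7} samples ({n / rec.fs:.0f} s)")

# the RMS contract: during the Index hold, ch1 bursts at ~sqrt(30^2 + 2^2)
idx = [i for i, g in enumerate(rec.labels) if g is es.GestureClass.Index]
hold_rms = np.sqrt(np.mean(rec.samples[idx[500:-500], 0] ** 2))
rest_rms = np.sqrt(np.mean(rec.samples[2000:8000, 0] ** 2))
print(f"ch1 RMS during Index hold: {hold_rms:.1f} (rest: {rest_rms:.1f}) — "
      f"the activation matrix sets the burst amplitude, baseline noise the rest")
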