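"""Electrode-style signal-quality report: activity detection, SNR, PSD.

Activity is wherever the 100 ms moving-RMS envelope exceeds 6x the standard
deviation of the 10 s calibration baseline; SNR is the linear ratio of RMS
amplitude between active and inactive states; spectra come from Welch's
method (1 s Hann segments, 50% overlap).
"""

import numpy as np

import emgsleeve as es

rec = es.generate_session(es.SessionProtocol(), es.SynthConfig(), 1000.0, seed=2)
x = rec.channel("ch7")  # the shared digit-flexor channel is active in every pose

mask = es.detect_activity(x, rec.fs, es.DetectionConfig())
snr = es.compute_snr(x, mask)
print(f"active fraction: {100 * mask.mean():.1f}% "
      f"(protocol holds occupy {7 * 5 / 115:.0%} of the session)")
print(f"SNR (linear): {snr:.1f}")

psd = es.welch_psd(x, rec.fs)
inband = (psd.freqs >= 19) & (psd.freqs <= 500)
frac = np.trapezoid(psd.density[inband], psd.freqs[inband]) / psd.total_power()
print(f"fraction of power in 19-500 Hz: {100 * frac:.1f}%")

# two channels recording the same process have highly correlated spectra
r = es.psd_correlation(es.welch_psd(rec.channel("ch1"), rec.fs),
                       es.welch_psd(rec.channel("ch2"), rec.fs),
                       band=(19.0, 499.0))
print(f"PSD correlation ch1 vs ch2 over the filtered band: {r:.3f} — "
      f"near 1 means the electrodes see the same spectral content")
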