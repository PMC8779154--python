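"""Software equivalent of the analog band-limiting front end (19–500 Hz).

The hardware chain is a second-order Butterworth high-pass at 19 Hz (motion
artifact rejection) cascaded with a third-order Bessel low-pass at 500 Hz
(high-frequency noise rejection).  Both stages are discretized with the
bilinear transform with frequency pre-warping, so the analog -3 dB cutoffs
are preserved exactly in the digital designs; the Bessel stage uses
magnitude (-3 dB) normalization, the conventional reading of a "cutoff
frequency".  Application is causal (forward-only) by default, since analog
hardware ahead of the ADC cannot see the future.

One degenerate corner matters in practice: at fs = 1 kHz the 500 Hz
low-pass edge coincides with Nyquist, where no discrete low-pass can be
designed.  The sampled signal is already Nyquist-limited, so in that exact
case the low-pass stage reduces to the identity; a cutoff strictly above
Nyquist is an error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import FilterSpec
from .io import EmgRecording

__all__ = ["FilterChain", "design_chain", "apply_bandlimit", "measured_hp_cutoff"]


@dataclass(frozen=True)
class FilterChain:
    """Designed discrete filter chain: high-pass and optional low-pass SOS."""

    hp_sos: np.ndarray
    lp_sos: np.ndarray | None  # None when lp_cutoff == Nyquist (identity stage)
    fs: float
    spec: FilterSpec

    def response(self, freqs: np.ndarray) -> np.ndarray:
        """Complex frequency response of the full chain at ``freqs`` (Hz)."""
        _, h = sps.sosfreqz(self.hp_sos, worN=freqs, fs=self.fs)
        if self.lp_sos is not None:
            _, h_lp = sps.sosfreqz(self.lp_sos, worN=freqs, fs=self.fs)
            h = h * h_lp
        return h

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Filter one channel, causally or zero-phase per the spec flag."""
        if self.spec.causal:
            y = sps.sosfilt(self.hp_sos, x)
            if self.lp_sos is not None:
                y = sps.sosfilt(self.lp_sos, y)
        else:
            y = sps.sosfiltfilt(self.hp_sos, x)
            if self.lp_sos is not None:
                y = sps.sosfiltfilt(self.lp_sos, y)
        return y


def design_chain(spec: FilterSpec, fs: float) -> FilterChain:
    """Design the discrete band-limiting chain for sampling rate ``fs``.

    Raises ``ValueError`` if a cutoff cannot be realized at this ``fs``
    (high-pass at or above Nyquist, or low-pass strictly above Nyquist).
    """
    nyq = fs / 2.0
    if spec.hp_cutoff >= nyq:
        raise ValueError(
            f"high-pass cutoff {spec.hp_cutoff} Hz is not below Nyquist "
            f"({nyq} Hz at fs={fs})"
        )
    if spec.lp_cutoff > nyq:
        raise ValueError(
            f"low-pass cutoff {spec.lp_cutoff} Hz exceeds Nyquist "
            f"({nyq} Hz at fs={fs}); chain cannot be designed"
        )
    hp_sos = sps.butter(
        spec.hp_order, spec.hp_cutoff, btype="highpass", fs=fs, output="sos"
    )
    if spec.lp_cutoff == nyq:
        lp_sos = None
    else:
        lp_sos = sps.bessel(
            spec.lp_order, spec.lp_cutoff, btype="lowpass", norm="mag",
            fs=fs, output="sos",
        )
    chain = FilterChain(hp_sos=hp_sos, lp_sos=lp_sos, fs=fs, spec=spec)
    for sos in (hp_sos,) if lp_sos is None else (hp_sos, lp_sos):
        _, poles, _ = sps.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0):
            raise ValueError("designed filter is unstable (pole on/outside unit circle)")
    return chain


def measured_hp_cutoff(chain: FilterChain, grid_hz: float = 0.01) -> float:
    """Locate the high-pass stage's -3 dB point by scanning its response.

    Evaluates the designed discrete high-pass magnitude on a ``grid_hz``
    frequency grid and returns the frequency where gain first crosses
    1/sqrt(2) of the passband gain (linear interpolation between grid
    points).  Used to verify cutoff-preserving discretization.
    """
    nyq = chain.fs / 2.0
    freqs = np.arange(grid_hz, min(4.0 * chain.spec.hp_cutoff, nyq), grid_hz)
    _, h = sps.sosfreqz(chain.hp_sos, worN=freqs, fs=chain.fs)
    mag = np.abs(h)
    # passband gain: high-frequency asymptote of the high-pass stage
    f_pass = np.array([min(20.0 * chain.spec.hp_cutoff, 0.99 * nyq)])
    _, h_pass = sps.sosfreqz(chain.hp_sos, worN=f_pass, fs=chain.fs)
    target = np.abs(h_pass[0]) / np.sqrt(2.0)
    above = np.nonzero(mag >= target)[0]
    if len(above) == 0:
        raise ValueError("gain never reaches the -3 dB target on the scanned grid")
    i = above[0]
    if i == 0:
        return float(freqs[0])
    f0, f1, m0, m1 = freqs[i - 1], freqs[i], mag[i - 1], mag[i]
    return float(f0 + (target - m0) / (m1 - m0) * (f1 - f0))


def apply_bandlimit(rec: EmgRecording, spec: FilterSpec | None = None) -> EmgRecording:
    """Band-limit every channel of a recording independently.

    Labels and metadata are carried through unchanged; the output has the
    same length as the input (zero initial conditions, so the causal
    startup transient is part of the output, exactly as in hardware).
    """
    if spec is None:
        spec = FilterSpec()
    chain = design_chain(spec, rec.fs)
    filtered = np.column_stack(
        [chain.apply(rec.samples[:, c]) for c in range(rec.n_channels)]
    )
    return EmgRecording(
        filtered, rec.fs, channel_names=list(rec.channel_names),
        labels=None if rec.labels is None else list(rec.labels),
    )
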