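"""Signal-quality metrics for electrode comparison: burst detection, SNR,
Welch PSD and PSD correlation.

Muscle activity is detected where the moving-RMS envelope exceeds 6x the
standard deviation of a designated baseline (rest) segment; SNR is the
linear ratio of RMS amplitude during active vs inactive states.  Power
spectral density uses Welch's averaged-periodogram method, and spectra from
two electrodes are compared by Pearson correlation of their densities over
the filtered band (19-500 Hz).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps
from scipy.ndimage import uniform_filter1d

__all__ = [
    "DetectionConfig",
    "PsdEstimate",
    "moving_rms",
    "detect_activity",
    "compute_snr",
    "welch_psd",
    "psd_correlation",
]


@dataclass(frozen=True)
class DetectionConfig:
    """Activity-detection parameters.

    ``k`` = 6 reproduces the 6xSD-of-baseline rule; ``rms_window_ms`` is
    the moving-RMS horizon (a conventional sEMG envelope scale; the rule's
    original statement fixes only the threshold, not the horizon).
    """

    baseline_window_s: float = 10.0
    rms_window_ms: float = 100.0
    k: float = 6.0

    def __post_init__(self) -> None:
        if min(self.baseline_window_s, self.rms_window_ms, self.k) <= 0:
            raise ValueError("all detection parameters must be positive")


@dataclass(frozen=True)
class PsdEstimate:
    """A one-sided power spectral density estimate on an ascending Hz grid."""

    freqs: np.ndarray
    density: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        d = np.asarray(self.density, dtype=float)
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "density", d)
        if f.shape != d.shape or f.ndim != 1:
            raise ValueError("freqs and density must be matching 1-D arrays")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequency grid must be strictly ascending")
        if np.any(d < 0):
            raise ValueError("spectral density must be nonnegative")

    def total_power(self) -> float:
        """Trapezoid-integrated density; ~ variance for zero-mean input."""
        return float(np.trapezoid(self.density, self.freqs))


def moving_rms(x: np.ndarray, fs: float, window_ms: float = 100.0) -> np.ndarray:
    """Centered moving-RMS envelope, same length as the input."""
    x = np.asarray(x, dtype=float)
    w = max(1, int(round(window_ms / 1000.0 * fs)))
    return np.sqrt(uniform_filter1d(x**2, size=w, mode="nearest"))


def detect_activity(x: np.ndarray, fs: float,
                    cfg: DetectionConfig | None = None) -> np.ndarray:
    """Boolean per-sample mask: moving-RMS > k x SD(baseline segment).

    The baseline is the first ``baseline_window_s`` seconds, assumed rest;
    its raw-sample standard deviation sets the threshold, so the rule is
    invariant to rescaling the whole signal.
    """
    if cfg is None:
        cfg = DetectionConfig()
    x = np.asarray(x, dtype=float)
    nb = int(round(cfg.baseline_window_s * fs))
    if x.ndim != 1:
        raise ValueError("detect_activity expects a single channel")
    if nb >= len(x):
        raise ValueError(
            f"baseline window ({nb} samples) is not shorter than the signal "
            f"({len(x)} samples)"
        )
    threshold = cfg.k * float(np.std(x[:nb]))
    return moving_rms(x, fs, cfg.rms_window_ms) > threshold


def compute_snr(x: np.ndarray, active_mask: np.ndarray) -> float:
    """Linear SNR: RMS of active samples over RMS of inactive samples."""
    x = np.asarray(x, dtype=float)
    mask = np.asarray(active_mask, dtype=bool)
    if mask.shape != x.shape:
        raise ValueError("mask length must equal signal length")
    if mask.all() or not mask.any():
        raise ValueError("mask must contain both active and inactive samples")
    rms_active = np.sqrt(np.mean(x[mask] ** 2))
    rms_inactive = np.sqrt(np.mean(x[~mask] ** 2))
    if rms_inactive == 0:
        raise ValueError("inactive-state RMS is zero; SNR undefined")
    return float(rms_active / rms_inactive)


def welch_psd(x: np.ndarray, fs: float, segment_s: float = 1.0,
              overlap: float = 0.5, window: str = "hann") -> PsdEstimate:
    """One-sided Welch PSD with 1 s Hann segments at 50% overlap by default."""
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_s * fs))
    if nperseg > len(x):
        raise ValueError(
            f"segment of {nperseg} samples exceeds signal length {len(x)}"
        )
    noverlap = int(round(nperseg * overlap))
    freqs, density = sps.welch(
        x, fs=fs, window=window, nperseg=nperseg, noverlap=noverlap,
        detrend="constant",
    )
    return PsdEstimate(freqs, density, {
        "segment_s": segment_s, "overlap": overlap, "window": window,
    })


def psd_correlation(a: PsdEstimate, b: PsdEstimate,
                    band: tuple[float, float] = (19.0, 500.0)) -> float:
    """Pearson correlation of two PSDs over ``band`` (Hz).

    ``b`` is interpolated onto ``a``'s grid points inside the band;
    scale-invariant, so identical spectral shapes correlate at 1.0.
    """
    lo, hi = band
    for est, name in ((a, "a"), (b, "b")):
        if est.freqs[0] > lo or est.freqs[-1] < hi:
            raise ValueError(
                f"estimate {name} covers [{est.freqs[0]}, {est.freqs[-1]}] Hz, "
                f"not the requested band [{lo}, {hi}]"
            )
    sel = (a.freqs >= lo) & (a.freqs <= hi)
    if np.count_nonzero(sel) < 3:
        raise ValueError("fewer than 3 grid points inside the band")
    da = a.density[sel]
    db = np.interp(a.freqs[sel], b.freqs, b.density)
    return float(np.corrcoef(da, db)[0, 1])
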