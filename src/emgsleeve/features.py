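"""270 ms feature bins and the three time-domain sEMG features.

Each bin of N samples yields, per channel:

* WAMP (Willison amplitude) — the count of consecutive-sample differences
  whose magnitude strictly exceeds a threshold epsilon; a proxy for the
  number of motor-unit action potentials in the window.
* WL (waveform length) — the cumulative absolute sample-to-sample
  variation, a complexity measure that grows with contraction strength.
* RMS — root-mean-square amplitude, correlated with contraction force.

A 7-channel recording therefore yields 21-dimensional feature vectors,
ordered channel-major with (WAMP, WL, RMS) within each channel.  The
epsilon threshold is data-driven: 3x the median per-channel RMS of first
differences over the initial calibration rest, so it transfers across
amplitude scales.  Feature normalization divides each dimension by its
training-set maximum absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .config import BinConfig
from .gestures import GestureClass
from .io import EmgRecording

__all__ = [
    "FeatureVector",
    "segment_bins",
    "wamp",
    "waveform_length",
    "rms",
    "calibrate_wamp_threshold",
    "extract_features",
    "normalize_features",
    "apply_normalization",
    "feature_matrix",
    "write_features",
    "read_features",
]

FEATURE_NAMES = ("wamp", "wl", "rms")


@dataclass(frozen=True)
class FeatureVector:
    """One bin's features: 3 x n_channels values plus an optional label."""

    bin_index: int
    t_start: float
    values: np.ndarray
    label: GestureClass | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.values.ndim != 1 or len(self.values) % len(FEATURE_NAMES):
            raise ValueError("values must be a flat 3 x n_channels vector")


def segment_bins(rec: EmgRecording, cfg: BinConfig | None = None) -> list[np.ndarray]:
    """Cut a recording into consecutive fixed-width sample windows.

    Window length is ``floor(bin_ms / 1000 * fs)`` samples (270 at the
    default 270 ms and 1 kHz); the trailing partial window is discarded.
    With ``overlap`` > 0 windows advance by ``(1 - overlap)`` of their
    width (default: non-overlapping, matching firmware that stores exactly
    one bin at a time).
    """
    if cfg is None:
        cfg = BinConfig()
    if rec.n_samples == 0:
        raise ValueError("cannot segment an empty recording")
    width = int(np.floor(cfg.bin_ms / 1000.0 * rec.fs))
    if width < 1:
        raise ValueError(
            f"bin_ms={cfg.bin_ms} at fs={rec.fs} yields an empty window"
        )
    stride = max(1, int(round(width * (1.0 - cfg.overlap))))
    starts = range(0, rec.n_samples - width + 1, stride)
    return [rec.samples[s:s + width] for s in starts]


def wamp(x: np.ndarray, epsilon: float) -> int:
    """Willison amplitude: #{i : |x_i - x_{i-1}| > epsilon}, strict."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("wamp needs a 1-D window of at least 2 samples")
    return int(np.count_nonzero(np.abs(np.diff(x)) > epsilon))


def waveform_length(x: np.ndarray) -> float:
    """Waveform length: sum of |x_i - x_{i-1}| over the window."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("waveform_length needs a 1-D window of at least 2 samples")
    return float(np.sum(np.abs(np.diff(x))))


def rms(x: np.ndarray) -> float:
    """Root-mean-square amplitude: sqrt(mean(x_i^2))."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("rms of an empty window is undefined")
    return float(np.sqrt(np.mean(np.square(x))))


def calibrate_wamp_threshold(rec: EmgRecording, calibration_s: float = 10.0) -> float:
    """Data-driven WAMP epsilon from the initial calibration rest segment.

    epsilon = 3 x median over channels of the RMS of first differences in
    the first ``calibration_s`` seconds.  At rest the differences are
    baseline noise, so the threshold sits well above noise flicker yet far
    below burst excursions, whatever the amplitude scale.
    """
    n = min(rec.n_samples, int(round(calibration_s * rec.fs)))
    if n < 2:
        raise ValueError("calibration segment too short to estimate a threshold")
    seg = rec.samples[:n]
    diff_rms = np.sqrt(np.mean(np.diff(seg, axis=0) ** 2, axis=0))
    return float(3.0 * np.median(diff_rms))


def _bin_label(labels: list[GestureClass]) -> GestureClass:
    """Strict-majority label of a bin; ties and no-majority fall back to Rest."""
    counts: dict[GestureClass, int] = {}
    for g in labels:
        counts[g] = counts.get(g, 0) + 1
    best = max(counts, key=lambda g: counts[g])
    if counts[best] * 2 > len(labels):
        return best
    return GestureClass.Rest


def extract_features(rec: EmgRecording, cfg: BinConfig | None = None,
                     epsilon: float | None = None) -> list[FeatureVector]:
    """Compute one FeatureVector per bin of the recording.

    ``epsilon`` overrides the config's WAMP threshold; when both are unset
    it is calibrated from the recording's initial rest segment.  Values are
    channel-major, (WAMP, WL, RMS) within channel, channels in recording
    order.  Bins inherit the strict-majority per-sample label when the
    recording is labeled.
    """
    if cfg is None:
        cfg = BinConfig()
    if epsilon is None:
        epsilon = cfg.wamp_threshold
    if epsilon is None:
        epsilon = calibrate_wamp_threshold(rec)
    width = int(np.floor(cfg.bin_ms / 1000.0 * rec.fs))
    stride = max(1, int(round(width * (1.0 - cfg.overlap))))
    windows = segment_bins(rec, cfg)
    out: list[FeatureVector] = []
    for k, w in enumerate(windows):
        start = k * stride
        vals = np.empty(3 * rec.n_channels)
        for c in range(rec.n_channels):
            x = w[:, c]
            vals[3 * c] = wamp(x, epsilon)
            vals[3 * c + 1] = waveform_length(x)
            vals[3 * c + 2] = rms(x)
        label = None
        if rec.labels is not None:
            label = _bin_label(rec.labels[start:start + width])
        out.append(FeatureVector(k, start / rec.fs, vals, label))
    return out


def normalize_features(
    train_features: list[FeatureVector],
    apply_to: list[FeatureVector] | None = None,
) -> tuple[list[FeatureVector], np.ndarray]:
    """Max-abs normalization fit on the training set.

    Each feature dimension is divided by its training-set maximum absolute
    value; dimensions whose maximum is zero pass through unchanged.
    Returns the normalized features (``apply_to``, defaulting to the
    training set itself) and the per-dimension constants, which are stored
    with the model so online streaming reproduces training-time scaling.
    """
    if not train_features:
        raise ValueError("cannot fit normalization on an empty training set")
    X = np.stack([f.values for f in train_features])
    constants = np.max(np.abs(X), axis=0)
    targets = train_features if apply_to is None else apply_to
    return apply_normalization(targets, constants), constants


def apply_normalization(features: list[FeatureVector],
                        constants: np.ndarray) -> list[FeatureVector]:
    """Scale features by stored per-dimension constants (zero-max: identity)."""
    constants = np.asarray(constants, dtype=float)
    divisors = np.where(constants == 0.0, 1.0, constants)
    return [replace(f, values=f.values / divisors) for f in features]


def feature_matrix(
    features: list[FeatureVector],
) -> tuple[np.ndarray, list[GestureClass | None]]:
    """Stack features into an (n_bins, n_dims) matrix plus the label list."""
    if not features:
        raise ValueError("no feature vectors given")
    X = np.stack([f.values for f in features])
    return X, [f.label for f in features]


def _column_names(n_channels: int) -> list[str]:
    return [f"ch{c + 1}_{f}" for c in range(n_channels) for f in FEATURE_NAMES]


def write_features(features: list[FeatureVector], path: str | Path) -> None:
    """Write feature vectors as CSV: bin_index, t_start, features, label."""
    if not features:
        raise ValueError("no feature vectors to write")
    n_ch = len(features[0].values) // len(FEATURE_NAMES)
    data: dict[str, object] = {
        "bin_index": [f.bin_index for f in features],
        "t_start": [f.t_start for f in features],
    }
    stacked = np.stack([f.values for f in features])
    for j, name in enumerate(_column_names(n_ch)):
        data[name] = stacked[:, j]
    if any(f.label is not None for f in features):
        data["label"] = [f.label.name if f.label else GestureClass.Rest.name
                         for f in features]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def read_features(path: str | Path) -> list[FeatureVector]:
    """Read feature vectors from the CSV layout written by write_features."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"feature file not found: {path}")
    df = pd.read_csv(path)
    value_cols = [c for c in df.columns
                  if c not in ("bin_index", "t_start", "label")]
    out = []
    for _, row in df.iterrows():
        label = (GestureClass.from_name(str(row["label"]))
                 if "label" in df.columns else None)
        out.append(FeatureVector(
            int(row["bin_index"]), float(row["t_start"]),
            row[value_cols].to_numpy(dtype=float), label,
        ))
    return out
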