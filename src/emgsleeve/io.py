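"""Recording container and delimited-text readers/writers.

``EmgRecording`` is the pipeline's universal currency: an ``n_samples x
n_channels`` float matrix, a sampling rate, ordered channel names and an
optional per-sample gesture label sequence.  Recordings are serialized as
plain CSV (``time, ch1..chN[, label]``) so fixtures stay diff-able.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gestures import GestureClass

__all__ = ["EmgRecording", "read_recording", "write_recording"]


@dataclass
class EmgRecording:
    """A sampled multi-channel surface-EMG signal.

    Parameters
    ----------
    samples
        Amplitudes in arbitrary units emulating microvolts, shaped
        ``(n_samples, n_channels)``.
    fs
        Sampling rate in Hz (1000 for the hardware this emulates).
    channel_names
        Ordered channel identifiers; defaults to ``ch1..chN``.
    labels
        Optional per-sample :class:`GestureClass`, length ``n_samples``.
    """

    samples: np.ndarray
    fs: float
    channel_names: list[str] = field(default_factory=list)
    labels: list[GestureClass] | None = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.ndim != 2 or self.samples.shape[1] < 1:
            raise ValueError("samples must be a 2-D n_samples x n_channels array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if not self.channel_names:
            self.channel_names = [f"ch{i + 1}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.n_channels} channels"
            )
        if self.labels is not None:
            self.labels = list(self.labels)
            if len(self.labels) != self.n_samples:
                raise ValueError(
                    f"{len(self.labels)} labels for {self.n_samples} samples"
                )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, ``t_i = i / fs``."""
        return np.arange(self.n_samples) / self.fs

    def channel(self, name: str) -> np.ndarray:
        return self.samples[:, self.channel_names.index(name)]


def read_recording(path: str | Path, fs_override: float | None = None) -> EmgRecording:
    """Read a recording from a headered CSV file.

    The header names the columns; a ``time`` column (seconds) sets the
    sampling rate unless ``fs_override`` is given, and a ``label`` column is
    parsed to :class:`GestureClass` names.  Remaining columns are channels,
    kept in header order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"recording file not found: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # e.g. inconsistent row lengths
        raise ValueError(f"malformed recording file {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"recording file {path} has no data rows")

    cols = list(df.columns)
    labels = None
    if "label" in cols:
        try:
            labels = [GestureClass.from_name(str(v)) for v in df["label"]]
        except ValueError as exc:
            raise ValueError(f"bad label in {path}: {exc}") from exc
        cols.remove("label")

    fs = fs_override
    if "time" in cols:
        t = df["time"].to_numpy(dtype=float)
        if fs is None:
            if len(t) < 2:
                raise ValueError(
                    f"{path}: cannot infer fs from a single row; pass fs_override"
                )
            dt = np.diff(t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError(f"{path}: time column is not uniformly increasing")
            fs = 1.0 / dt[0]
        cols.remove("time")
    elif fs is None:
        raise ValueError(f"{path}: no time column and no fs_override given")

    if not cols:
        raise ValueError(f"{path}: no channel columns")
    try:
        samples = df[cols].to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric sample value in {path}: {exc}") from exc
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"non-finite sample value in {path}")
    return EmgRecording(samples, float(fs), channel_names=cols, labels=labels)


def write_recording(rec: EmgRecording, path: str | Path) -> None:
    """Write a recording as CSV: time (s), one column per channel, labels last.

    Labels are serialized as class names, not bit codes, so fixtures stay
    human-readable.
    """
    data: dict[str, np.ndarray | list[str]] = {"time": rec.times}
    for j, name in enumerate(rec.channel_names):
        data[name] = rec.samples[:, j]
    if rec.labels is not None:
        data["label"] = [g.name for g in rec.labels]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")
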