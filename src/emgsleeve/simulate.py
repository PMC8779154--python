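"""Synthetic labeled sEMG session generator.

Emulates a gesture-training session: 10 s of calibration rest, then each of
the seven finger-flexion poses held 5 s with 10 s rest in between, at 1 kHz
on 7 channels.  During a hold, each channel carries band-limited Gaussian
"interference-pattern" noise whose RMS is set by a per-gesture per-channel
activation matrix, ramped with a raised-cosine onset/offset envelope and
riding on white baseline sensor noise; optional sinusoids add sub-band
motion artifact and powerline pickup.  No motor-unit waveshape modeling is
attempted — the downstream features are amplitude-domain, so burst RMS
structure is what matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .config import SessionProtocol, SynthConfig
from .gestures import GestureClass
from .io import EmgRecording

__all__ = ["SubjectData", "label_timeline", "generate_session", "generate_subject"]

_CLASS_ORDER = list(GestureClass)


@dataclass(frozen=True)
class SubjectData:
    """Train/test split of one synthetic subject's sessions."""

    train: tuple[EmgRecording, ...]
    test: tuple[EmgRecording, ...]

    @property
    def sessions(self) -> tuple[EmgRecording, ...]:
        return self.train + self.test


def _segments(protocol: SessionProtocol, fs: float):
    """Yield (start_sample, end_sample, gesture, is_hold) per protocol segment."""
    edges = [("calibration", GestureClass.Rest, protocol.calibration_s)]
    for pose in protocol.pose_sequence:
        edges.append(("hold", pose, protocol.hold_s))
        edges.append(("rest", GestureClass.Rest, protocol.rest_s))
    start = 0
    t = 0.0
    for kind, g, dur in edges:
        t += dur
        end = round(t * fs)
        yield start, end, g, kind == "hold"
        start = end


def label_timeline(protocol: SessionProtocol, fs: float) -> list[GestureClass]:
    """Per-sample gesture labels; a function of the protocol alone."""
    labels: list[GestureClass] = []
    for start, end, g, _ in _segments(protocol, fs):
        labels.extend([g] * (end - start))
    return labels


def _raised_cosine_envelope(n: int, rise_samples: int) -> np.ndarray:
    """Unit-plateau envelope with raised-cosine ramps at both ends."""
    env = np.ones(n)
    r = min(rise_samples, n // 2)
    if r > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(1, r + 1) / r))
        env[:r] = ramp
        env[n - r:] = ramp[::-1]
    return env


def _band_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                fs: float) -> np.ndarray:
    """Unit-RMS Gaussian noise band-passed to ``band`` (zero-phase)."""
    lo, hi = band
    nyq = fs / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(
            f"burst band {band} incompatible with fs={fs} (Nyquist {nyq} Hz)"
        )
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    rms = np.sqrt(np.mean(x**2))
    return x / rms if rms > 0 else x


def generate_session(protocol: SessionProtocol, cfg: SynthConfig, fs: float,
                     seed: int | None = None) -> EmgRecording:
    """Generate one labeled session.

    The label timeline follows the protocol exactly; sample amplitudes add
    (i) a burst carrier whose RMS during the hold of gesture ``g`` on
    channel ``c`` is ``cfg.activation[g, c]`` shaped by the onset/offset
    envelope, (ii) white baseline noise of SD ``cfg.baseline_std``, and
    (iii) any configured artifact/powerline sinusoids.  Identical
    ``(protocol, cfg, fs, seed)`` give identical output.
    """
    if seed is None:
        seed = cfg.seed
    rng = np.random.default_rng(seed)
    labels = label_timeline(protocol, fs)
    n = len(labels)
    n_ch = cfg.n_channels
    rise = round(cfg.envelope_rise_ms / 1000.0 * fs)

    # per-sample, per-channel target burst RMS
    gain = np.zeros((n, n_ch))
    for start, end, g, is_hold in _segments(protocol, fs):
        if not is_hold:
            continue
        env = _raised_cosine_envelope(end - start, rise)
        gain[start:end] = env[:, None] * cfg.activation[_CLASS_ORDER.index(g)]

    samples = np.empty((n, n_ch))
    for c in range(n_ch):
        carrier = _band_noise(rng, n, cfg.band, fs)
        samples[:, c] = carrier * gain[:, c]
    samples += rng.standard_normal((n, n_ch)) * cfg.baseline_std

    t = np.arange(n) / fs
    if cfg.artifact_amp > 0:
        samples += (cfg.artifact_amp * np.sin(2 * np.pi * cfg.artifact_freq * t))[:, None]
    if cfg.powerline_amp > 0:
        samples += (cfg.powerline_amp * np.sin(2 * np.pi * cfg.powerline_freq * t))[:, None]

    return EmgRecording(samples, fs, labels=labels)


def generate_subject(protocol: SessionProtocol, cfg: SynthConfig, fs: float,
                     master_seed: int | None = None) -> SubjectData:
    """Generate ``protocol.n_datasets`` sessions split into train and test.

    Session ``i`` uses seed ``master_seed + i`` so the datasets are
    reproducible yet statistically distinct; the first ``train_fraction``
    sessions form the training set and the remainder the test set.
    """
    if protocol.n_datasets < 2:
        raise ValueError("n_datasets must be >= 2 to form a train/test split")
    if master_seed is None:
        master_seed = cfg.seed
    recs = [
        generate_session(protocol, cfg, fs, seed=master_seed + i)
        for i in range(protocol.n_datasets)
    ]
    k = protocol.train_fraction
    return SubjectData(train=tuple(recs[:k]), test=tuple(recs[k:]))
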