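"""Pipeline configuration: filter chain, binning, ANN training, simulation.

Every stage's parameters live in one dataclass with defaults matching the
hardware/firmware this package emulates: a 19 Hz second-order Butterworth
high-pass and 500 Hz third-order Bessel low-pass, 270 ms feature bins at
1 kHz, and ANN training at learning rate 1e-4, batch size 5, 6000 epochs
with 3 hidden neurons.  ``load_config`` reads a YAML file in which every
key is optional; missing keys take these defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import yaml

from .gestures import NON_REST_CLASSES, GestureClass

__all__ = [
    "FilterSpec",
    "BinConfig",
    "TrainConfig",
    "SessionProtocol",
    "SynthConfig",
    "PipelineConfig",
    "load_config",
    "default_activation_matrix",
]


@dataclass(frozen=True)
class FilterSpec:
    """Software equivalent of the analog front-end band-limiting chain.

    ``causal=True`` applies the filters forward-only, as analog hardware
    running ahead of the ADC must.
    """

    hp_cutoff: float = 19.0
    hp_order: int = 2
    hp_family: str = "butterworth"
    lp_cutoff: float = 500.0
    lp_order: int = 3
    lp_family: str = "bessel"
    causal: bool = True

    def __post_init__(self) -> None:
        if self.hp_cutoff <= 0:
            raise ValueError(f"hp_cutoff must be positive, got {self.hp_cutoff}")
        if self.lp_cutoff <= self.hp_cutoff:
            raise ValueError(
                f"lp_cutoff ({self.lp_cutoff}) must exceed hp_cutoff "
                f"({self.hp_cutoff})"
            )
        if self.hp_order < 1 or self.lp_order < 1:
            raise ValueError("filter orders must be >= 1")
        if self.hp_family.lower() != "butterworth":
            raise ValueError(f"unsupported high-pass family {self.hp_family!r}")
        if self.lp_family.lower() != "bessel":
            raise ValueError(f"unsupported low-pass family {self.lp_family!r}")


@dataclass(frozen=True)
class BinConfig:
    """Feature-bin segmentation parameters.

    ``wamp_threshold`` is the Willison-amplitude comparison threshold
    epsilon in signal amplitude units; ``None`` means "calibrate from the
    rest baseline" (see :func:`emgsleeve.features.calibrate_wamp_threshold`).
    """

    bin_ms: float = 270.0
    overlap: float = 0.0
    wamp_threshold: float | None = None
    label_rule: str = "majority"

    def __post_init__(self) -> None:
        if self.bin_ms <= 0:
            raise ValueError(f"bin_ms must be positive, got {self.bin_ms}")
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError(f"overlap must be in [0, 1), got {self.overlap}")
        if self.wamp_threshold is not None and self.wamp_threshold < 0:
            raise ValueError("wamp_threshold must be >= 0")
        if self.label_rule != "majority":
            raise ValueError(f"unknown label_rule {self.label_rule!r}")


@dataclass(frozen=True)
class TrainConfig:
    """Mini-batch gradient-descent hyperparameters for the ANN."""

    learning_rate: float = 1e-4
    batch_size: int = 5
    epochs: int = 6000
    n_hidden: int = 3
    loss: str = "mse"
    shuffle_each_epoch: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.n_hidden < 1:
            raise ValueError("n_hidden must be >= 1")
        if self.loss != "mse":
            raise ValueError(f"unsupported loss {self.loss!r}")


@dataclass(frozen=True)
class SessionProtocol:
    """Timing of one recording session.

    A session opens with ``calibration_s`` of rest (baseline data), then
    each pose in ``pose_sequence`` is held for ``hold_s`` followed by
    ``rest_s`` of rest.  One complete cycle of all poses forms one dataset;
    ``n_datasets`` are recorded per subject and the first ``train_fraction``
    of them are used for training, the remainder for testing.
    """

    calibration_s: float = 10.0
    hold_s: float = 5.0
    rest_s: float = 10.0
    pose_sequence: tuple[GestureClass, ...] = NON_REST_CLASSES
    n_datasets: int = 10
    train_fraction: int = 5

    def __post_init__(self) -> None:
        if min(self.calibration_s, self.hold_s, self.rest_s) <= 0:
            raise ValueError("all protocol durations must be positive")
        if len(self.pose_sequence) == 0:
            raise ValueError("pose_sequence must contain at least one pose")
        if GestureClass.Rest in self.pose_sequence:
            raise ValueError("pose_sequence must not contain Rest")
        if not 1 <= self.train_fraction < self.n_datasets:
            raise ValueError(
                f"train_fraction ({self.train_fraction}) must be in "
                f"[1, n_datasets) = [1, {self.n_datasets})"
            )

    @property
    def duration_s(self) -> float:
        return self.calibration_s + len(self.pose_sequence) * (
            self.hold_s + self.rest_s
        )


def default_activation_matrix(n_channels: int = 7) -> np.ndarray:
    """Synthetic per-gesture per-channel burst-RMS gains (arbitrary units).

    No published activation map exists for this electrode layout, so this is
    a constructed, well-separated stand-in: channel pairs are assigned to
    finger groups the way forearm flexor electrodes would be (ch1-2 index,
    ch3-4 middle, ch5-6 ring/pinky) and ch7 plays a shared digit flexor
    whose drive grows with the number of active groups.  Primary channels
    burst at 30 units with 20% crosstalk onto neighbouring groups; the rest
    row is zero.  Rows follow ``GestureClass`` declaration order.
    """
    if n_channels != 7:
        raise ValueError("the default activation matrix is defined for 7 channels")
    amp, cross = 30.0, 6.0
    group_of = {0: "I", 1: "I", 2: "M", 3: "M", 4: "R", 5: "R"}
    members = {
        GestureClass.Rest: set(),
        GestureClass.Index: {"I"},
        GestureClass.Middle: {"M"},
        GestureClass.RingPinky: {"R"},
        GestureClass.IndexMiddle: {"I", "M"},
        GestureClass.MiddleRingPinky: {"M", "R"},
        GestureClass.IndexRingPinky: {"I", "R"},
        GestureClass.AllFingers: {"I", "M", "R"},
    }
    neighbours = {"I": {"M"}, "M": {"I", "R"}, "R": {"M"}}
    act = np.zeros((len(GestureClass), n_channels))
    for i, g in enumerate(GestureClass):
        active = members[g]
        for ch in range(6):
            grp = group_of[ch]
            if grp in active:
                act[i, ch] = amp
            elif active & neighbours[grp]:
                act[i, ch] = cross
        act[i, 6] = 10.0 * len(active)
    return act


@dataclass(frozen=True)
class SynthConfig:
    """Signal model for the synthetic sEMG generator.

    Bursts are Gaussian noise band-passed to ``band`` Hz and scaled so
    their RMS matches the activation matrix entry, shaped by a raised-cosine
    onset/offset envelope; baseline sensor noise is white with standard
    deviation ``baseline_std``.  Optional deterministic sinusoids emulate
    sub-19 Hz motion artifact and 60 Hz powerline pickup.
    """

    activation: np.ndarray = field(default_factory=default_activation_matrix)
    band: tuple[float, float] = (20.0, 450.0)
    baseline_std: float = 2.0
    artifact_amp: float = 0.0
    artifact_freq: float = 8.0
    powerline_amp: float = 0.0
    powerline_freq: float = 60.0
    envelope_rise_ms: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        act = np.atleast_2d(np.asarray(self.activation, dtype=float))
        object.__setattr__(self, "activation", act)
        if act.shape[0] != len(GestureClass):
            raise ValueError(
                f"activation must have {len(GestureClass)} rows "
                f"(one per gesture class), got {act.shape[0]}"
            )
        if not np.all(np.isfinite(act)) or np.any(act < 0):
            raise ValueError("activation gains must be finite and nonnegative")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"bad burst band {self.band}")
        if self.baseline_std <= 0:
            raise ValueError("baseline_std must be positive")
        if self.envelope_rise_ms < 0:
            raise ValueError("envelope_rise_ms must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.activation.shape[1]


@dataclass(frozen=True)
class PipelineConfig:
    """Top-level bundle of every stage's configuration plus the global seed.

    The single seed is forwarded to every stochastic stage so a whole
    simulate/train/evaluate run is reproducible end to end.
    """

    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    bin_config: BinConfig = field(default_factory=BinConfig)
    ann_hyperparams: TrainConfig = field(default_factory=TrainConfig)
    synth_config: SynthConfig = field(default_factory=SynthConfig)
    protocol: SessionProtocol = field(default_factory=SessionProtocol)
    fs: float = 1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")


_SECTION_TYPES = {
    "filter_spec": FilterSpec,
    "bin_config": BinConfig,
    "ann_hyperparams": TrainConfig,
    "synth_config": SynthConfig,
    "protocol": SessionProtocol,
}


def _build_section(cls, mapping: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    if cls is SessionProtocol and "pose_sequence" in kwargs:
        kwargs["pose_sequence"] = tuple(
            GestureClass.from_name(n) for n in kwargs["pose_sequence"]
        )
    if cls is SynthConfig and "band" in kwargs:
        kwargs["band"] = tuple(kwargs["band"])
    return cls(**kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline configuration; missing keys take the defaults.

    The file may contain top-level ``fs`` and ``seed`` plus any of the
    sections ``filter_spec``, ``bin_config``, ``ann_hyperparams``,
    ``synth_config`` and ``protocol``, each a mapping of field overrides.
    An empty file yields the full default configuration.  Out-of-range
    values raise ``ValueError`` via the dataclass validators.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")

    unknown = set(raw) - set(_SECTION_TYPES) - {"fs", "seed"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")

    sections = {}
    for key, cls in _SECTION_TYPES.items():
        sub = raw.get(key, {}) or {}
        if not isinstance(sub, dict):
            raise ValueError(f"config section {key!r} must be a mapping")
        sections[key] = _build_section(cls, sub)

    cfg = PipelineConfig(
        fs=float(raw.get("fs", 1000.0)),
        seed=int(raw.get("seed", 0)),
        **sections,
    )
    # forward the global seed into stages that did not set their own
    if "seed" not in (raw.get("synth_config") or {}):
        cfg = replace(cfg, synth_config=replace(cfg.synth_config, seed=cfg.seed))
    if "seed" not in (raw.get("ann_hyperparams") or {}):
        cfg = replace(cfg, ann_hyperparams=replace(cfg.ann_hyperparams, seed=cfg.seed))
    return cfg
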