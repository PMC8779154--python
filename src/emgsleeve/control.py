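"""Online "testing mode": stream a recording through the pipeline in 270 ms
steps, decode gestures, issue hand commands, and score online trials.

This emulates the firmware loop of a myoelectric prosthesis controller: the
incoming signal is band-limited causally, chopped into consecutive bins,
featurized with the stored calibration (WAMP epsilon and normalization
constants), classified by the embedded ANN, thresholded to a 3-bit state
vector and decoded to a gesture — one actuation decision per bin, with no
debouncing between decisions.  Trial scoring follows a modal rule: the most
frequent non-rest decision inside a hold window (edges trimmed by one bin)
is the verdict for that trial.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ann import AnnModel, ConfusionMatrix, forward_batch, threshold_output
from .config import BinConfig, PipelineConfig, SessionProtocol
from .features import apply_normalization, extract_features
from .gestures import GestureClass, StateVector
from .io import EmgRecording
from .preprocess import apply_bandlimit

__all__ = [
    "GestureTimeline",
    "HandCommand",
    "decode_gesture",
    "gesture_to_command",
    "stream_classify",
    "hold_bin_windows",
    "score_online_trials",
    "write_timeline",
]


@dataclass(frozen=True)
class GestureTimeline:
    """One gesture decision per processed bin."""

    step_s: float
    decisions: tuple[GestureClass, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.step_s <= 0:
            raise ValueError("step_s must be positive")

    @property
    def codes(self) -> list[StateVector]:
        return [g.code for g in self.decisions]


@dataclass(frozen=True)
class HandCommand:
    """Boolean flags for the six servo actuators of the prosthetic hand."""

    thumb: bool = False
    index: bool = False
    middle: bool = False
    ring: bool = False
    pinky: bool = False
    thumb_abduction: bool = False


def decode_gesture(code: StateVector) -> GestureClass:
    """Exact state-vector table lookup; total over all 8 codes."""
    return GestureClass.from_code(code)


#: Finger-flexion map per gesture; thumb abduction stays false for all
#: classes (no trained pose involves it).  All Fingers flexes all five.
_COMMANDS: dict[GestureClass, HandCommand] = {
    GestureClass.Rest: HandCommand(),
    GestureClass.Index: HandCommand(index=True),
    GestureClass.Middle: HandCommand(middle=True),
    GestureClass.RingPinky: HandCommand(ring=True, pinky=True),
    GestureClass.IndexMiddle: HandCommand(index=True, middle=True),
    GestureClass.MiddleRingPinky: HandCommand(middle=True, ring=True, pinky=True),
    GestureClass.IndexRingPinky: HandCommand(index=True, ring=True, pinky=True),
    GestureClass.AllFingers: HandCommand(
        thumb=True, index=True, middle=True, ring=True, pinky=True
    ),
}


def gesture_to_command(g: GestureClass) -> HandCommand:
    """Flex exactly the fingers the gesture names; Rest disengages all."""
    return _COMMANDS[g]


def stream_classify(model: AnnModel, rec: EmgRecording,
                    cfg: PipelineConfig | None = None) -> GestureTimeline:
    """Run the online pipeline over a recording, one decision per bin.

    Causal band-limiting, consecutive bins, WAMP/WL/RMS with the model's
    stored epsilon, the model's stored normalization, forward pass,
    threshold, decode.  Deterministic given (model, recording, config), and
    bin-for-bin identical to offline evaluation on the same binning.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if model.norm_constants is None:
        raise ValueError("model has no stored normalization constants")
    width = int(np.floor(cfg.bin_config.bin_ms / 1000.0 * rec.fs))
    if rec.n_samples < width:
        raise ValueError(
            f"recording ({rec.n_samples} samples) is shorter than one bin "
            f"({width} samples)"
        )
    filtered = apply_bandlimit(rec, cfg.filter_spec)
    feats = extract_features(filtered, cfg.bin_config, epsilon=model.wamp_epsilon)
    feats = apply_normalization(feats, model.norm_constants)
    X = np.stack([f.values for f in feats])
    _, A = forward_batch(model, X)
    decisions = tuple(
        GestureClass.from_code(threshold_output(a)) for a in A
    )
    tag = hashlib.sha1(
        np.ascontiguousarray(model.w1).tobytes()
        + np.ascontiguousarray(model.w2).tobytes()
        + repr(cfg.bin_config).encode()
    ).hexdigest()[:12]
    return GestureTimeline(
        step_s=cfg.bin_config.bin_ms / 1000.0,
        decisions=decisions,
        provenance=f"model:{tag}",
    )


def hold_bin_windows(protocol: SessionProtocol, fs: float,
                     cfg: BinConfig | None = None,
                     ) -> list[tuple[int, int, GestureClass]]:
    """Bin-index ranges [start, end) fully inside each pose hold.

    Derived from the protocol timing alone, so trial scoring knows where
    each hold lies on the bin grid used by ``stream_classify``.
    """
    if cfg is None:
        cfg = BinConfig()
    width = int(np.floor(cfg.bin_ms / 1000.0 * fs))
    windows = []
    t = protocol.calibration_s
    for pose in protocol.pose_sequence:
        s0 = round(t * fs)
        s1 = round((t + protocol.hold_s) * fs)
        first = int(np.ceil(s0 / width))
        last = int(np.floor(s1 / width))  # bins [first, last) lie inside
        windows.append((first, last, pose))
        t += protocol.hold_s + protocol.rest_s
    return windows


def score_online_trials(timeline: GestureTimeline,
                        hold_windows: list[tuple[int, int, GestureClass]],
                        ) -> ConfusionMatrix:
    """One verdict per hold window: modal non-rest decision vs true pose.

    The first and last bin of each window are trimmed (transition bins);
    the most frequent non-rest decision among the rest is the verdict, with
    ties broken by earliest occurrence.  A window with no non-rest decision
    at all is scored as Rest (a missed trial).
    """
    cm = ConfusionMatrix()
    for start, end, true_g in hold_windows:
        if end - start < 3:
            raise ValueError(
                f"hold window [{start}, {end}) has fewer than 3 bins"
            )
        inner = timeline.decisions[start + 1:end - 1]
        votes: dict[GestureClass, int] = {}
        for g in inner:
            if g is not GestureClass.Rest:
                votes[g] = votes.get(g, 0) + 1
        if votes:
            best = max(votes.values())
            verdict = next(g for g in inner if votes.get(g) == best)
        else:
            verdict = GestureClass.Rest
        cm.add(true_g, verdict)
    return cm


def write_timeline(timeline: GestureTimeline, path) -> None:
    """Write a decision timeline as CSV: t_start, class, bits a/b/c."""
    rows = {
        "t_start": [i * timeline.step_s for i in range(len(timeline.decisions))],
        "gesture": [g.name for g in timeline.decisions],
        "a": [g.code[0] for g in timeline.decisions],
        "b": [g.code[1] for g in timeline.decisions],
        "c": [g.code[2] for g in timeline.decisions],
    }
    pd.DataFrame(rows).to_csv(path, index=False)
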