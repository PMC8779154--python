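"""End-to-end convenience layer: subject-level training and evaluation.

Mirrors the study workflow: several recorded sessions per subject, the
first half used to fit the WAMP threshold, the feature normalization and
the ANN; the second half held out for offline evaluation and for online
streaming through the control loop.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ann import AnnModel, ConfusionMatrix, evaluate, init_model, train
from .config import PipelineConfig
from .features import (FeatureVector, apply_normalization,
                       calibrate_wamp_threshold, extract_features,
                       normalize_features)
from .io import EmgRecording
from .preprocess import apply_bandlimit
from .simulate import SubjectData, generate_subject

__all__ = ["SubjectResult", "featurize_session", "train_subject_model",
           "run_subject_study"]


@dataclass
class SubjectResult:
    """Everything a subject-level train/evaluate run produces."""

    model: AnnModel
    loss_history: np.ndarray
    train_features: list[FeatureVector]   # normalized
    test_features: list[FeatureVector]    # normalized
    test_sessions: tuple[EmgRecording, ...]
    offline_cm: ConfusionMatrix
    config: PipelineConfig


def featurize_session(rec: EmgRecording, cfg: PipelineConfig,
                      epsilon: float) -> list[FeatureVector]:
    """Band-limit one session causally and extract labeled feature bins."""
    filtered = apply_bandlimit(rec, cfg.filter_spec)
    return extract_features(filtered, cfg.bin_config, epsilon=epsilon)


def train_subject_model(
    train_sessions: list[EmgRecording] | tuple[EmgRecording, ...],
    cfg: PipelineConfig | None = None,
) -> tuple[AnnModel, np.ndarray, list[FeatureVector], float]:
    """Fit epsilon, normalization and the ANN from training sessions.

    The WAMP threshold is calibrated once, from the initial rest segment of
    the first training session (band-limited), and reused for every session
    and later for online streaming — the constants travel with the model.
    Returns (trained model, loss history, normalized training features,
    epsilon).
    """
    if cfg is None:
        cfg = PipelineConfig()
    if not train_sessions:
        raise ValueError("no training sessions given")
    first_filtered = apply_bandlimit(train_sessions[0], cfg.filter_spec)
    epsilon = (cfg.bin_config.wamp_threshold
               if cfg.bin_config.wamp_threshold is not None
               else calibrate_wamp_threshold(first_filtered,
                                             cfg.protocol.calibration_s))
    feats: list[FeatureVector] = []
    for rec in train_sessions:
        feats.extend(featurize_session(rec, cfg, epsilon))
    normalized, constants = normalize_features(feats)
    model = init_model(
        seed=cfg.seed,
        n_inputs=len(normalized[0].values),
        n_hidden=cfg.ann_hyperparams.n_hidden,
    )
    train_cfg = replace(cfg.ann_hyperparams, seed=cfg.seed)
    model, history = train(model, normalized, train_cfg)
    model.norm_constants = constants
    model.wamp_epsilon = epsilon
    return model, history, normalized, epsilon


def run_subject_study(cfg: PipelineConfig | None = None,
                      subject: SubjectData | None = None) -> SubjectResult:
    """Simulate (or accept) one subject, train, and evaluate offline.

    With no ``subject`` given, sessions are synthesized from the config's
    protocol and signal model using the config seed.
    """
    if cfg is None:
        cfg = PipelineConfig()
    if subject is None:
        subject = generate_subject(cfg.protocol, cfg.synth_config, cfg.fs,
                                   master_seed=cfg.seed)
    model, history, train_feats, epsilon = train_subject_model(
        list(subject.train), cfg
    )
    test_feats: list[FeatureVector] = []
    for rec in subject.test:
        test_feats.extend(featurize_session(rec, cfg, epsilon))
    test_feats = apply_normalization(test_feats, model.norm_constants)
    cm = evaluate(model, test_feats)
    return SubjectResult(
        model=model, loss_history=history, train_features=train_feats,
        test_features=test_feats, test_sessions=subject.test,
        offline_cm=cm, config=cfg,
    )
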