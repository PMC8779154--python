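"""From-scratch feedforward ANN for 8-way gesture classification.

A 21-3-3 network (21 features in, one hidden layer of 3 neurons, 3 output
neurons) with logistic-sigmoid activations on both layers, trained by
back-propagation with mini-batch gradient descent on the squared error
between the output activations and the gesture's 3-bit target code.  The
objective follows the classical backprop formulation: per-sample loss
``1/2 * sum_k (a_k - t_k)^2``, with mini-batch gradients summed (not
averaged) over the batch, so the step size per sample is independent of
batch size and output width.  The 3-bit code makes the output layer a bank
of three independent soft bits; thresholding each at 0.5 and decoding
through the state-vector table turns any output into exactly one of the
eight gesture classes.

Everything here is written out explicitly in numpy — forward pass, deltas,
weight updates and a central-finite-difference gradient checker that serves
as the module's correctness oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import TrainConfig
from .features import FeatureVector
from .gestures import GestureClass, StateVector

__all__ = [
    "AnnModel",
    "ConfusionMatrix",
    "init_model",
    "forward",
    "forward_batch",
    "threshold_output",
    "predict",
    "train",
    "batch_loss",
    "mse",
    "gradient_check",
    "evaluate",
    "save_model",
    "load_model",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # split by sign to avoid overflow in exp for large |z|
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class AnnModel:
    """Weights, biases and feature-normalization constants of the network."""

    w1: np.ndarray  # (n_hidden, n_inputs)
    b1: np.ndarray  # (n_hidden,)
    w2: np.ndarray  # (n_outputs, n_hidden)
    b2: np.ndarray  # (n_outputs,)
    norm_constants: np.ndarray | None = None
    wamp_epsilon: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("w1", "b1", "w2", "b2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        h, n_in = self.w1.shape
        n_out, h2 = self.w2.shape
        if h2 != h or self.b1.shape != (h,) or self.b2.shape != (n_out,):
            raise ValueError("inconsistent layer shapes")
        if not all(np.all(np.isfinite(getattr(self, n)))
                   for n in ("w1", "b1", "w2", "b2")):
            raise ValueError("non-finite network parameters")
        if self.norm_constants is not None:
            self.norm_constants = np.asarray(self.norm_constants, dtype=float)
            if self.norm_constants.shape != (n_in,):
                raise ValueError(
                    f"normalization constants shape {self.norm_constants.shape} "
                    f"does not match {n_in} inputs"
                )

    @property
    def layer_sizes(self) -> tuple[int, int, int]:
        return (self.w1.shape[1], self.w1.shape[0], self.w2.shape[0])

    def copy(self) -> "AnnModel":
        return AnnModel(
            self.w1.copy(), self.b1.copy(), self.w2.copy(), self.b2.copy(),
            None if self.norm_constants is None else self.norm_constants.copy(),
            self.wamp_epsilon, self.seed,
        )


def init_model(seed: int = 0, n_inputs: int = 21, n_hidden: int = 3,
               n_outputs: int = 3) -> AnnModel:
    """Glorot-uniform initialization: weights in [-r, r], r = sqrt(6/(fan_in+fan_out)),
    biases zero.  Reproducible per seed."""
    rng = np.random.default_rng(seed)
    r1 = np.sqrt(6.0 / (n_inputs + n_hidden))
    r2 = np.sqrt(6.0 / (n_hidden + n_outputs))
    return AnnModel(
        w1=rng.uniform(-r1, r1, size=(n_hidden, n_inputs)),
        b1=np.zeros(n_hidden),
        w2=rng.uniform(-r2, r2, size=(n_outputs, n_hidden)),
        b2=np.zeros(n_outputs),
        seed=seed,
    )


def forward_batch(model: AnnModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hidden and output activations for a batch, X shaped (n, n_inputs)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"input has {X.shape[1]} features, model expects {model.layer_sizes[0]}"
        )
    H = _sigmoid(X @ model.w1.T + model.b1)
    A = _sigmoid(H @ model.w2.T + model.b2)
    return H, A


def forward(model: AnnModel, x: np.ndarray) -> np.ndarray:
    """Output activations sigmoid(W2 sigmoid(W1 x + b1) + b2), each in (0,1)."""
    _, A = forward_batch(model, np.atleast_2d(x))
    return A[0]


def threshold_output(activations: np.ndarray) -> StateVector:
    """Quantize output activations to a state vector: bit = 1 iff a > 0.5.

    The strict inequality sends the degenerate all-0.5 output to (0,0,0),
    i.e. fail-safe to Rest.
    """
    a = np.asarray(activations, dtype=float)
    if a.shape != (3,):
        raise ValueError("expected a 3-vector of activations")
    return tuple(int(v > 0.5) for v in a)  # type: ignore[return-value]


def predict(model: AnnModel, x: np.ndarray) -> GestureClass:
    """forward -> threshold -> decode; total over all inputs."""
    return GestureClass.from_code(threshold_output(forward(model, x)))


def batch_loss(model: AnnModel, X: np.ndarray, T: np.ndarray) -> float:
    """Training objective: 1/2 sum over samples and bits of (a - t)^2."""
    _, A = forward_batch(model, X)
    return float(0.5 * np.sum((A - np.atleast_2d(T)) ** 2))


def mse(model: AnnModel, X: np.ndarray, T: np.ndarray) -> float:
    """Monitoring metric: mean over samples and bits of (a - t)^2."""
    _, A = forward_batch(model, X)
    return float(np.mean((A - np.atleast_2d(T)) ** 2))


def _targets(labels: list[GestureClass]) -> np.ndarray:
    for g in labels:
        if not isinstance(g, GestureClass):
            raise ValueError(f"label {g!r} has no state-vector code")
    return np.array([g.code for g in labels], dtype=float)


def _gradients(model: AnnModel, X: np.ndarray, T: np.ndarray):
    """Back-propagated gradients of batch_loss w.r.t. all parameters."""
    H, A = forward_batch(model, X)
    dA = A - T                              # dL/dA for L = 1/2 sum (A-T)^2
    dZ2 = dA * A * (1.0 - A)                # sigmoid'
    gw2 = dZ2.T @ H
    gb2 = dZ2.sum(axis=0)
    dH = dZ2 @ model.w2
    dZ1 = dH * H * (1.0 - H)
    gw1 = dZ1.T @ X
    gb1 = dZ1.sum(axis=0)
    return gw1, gb1, gw2, gb2


def train(model: AnnModel, features: list[FeatureVector] | None,
          cfg: TrainConfig | None = None,
          X: np.ndarray | None = None,
          labels: list[GestureClass] | None = None,
          ) -> tuple[AnnModel, np.ndarray]:
    """Mini-batch gradient descent on the 3-bit-code squared error.

    Accepts either labeled ``features`` or an explicit ``(X, labels)``
    pair.  Samples are reshuffled each epoch with a generator seeded from
    the config, so identical configs give identical loss histories.
    Returns the trained model (the input model is not mutated) and the
    per-epoch mean of the per-sample MSE monitoring metric, length
    ``cfg.epochs``.
    """
    if cfg is None:
        cfg = TrainConfig()
    if features is not None:
        if not features:
            raise ValueError("empty training set")
        X = np.stack([f.values for f in features])
        labels = [f.label for f in features]  # type: ignore[misc]
        if any(l is None for l in labels):
            raise ValueError("all training feature vectors must be labeled")
    if X is None or labels is None:
        raise ValueError("provide either features or (X, labels)")
    X = np.asarray(X, dtype=float)
    T = _targets(labels)
    if len(X) != len(T):
        raise ValueError("feature/label length mismatch")

    m = model.copy()
    rng = np.random.default_rng(cfg.seed)
    n = len(X)
    lr = cfg.learning_rate
    history = np.empty(cfg.epochs)
    w1, b1, w2, b2 = m.w1, m.b1, m.w2, m.b2
    for epoch in range(cfg.epochs):
        order = rng.permutation(n) if cfg.shuffle_each_epoch else np.arange(n)
        epoch_loss = 0.0
        n_batches = 0
        for s in range(0, n, cfg.batch_size):
            idx = order[s:s + cfg.batch_size]
            Xb, Tb = X[idx], T[idx]
            # forward
            H = _sigmoid(Xb @ w1.T + b1)
            A = _sigmoid(H @ w2.T + b2)
            diff = A - Tb
            epoch_loss += float(np.mean(diff**2))
            n_batches += 1
            # backward: gradients of 1/2 sum (a-t)^2, summed over the batch
            dZ2 = diff * A * (1.0 - A)
            dZ1 = (dZ2 @ w2) * H * (1.0 - H)
            w2 -= lr * (dZ2.T @ H)
            b2 -= lr * dZ2.sum(axis=0)
            w1 -= lr * (dZ1.T @ Xb)
            b1 -= lr * dZ1.sum(axis=0)
        history[epoch] = epoch_loss / n_batches
    return m, history


def gradient_check(model: AnnModel, x: np.ndarray, target: np.ndarray,
                   step: float = 1e-5) -> float:
    """Max relative error between analytic and central-difference gradients.

    The oracle for the back-propagation code: perturbs every parameter by
    +/-``step``, differences the loss, and compares with the analytic
    gradient.  Relative error uses max(|analytic|, |numeric|, 1e-8) in the
    denominator so near-zero gradients do not blow it up.
    """
    X = np.atleast_2d(np.asarray(x, dtype=float))
    T = np.atleast_2d(np.asarray(target, dtype=float))
    analytic = _gradients(model, X, T)
    m = model.copy()
    params = [m.w1, m.b1, m.w2, m.b2]
    worst = 0.0
    for p, ga in zip(params, analytic):
        it = np.nditer(p, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = p[ix]
            p[ix] = orig + step
            lp = batch_loss(m, X, T)
            p[ix] = orig - step
            lm = batch_loss(m, X, T)
            p[ix] = orig
            gn = (lp - lm) / (2.0 * step)
            denom = max(abs(ga[ix]), abs(gn), 1e-8)
            worst = max(worst, abs(ga[ix] - gn) / denom)
    return worst


@dataclass
class ConfusionMatrix:
    """Class-by-class counts (rows = true, columns = predicted)."""

    classes: list[GestureClass] = field(default_factory=lambda: list(GestureClass))
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        k = len(self.classes)
        if self.counts is None:
            self.counts = np.zeros((k, k), dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (k, k) or np.any(self.counts < 0):
            raise ValueError("counts must be a nonnegative k x k matrix")

    def add(self, true: GestureClass, predicted: GestureClass) -> None:
        self.counts[self.classes.index(true), self.classes.index(predicted)] += 1

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def percentages(self) -> np.ndarray:
        """Row-normalized percentages; all-zero rows stay zero."""
        sums = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(sums > 0, 100.0 * self.counts / sums, 0.0)
        return pct

    def accuracy(self) -> float:
        """Overall fraction of correct classifications."""
        if self.total == 0:
            raise ValueError("empty confusion matrix")
        return float(np.trace(self.counts) / self.total)

    def class_accuracy(self, g: GestureClass) -> float:
        """Diagonal fraction for one true class."""
        i = self.classes.index(g)
        row = self.counts[i].sum()
        if row == 0:
            raise ValueError(f"no test samples with true class {g.name}")
        return float(self.counts[i, i] / row)

    def to_frame(self):
        import pandas as pd
        names = [g.name for g in self.classes]
        return pd.DataFrame(self.counts, index=names, columns=names)


def evaluate(model: AnnModel, features: list[FeatureVector]) -> ConfusionMatrix:
    """Confusion matrix of forward -> threshold -> decode on labeled features."""
    if not features:
        raise ValueError("empty test set")
    cm = ConfusionMatrix()
    X = np.stack([f.values for f in features])
    _, A = forward_batch(model, X)
    for f, a in zip(features, A):
        if f.label is None:
            raise ValueError("all test feature vectors must be labeled")
        cm.add(f.label, GestureClass.from_code(threshold_output(a)))
    return cm


def save_model(model: AnnModel, path: str | Path) -> None:
    """Serialize the model (weights + normalization constants) as JSON."""
    if model.norm_constants is None:
        raise ValueError(
            "model has no normalization constants; fit them before saving "
            "so online streaming can reproduce training-time scaling"
        )
    doc = {
        "layer_sizes": list(model.layer_sizes),
        "w1": model.w1.tolist(),
        "b1": model.b1.tolist(),
        "w2": model.w2.tolist(),
        "b2": model.b2.tolist(),
        "norm_constants": model.norm_constants.tolist(),
        "wamp_epsilon": model.wamp_epsilon,
        "seed": model.seed,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model(path: str | Path) -> AnnModel:
    """Load a JSON model file; validates shapes and required blocks."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed model file {path}: {exc}") from exc
    required = {"layer_sizes", "w1", "b1", "w2", "b2", "norm_constants"}
    missing = required - set(doc)
    if missing:
        raise ValueError(f"model file {path} missing blocks: {sorted(missing)}")
    model = AnnModel(
        w1=np.array(doc["w1"]), b1=np.array(doc["b1"]),
        w2=np.array(doc["w2"]), b2=np.array(doc["b2"]),
        norm_constants=np.array(doc["norm_constants"]),
        wamp_epsilon=(None if doc.get("wamp_epsilon") is None
                      else float(doc["wamp_epsilon"])),
        seed=int(doc.get("seed", 0)),
    )
    if list(model.layer_sizes) != list(doc["layer_sizes"]):
        raise ValueError(
            f"declared layer_sizes {doc['layer_sizes']} do not match "
            f"matrix shapes {model.layer_sizes}"
        )
    return model
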