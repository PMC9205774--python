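"""Weakly supervised tile classifier.

The trainable unit of the pipeline: a four-layer fully connected network
(512x256, 256x256, 256x128, 128x2 with ReLU activations) applied to tile
feature vectors, where every tile inherits the label of its patient.
Class imbalance is handled by random undersampling of tile rows before
training, and patient-level predictions are obtained by aggregating tile
class-1 probabilities (arithmetic mean by default).

The network and its optimizer are implemented directly on numpy arrays so
that a full training run is a pure, bit-reproducible function of
(data, seed, hyperparameters) — a property the decentralized-training
equivalence checks rely on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "PatientBag",
    "ModelParams",
    "Hyperparams",
    "ConfigurationError",
    "LAYER_WIDTHS",
    "balance_by_undersampling",
    "init_model",
    "train_steps",
    "train_full",
    "epoch_order",
    "predict_tiles",
    "patient_score",
    "data_fingerprint",
]

#: hidden/output widths of the classification head; the input width is the
#: feature dimension (512 by default).
LAYER_WIDTHS = (256, 256, 128, 2)


class ConfigurationError(ValueError):
    """Raised for invalid model / training configuration."""


@dataclass(frozen=True)
class PatientBag:
    """One patient's weak label and its bag of tile feature vectors.

    The bag is the unit of train/test splitting and of patient-level
    evaluation; ``label`` is 1 for the altered class (e.g. BRAF-mut or
    MSI/dMMR) and 0 otherwise.
    """

    patient_id: str
    cohort_id: str
    label: int
    features: np.ndarray  # (n_tiles, feature_dim)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        feats = np.asarray(self.features, dtype=np.float64)
        if feats.ndim != 2 or feats.shape[0] < 1:
            raise ValueError("features must be a non-empty 2-D array")
        object.__setattr__(self, "features", feats)


@dataclass
class ModelParams:
    """Ordered weight/bias tensors of the tile classifier.

    ``weights[i]`` has shape (fan_in, fan_out); ``biases[i]`` has shape
    (fan_out,). This is the object that is trained locally, merged at sync
    events, and checkpointed.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def n_params(self) -> int:
        return sum(w.size for w in self.weights) + sum(b.size for b in self.biases)

    @property
    def input_dim(self) -> int:
        return self.weights[0].shape[0]

    def copy(self) -> "ModelParams":
        return ModelParams([w.copy() for w in self.weights], [b.copy() for b in self.biases])

    def flatten(self) -> np.ndarray:
        """Concatenate all tensors into one flat float64 vector."""
        parts = []
        for w, b in zip(self.weights, self.biases):
            parts.append(w.ravel())
            parts.append(b.ravel())
        return np.concatenate(parts)

    def unflatten(self, vec: np.ndarray) -> "ModelParams":
        """Inverse of :meth:`flatten`, using self's shapes as the manifest."""
        vec = np.asarray(vec, dtype=np.float64)
        if vec.size != self.n_params:
            raise ValueError(f"expected {self.n_params} values, got {vec.size}")
        weights, biases, pos = [], [], 0
        for w, b in zip(self.weights, self.biases):
            weights.append(vec[pos : pos + w.size].reshape(w.shape).copy())
            pos += w.size
            biases.append(vec[pos : pos + b.size].reshape(b.shape).copy())
            pos += b.size
        return ModelParams(weights, biases)

    def digest(self) -> str:
        """SHA-256 over the flat parameter vector; used in sync-event logs."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.flatten()).tobytes())
        return h.hexdigest()

    def validate(self) -> None:
        for w, b in zip(self.weights, self.biases):
            if not (np.isfinite(w).all() and np.isfinite(b).all()):
                raise ValueError("non-finite model parameters")


@dataclass(frozen=True)
class Hyperparams:
    """Training hyperparameters shared by local, merged and swarm trainers.

    Defaults (batch 64, learning rate 0.2, plain SGD, 5 base epochs) are
    recorded in every run manifest. Plain SGD is the default so the
    swarm-equivalence oracle is exact (an adaptive Adam optimizer is
    available behind the same switch); batch size and learning rate are
    chosen so that desk-scale runs reach near-convergence within the five
    base epochs, the regime in which early swarm checkpoints are
    meaningful.
    """

    batch_size: int = 64
    learning_rate: float = 0.2
    optimizer: str = "sgd"  # "sgd" (plain) or "adaptive" (Adam)
    epochs_base: int = 5

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if not self.learning_rate > 0 and self.learning_rate != 0.0:
            raise ConfigurationError("learning_rate must be >= 0")
        if self.optimizer not in ("sgd", "adaptive"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


# ---------------------------------------------------------------------------
# data handling


def data_fingerprint(X: np.ndarray, y: np.ndarray) -> int:
    """Stable 63-bit fingerprint of a tile table (used to derive shuffles)."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.asarray(X, dtype=np.float64)).tobytes())
    h.update(np.ascontiguousarray(np.asarray(y, dtype=np.int64)).tobytes())
    return int.from_bytes(h.digest()[:8], "little") >> 1


def balance_by_undersampling(
    X: np.ndarray, y: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Equalize the two tile classes by random undersampling of the majority.

    Returns a subset of the input rows (original order preserved) in which
    both classes have exactly ``min(class counts)`` tiles. Deterministic
    under ``seed``. Raises if a class is absent — the cohort is then
    unusable for this target.
    """
    y = np.asarray(y)
    X = np.asarray(X)
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    if len(idx0) == 0 or len(idx1) == 0:
        raise ValueError("both classes must be present for undersampling")
    n = min(len(idx0), len(idx1))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xBA1A]))
    keep0 = idx0 if len(idx0) == n else np.sort(rng.choice(idx0, size=n, replace=False))
    keep1 = idx1 if len(idx1) == n else np.sort(rng.choice(idx1, size=n, replace=False))
    keep = np.sort(np.concatenate([keep0, keep1]))
    return X[keep], y[keep]


def bags_to_tile_table(bags: Sequence[PatientBag]) -> tuple[np.ndarray, np.ndarray]:
    """Stack bag tiles into (X, y); each tile inherits its patient's label."""
    X = np.concatenate([b.features for b in bags], axis=0)
    y = np.concatenate([np.full(b.features.shape[0], b.label, dtype=np.int64) for b in bags])
    return X, y


# ---------------------------------------------------------------------------
# model


def init_model(seed: int, feature_dim: int = 512) -> ModelParams:
    """He-normal initialization of the four-layer network; zero biases."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x1217]))
    dims = (feature_dim,) + LAYER_WIDTHS
    weights, biases = [], []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return ModelParams(weights, biases)


def _forward(model: ModelParams, X: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Forward pass; returns logits and the post-activation cache."""
    acts = [X]
    h = X
    last = len(model.weights) - 1
    for i, (w, b) in enumerate(zip(model.weights, model.biases)):
        h = h @ w + b
        if i < last:
            h = np.maximum(h, 0.0)
            acts.append(h)
    return h, acts


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(model: ModelParams, X: np.ndarray, y: np.ndarray) -> float:
    """Mean cross-entropy of tile-level softmax outputs."""
    logits, _ = _forward(model, np.asarray(X, dtype=np.float64))
    p = _softmax(logits)
    return float(-np.mean(np.log(p[np.arange(len(y)), np.asarray(y, dtype=int)] + 1e-300)))


def _gradients(
    model: ModelParams, X: np.ndarray, y: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Backprop of the mean cross-entropy over the batch."""
    n = X.shape[0]
    logits, acts = _forward(model, X)
    delta = _softmax(logits)
    delta[np.arange(n), y] -= 1.0
    delta /= n
    gw: list[np.ndarray] = [None] * len(model.weights)  # type: ignore[list-item]
    gb: list[np.ndarray] = [None] * len(model.biases)  # type: ignore[list-item]
    for i in range(len(model.weights) - 1, -1, -1):
        gw[i] = acts[i].T @ delta
        gb[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * (acts[i] > 0)
    return gw, gb


class _AdamState:
    """Per-trainer Adam moment buffers (plain SGD keeps no state)."""

    def __init__(self, model: ModelParams, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.m = [np.zeros_like(w) for w in model.weights] + [np.zeros_like(b) for b in model.biases]
        self.v = [np.zeros_like(a) for a in self.m]
        self.t = 0
        self.beta1, self.beta2, self.eps = beta1, beta2, eps


def _apply_step(model: ModelParams, gw, gb, hp: Hyperparams, adam: _AdamState | None) -> None:
    lr = hp.learning_rate
    if hp.optimizer == "sgd":
        for i in range(len(model.weights)):
            model.weights[i] -= lr * gw[i]
            model.biases[i] -= lr * gb[i]
        return
    assert adam is not None
    adam.t += 1
    grads = list(gw) + list(gb)
    params = list(model.weights) + list(model.biases)
    bc1 = 1.0 - adam.beta1**adam.t
    bc2 = 1.0 - adam.beta2**adam.t
    for p, g, m, v in zip(params, grads, adam.m, adam.v):
        m *= adam.beta1
        m += (1 - adam.beta1) * g
        v *= adam.beta2
        v += (1 - adam.beta2) * g * g
        p -= lr * (m / bc1) / (np.sqrt(v / bc2) + adam.eps)


def train_steps(
    model: ModelParams,
    batches: Iterable[tuple[np.ndarray, np.ndarray]],
    k: int,
    hp: Hyperparams,
    adam_state: _AdamState | None = None,
) -> ModelParams:
    """Perform exactly ``k`` optimizer steps on successive batches.

    Pure with respect to ``model`` (a new ModelParams is returned); ``k=0``
    returns an identical copy. Each batch is a (features, tile_labels) pair
    with the patient label attached to every tile.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    out = model.copy()
    if k == 0:
        return out
    if hp.optimizer == "adaptive" and adam_state is None:
        adam_state = _AdamState(out)
    it = iter(batches)
    for _ in range(k):
        try:
            Xb, yb = next(it)
        except StopIteration:
            raise ValueError("batch stream exhausted before k steps") from None
        Xb = np.asarray(Xb, dtype=np.float64)
        yb = np.asarray(yb, dtype=np.int64)
        if Xb.shape[0] == 0:
            raise ValueError("empty batch")
        gw, gb = _gradients(out, Xb, yb)
        _apply_step(out, gw, gb, hp, adam_state)
    return out


def epoch_order(seed: int, epoch: int, fingerprint: int, n: int) -> np.ndarray:
    """Shuffled index order for one epoch of one training table.

    The order is derived from (run seed, epoch index, fingerprint of the
    data), so two trainers holding byte-identical tables shuffle
    identically while distinct tables shuffle independently.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(epoch), int(fingerprint)]))
    return rng.permutation(n)


def minibatches(
    X: np.ndarray, y: np.ndarray, hp: Hyperparams, seed: int, start_epoch: int = 0
) -> Iterable[tuple[np.ndarray, np.ndarray]]:
    """Endless minibatch stream: per-epoch reshuffle, last batch may be short."""
    fp = data_fingerprint(X, y)
    n = X.shape[0]
    epoch = start_epoch
    while True:
        order = epoch_order(seed, epoch, fp, n)
        for j in range(0, n, hp.batch_size):
            sel = order[j : j + hp.batch_size]
            yield X[sel], y[sel]
        epoch += 1


def steps_per_epoch(n: int, batch_size: int) -> int:
    return -(-n // batch_size)


def train_full(
    X: np.ndarray, y: np.ndarray, epochs: int, hp: Hyperparams, seed: int
) -> ModelParams:
    """Train a fresh model for ``epochs`` full passes over (X, y).

    This is the single-trainer reference used for local and merged models;
    it shares its init, shuffle rule and step rule with the swarm peers so
    that degenerate swarm runs reproduce it exactly.
    """
    model = init_model(seed, feature_dim=X.shape[1])
    k = epochs * steps_per_epoch(X.shape[0], hp.batch_size)
    return train_steps(model, minibatches(X, y, hp, seed), k, hp)


# ---------------------------------------------------------------------------
# prediction


def predict_tiles(model: ModelParams, features: np.ndarray) -> np.ndarray:
    """Per-tile softmax probability of class 1, order-preserving."""
    X = np.asarray(features, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"feature dimension mismatch: got {X.shape}, model expects (*, {model.input_dim})"
        )
    logits, _ = _forward(model, X)
    return _softmax(logits)[:, 1]


def patient_score(tile_scores: Sequence[float], rule: str = "mean", top_k: int = 10) -> float:
    """Aggregate tile class-1 probabilities into one patient-level score.

    Default rule is the arithmetic mean; "majority" (fraction of tiles above
    0.5) and "topk_mean" are available behind the switch.
    """
    s = np.asarray(tile_scores, dtype=np.float64)
    if s.size == 0:
        raise ValueError("patient has no tile scores")
    if rule == "mean":
        return float(s.mean())
    if rule == "majority":
        return float(np.mean(s > 0.5))
    if rule == "topk_mean":
        k = min(top_k, s.size)
        return float(np.sort(s)[-k:].mean())
    raise ConfigurationError(f"unknown aggregation rule {rule!r}")


def predict_patients(
    model: ModelParams, bags: Sequence[PatientBag], rule: str = "mean"
) -> tuple[np.ndarray, np.ndarray]:
    """Patient-level (labels, scores) for a list of bags."""
    labels = np.array([b.label for b in bags], dtype=np.int64)
    scores = np.array(
        [patient_score(predict_tiles(model, b.features), rule=rule) for b in bags]
    )
    return labels, scores
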