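"""The feedforward pair classifier behind the bioactivity similarity index.

The network maps a summed 256-bit fingerprint pair encoding (entries in
{0,1,2}) to the probability that the pair is an S pair — two compounds
active on the same target. Architecture: input layer of width equal to
the encoding length, ReLU hidden layers with inverted dropout, and a
single sigmoid output unit. Training uses the Adam optimizer on binary
cross-entropy for a fixed number of epochs (no early stopping, no
validation split), with seeded shuffling between epochs. Implemented
directly on NumPy so that runs are bit-reproducible under a fixed seed
on a single CPU.

Two named configurations from the method:

* group-specific default: one hidden layer [256], dropout 0.5,
  10 epochs, learning rate 1e-3;
* BSI-Large (cross-family): hidden layers [512, 256, 128, 64],
  dropout 0.3, 10 epochs, learning rate 1e-4.

Fine-tuning continues training all layers (no freezing) at a reduced
learning rate, by default 5 epochs at 1e-4.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "ModelConfig",
    "BsiModel",
    "MPG_CONFIG",
    "LARGE_CONFIG",
    "build_model",
    "train",
    "predict_bsi",
    "finetune",
    "save",
    "load",
]

_CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    hidden_sizes: Tuple[int, ...] = (256,)
    dropout: float = 0.5
    epochs: int = 10
    learning_rate: float = 1e-3
    batch_size: int = 256
    seed: int = 0
    input_dim: int = 256

    def __post_init__(self) -> None:
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if self.epochs < 0 or self.learning_rate <= 0 or self.batch_size <= 0:
            raise ValueError("invalid training hyperparameters")
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hidden_sizes"] = list(self.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["hidden_sizes"] = tuple(d["hidden_sizes"])
        return cls(**d)


#: configuration selected for the per-group models
MPG_CONFIG = ModelConfig(hidden_sizes=(256,), dropout=0.5, epochs=10,
                         learning_rate=1e-3)
#: configuration of the cross-family model
LARGE_CONFIG = ModelConfig(hidden_sizes=(512, 256, 128, 64), dropout=0.3,
                           epochs=10, learning_rate=1e-4)


class BsiModel:
    """Weights + config + loss history. Treat instances as immutable:
    :func:`train` and :func:`finetune` return new models."""

    def __init__(self, config: ModelConfig,
                 weights: List[Tuple[np.ndarray, np.ndarray]],
                 loss_history: Optional[List[float]] = None,
                 provenance: Optional[dict] = None):
        self.config = config
        self.weights = weights
        self.loss_history = list(loss_history or [])
        self.provenance = dict(provenance or {})

    def copy(self) -> "BsiModel":
        return BsiModel(
            self.config,
            [(W.copy(), b.copy()) for W, b in self.weights],
            list(self.loss_history),
            dict(self.provenance),
        )

    # -- forward pass -------------------------------------------------
    def _forward(self, X: np.ndarray, dropout_rng: Optional[np.random.Generator] = None):
        """Return activations of every layer; applies inverted dropout to
        hidden activations when a generator is supplied (training mode)."""
        acts = [X]
        masks = []
        h = X
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(self.weights):
            z = h @ W + b
            if i < n_layers - 1:
                h = np.maximum(z, 0.0)
                if dropout_rng is not None and self.config.dropout > 0.0:
                    keep = 1.0 - self.config.dropout
                    mask = (dropout_rng.random(h.shape) < keep) / keep
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
            else:
                h = _sigmoid(z)
            acts.append(h)
        return acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        if single:
            X = X[None, :]
        if X.shape[1] != self.config.input_dim:
            raise ValueError(
                f"encoding length {X.shape[1]} != model input_dim {self.config.input_dim}"
            )
        acts, _ = self._forward(X, dropout_rng=None)
        out = acts[-1][:, 0]
        return out[0] if single else out


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def build_model(config: ModelConfig, allow_linear: bool = False) -> BsiModel:
    """Initialize the layer stack with fan-in uniform weights under the seed."""
    if not config.hidden_sizes and not allow_linear:
        raise ValueError("empty hidden_sizes requires allow_linear=True")
    rng = np.random.default_rng(config.seed)
    dims = [config.input_dim, *config.hidden_sizes, 1]
    weights = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = 1.0 / np.sqrt(fan_in)
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out))
        b = rng.uniform(-bound, bound, size=fan_out)
        weights.append((W, b))
    return BsiModel(config, weights)


def _bce(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-7, 1.0 - 1e-7)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


def _dataset_provenance(X: np.ndarray, y: np.ndarray) -> dict:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return {
        "n_pairs": int(len(y)),
        "n_positive": int(np.sum(y)),
        "sha256": h.hexdigest()[:16],
    }


def train(
    model: BsiModel,
    X: np.ndarray,
    y: np.ndarray,
    epochs: Optional[int] = None,
    learning_rate: Optional[float] = None,
    seed: Optional[int] = None,
) -> BsiModel:
    """Adam + binary cross-entropy for a fixed number of epochs.

    Returns a new model; the input model is untouched. ``epochs``,
    ``learning_rate`` and ``seed`` default to the model's config. Pairs
    are reshuffled between epochs. Zero epochs returns a copy of the
    initialization unchanged (with provenance recorded).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64).ravel()
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X and y shapes disagree")
    if X.shape[1] != model.config.input_dim:
        raise ValueError("encoding length does not match model input_dim")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("training data must contain both S and N pairs")
    cfg = model.config
    n_epochs = cfg.epochs if epochs is None else int(epochs)
    lr = cfg.learning_rate if learning_rate is None else float(learning_rate)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    out = model.copy()
    out.provenance.setdefault("training_runs", [])
    out.provenance["training_runs"].append(
        {**_dataset_provenance(X, y), "epochs": n_epochs, "learning_rate": lr}
    )
    if n_epochs == 0:
        return out

    params = out.weights
    m_state = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    v_state = [(np.zeros_like(W), np.zeros_like(b)) for W, b in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = X.shape[0]
    for _ in range(n_epochs):
        order = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb, yb = X[idx], y[idx]
            acts, masks = out._forward(xb, dropout_rng=rng)
            p = acts[-1][:, 0]
            epoch_losses.append(_bce(p, yb))
            # backprop: d(BCE)/d(logit) = p - y
            delta = ((p - yb) / len(yb))[:, None]
            grads = [None] * len(params)
            for li in range(len(params) - 1, -1, -1):
                a_prev = acts[li]
                gW = a_prev.T @ delta
                gb = delta.sum(axis=0)
                grads[li] = (gW, gb)
                if li > 0:
                    delta = delta @ params[li][0].T
                    hidden = acts[li]
                    # ReLU gradient through the (possibly dropped-out) activation
                    delta = delta * (hidden > 0)
                    if masks[li - 1] is not None:
                        delta = delta * masks[li - 1]
            step += 1
            for li, ((W, b), (gW, gb)) in enumerate(zip(params, grads)):
                mW, mb = m_state[li]
                vW, vb = v_state[li]
                mW[:] = beta1 * mW + (1 - beta1) * gW
                mb[:] = beta1 * mb + (1 - beta1) * gb
                vW[:] = beta2 * vW + (1 - beta2) * gW ** 2
                vb[:] = beta2 * vb + (1 - beta2) * gb ** 2
                corr1 = 1 - beta1 ** step
                corr2 = 1 - beta2 ** step
                W -= lr * (mW / corr1) / (np.sqrt(vW / corr2) + eps)
                b -= lr * (mb / corr1) / (np.sqrt(vb / corr2) + eps)
        out.loss_history.append(float(np.mean(epoch_losses)))
    return out


def predict_bsi(model: BsiModel, encoding: np.ndarray) -> np.ndarray:
    """Probability that the encoded pair(s) are S pairs — the BSI score.

    Accepts a single encoding vector or a batch matrix; inference is
    deterministic (dropout off) and batch and single-pair paths agree.
    """
    p = model.predict_proba(encoding)
    return np.clip(p, 1e-7, 1.0 - 1e-7)


def finetune(
    base: BsiModel,
    X: np.ndarray,
    y: np.ndarray,
    epochs: int = 5,
    learning_rate: float = 1e-4,
    seed: Optional[int] = None,
) -> BsiModel:
    """Transfer learning: continue training every layer (no freezing).

    Defaults follow the transfer protocol: five epochs at learning rate
    1e-4. Returns a new model; ``base`` is unchanged.
    """
    return train(base, X, y, epochs=epochs, learning_rate=learning_rate, seed=seed)


def save(model: BsiModel, path: str) -> None:
    """Write a self-describing checkpoint (weights + config + provenance)."""
    arrays = {}
    for i, (W, b) in enumerate(model.weights):
        arrays[f"W{i}"] = W
        arrays[f"b{i}"] = b
    meta = {
        "version": _CHECKPOINT_VERSION,
        "n_layers": len(model.weights),
        "config": model.config.to_dict(),
        "loss_history": model.loss_history,
        "provenance": model.provenance,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load(path: str) -> BsiModel:
    """Load a checkpoint; raises on truncated files or version mismatch."""
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            if meta.get("version") != _CHECKPOINT_VERSION:
                raise ValueError(
                    f"unsupported checkpoint version {meta.get('version')!r}"
                )
            config = ModelConfig.from_dict(meta["config"])
            weights = []
            for i in range(meta["n_layers"]):
                weights.append((data[f"W{i}"], data[f"b{i}"]))
    except (OSError, KeyError, ValueError, json.JSONDecodeError) as e:
        if isinstance(e, ValueError) and "checkpoint version" in str(e):
            raise
        raise ValueError(f"cannot load checkpoint {path!r}: {e}") from e
    dims_ok = weights[0][0].shape[0] == config.input_dim and weights[-1][0].shape[1] == 1
    if not dims_ok:
        raise ValueError("checkpoint weights do not match its config dimensions")
    return BsiModel(config, weights, meta["loss_history"], meta["provenance"])
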