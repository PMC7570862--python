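"""Stacked denoising autoencoder, written from scratch on numpy.

A denoising autoencoder layer corrupts its input by masking noise (each
component zeroed independently with probability ``a``, the denoising factor),
encodes with a sigmoid, decodes with a sigmoid, and is trained to minimise the
summed binary cross-entropy between the reconstruction and the *uncorrupted*
input by mini-batch gradient descent:

    y = sigmoid(W1 x' + b1)         (encode)
    z = sigmoid(W2 y + b2)          (decode)
    L(x, z) = -sum_j [ x_j log z_j + (1 - x_j) log(1 - z_j) ]

Layers are pretrained greedily: each layer trains on the clean encodings of
the previous one, re-corrupting its own input fresh at every mini-batch.  A
softmax head is then appended and the whole encoder stack is fine-tuned as an
ordinary MLP on categorical cross-entropy (no corruption at fine-tuning or
inference time; decoder parameters are frozen out).

Inputs are expected in [0, 1] (see :mod:`harsdae.windowing`).  All batched
arrays are row-major: ``(n_samples, n_features)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "DaeLayer",
    "SdaeModel",
    "TrainConfig",
    "TrainingDiverged",
    "sigmoid",
    "softmax",
    "corrupt",
    "encode",
    "decode",
    "recon_loss",
    "init_layer",
    "pretrain_layer",
    "pretrain_stack",
    "fine_tune",
    "predict",
    "save_model",
    "load_model",
]

EPS = 1e-12  # clip inside logs; prevents -inf without measurable bias


class TrainingDiverged(RuntimeError):
    """Loss became non-finite during training (learning rate too high)."""


def sigmoid(x: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    out = np.empty_like(x, dtype=x.dtype if np.issubdtype(x.dtype, np.floating) else float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    """Row-wise softmax."""
    x = np.atleast_2d(x)
    shifted = x - x.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class DaeLayer:
    """One denoising-autoencoder layer (encoder + decoder + denoising factor)."""

    W1: np.ndarray  # (d_in, d_hidden)
    b1: np.ndarray  # (d_hidden,)
    W2: np.ndarray  # (d_hidden, d_in)
    b2: np.ndarray  # (d_in,)
    corruption: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.corruption <= 1.0):
            raise ValueError("corruption probability must lie in [0, 1]")
        d_in, d_hidden = self.W1.shape
        if self.b1.shape != (d_hidden,) or self.W2.shape != (d_hidden, d_in) \
                or self.b2.shape != (d_in,):
            raise ValueError("inconsistent layer parameter shapes")

    @property
    def d_in(self) -> int:
        return self.W1.shape[0]

    @property
    def d_hidden(self) -> int:
        return self.W1.shape[1]


@dataclass
class SdaeModel:
    """An ordered stack of DAE layers plus an optional softmax head."""

    layers: list[DaeLayer]
    head_W: np.ndarray | None = None  # (d_last_hidden, n_classes)
    head_b: np.ndarray | None = None
    classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for lo, hi in zip(self.layers, self.layers[1:]):
            if lo.d_hidden != hi.d_in:
                raise ValueError(
                    f"layer dimensions do not chain: {lo.d_hidden} -> {hi.d_in}"
                )
        if self.head_W is not None and self.layers:
            if self.head_W.shape[0] != self.layers[-1].d_hidden:
                raise ValueError("softmax head input must equal last hidden size")

    @property
    def hidden_sizes(self) -> tuple[int, ...]:
        return tuple(l.d_hidden for l in self.layers)

    def encode_stack(self, X: np.ndarray) -> np.ndarray:
        """Clean (uncorrupted) encoding through every layer."""
        H = np.atleast_2d(np.asarray(X))
        for layer in self.layers:
            H = encode(layer, H)
        return H


@dataclass
class TrainConfig:
    """Hyperparameters for pretraining and fine-tuning.

    ``iterations`` counts full passes (epochs) over the training set and
    applies to both phases unless ``pretrain_epochs``/``finetune_epochs``
    override it.  Defaults follow the reference configuration: two hidden
    layers of 500 sigmoid units, denoising factor 0.5, pretraining rate 1e-7,
    fine-tuning rate 0.01, 200 iterations, batch size 64.
    """

    hidden_sizes: tuple[int, ...] = (500, 500)
    corruption: float = 0.5
    pretrain_lr: float = 1e-7
    finetune_lr: float = 0.01
    iterations: int = 200
    pretrain_epochs: int | None = None
    finetune_epochs: int | None = None
    batch_size: int = 64
    seed: int = 0
    dtype: str = "float64"
    restore_best: bool = True

    def __post_init__(self) -> None:
        if self.pretrain_lr <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0.0 <= self.corruption <= 1.0):
            raise ValueError("corruption must lie in [0, 1]")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")

    @property
    def n_pretrain_epochs(self) -> int:
        return self.pretrain_epochs if self.pretrain_epochs is not None else self.iterations

    @property
    def n_finetune_epochs(self) -> int:
        return self.finetune_epochs if self.finetune_epochs is not None else self.iterations


# ---------------------------------------------------------------------------
# elementary operations


def corrupt(x: np.ndarray, a: float, rng: np.random.Generator) -> np.ndarray:
    """Masking noise: each component zeroed independently with probability a."""
    if not (0.0 <= a <= 1.0):
        raise ValueError("denoising factor must lie in [0, 1]")
    if a == 0.0:
        return np.array(x, copy=True)
    mask = rng.random(np.shape(x)) >= a
    return np.asarray(x) * mask


def encode(layer: DaeLayer, x: np.ndarray) -> np.ndarray:
    x = np.atleast_2d(np.asarray(x))
    if x.shape[1] != layer.d_in:
        raise ValueError(f"input width {x.shape[1]} != layer d_in {layer.d_in}")
    return sigmoid(x @ layer.W1 + layer.b1)


def decode(layer: DaeLayer, y: np.ndarray) -> np.ndarray:
    y = np.atleast_2d(np.asarray(y))
    if y.shape[1] != layer.d_hidden:
        raise ValueError(f"code width {y.shape[1]} != layer d_hidden {layer.d_hidden}")
    return sigmoid(y @ layer.W2 + layer.b2)


def recon_loss(x: np.ndarray, z: np.ndarray) -> float:
    """Binary cross-entropy summed over components (mean over a batch).

    ``z`` is clipped to [EPS, 1-EPS]; ``x`` is expected in [0, 1].
    """
    x = np.asarray(x, dtype=float)
    z = np.clip(np.asarray(z, dtype=float), EPS, 1.0 - EPS)
    bce = -(x * np.log(z) + (1.0 - x) * np.log(1.0 - z))
    per_sample = bce.sum(axis=-1)
    return float(per_sample if per_sample.ndim == 0 else per_sample.mean())


# ---------------------------------------------------------------------------
# initialisation and training


def _glorot(rng: np.random.Generator, d_in: int, d_out: int, dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (d_in + d_out))
    return rng.uniform(-limit, limit, size=(d_in, d_out)).astype(dtype)


def init_layer(
    d_in: int, d_hidden: int, corruption: float, rng: np.random.Generator,
    dtype="float64",
) -> DaeLayer:
    """Glorot-uniform weights, zero biases (encoder drawn before decoder)."""
    return DaeLayer(
        W1=_glorot(rng, d_in, d_hidden, dtype),
        b1=np.zeros(d_hidden, dtype=dtype),
        W2=_glorot(rng, d_hidden, d_in, dtype),
        b2=np.zeros(d_in, dtype=dtype),
        corruption=corruption,
    )


def dae_gradients(layer: DaeLayer, X_clean: np.ndarray, X_corrupt: np.ndarray):
    """Analytic gradients of the summed reconstruction loss over a batch.

    Returns (loss, dW1, db1, dW2, db2) where ``loss`` is the batch *sum* of
    per-sample cross-entropies (the loss is a sum over components, and the
    same summation convention is kept over the mini-batch, so the step size
    per sample is independent of the batch size).  The sigmoid +
    cross-entropy pairing makes the decoder pre-activation gradient simply
    (z - x).
    """
    B = X_clean.shape[0]
    Y = encode(layer, X_corrupt)
    Z = decode(layer, Y)
    loss = recon_loss(X_clean, Z) * B
    dZpre = Z - X_clean
    dW2 = Y.T @ dZpre
    db2 = dZpre.sum(axis=0)
    dYpre = (dZpre @ layer.W2.T) * Y * (1.0 - Y)
    dW1 = X_corrupt.T @ dYpre
    db1 = dYpre.sum(axis=0)
    return loss, dW1, db1, dW2, db2


def pretrain_layer(
    X: np.ndarray,
    layer: DaeLayer,
    config: TrainConfig,
    seed=None,
) -> tuple[DaeLayer, list[float]]:
    """Train one DAE layer in place by mini-batch gradient descent.

    Every epoch reshuffles the data and re-corrupts each mini-batch with the
    layer's denoising factor; the loss is always measured against the clean
    input.  Returns the layer and the per-epoch mean loss trace.
    """
    X = np.atleast_2d(np.asarray(X))
    if X.shape[0] == 0:
        raise ValueError("cannot pretrain on an empty data set")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = X.shape[0]
    lr = config.pretrain_lr
    trace: list[float] = []
    for _ in range(config.n_pretrain_epochs):
        perm = rng.permutation(n)
        total, seen = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx = perm[lo: lo + config.batch_size]
            Xb = X[idx]
            Xc = corrupt(Xb, layer.corruption, rng)
            loss, dW1, db1, dW2, db2 = dae_gradients(layer, Xb, Xc)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite reconstruction loss at epoch {len(trace)}; "
                    f"pretrain_lr={lr} is likely too high"
                )
            layer.W1 -= lr * dW1
            layer.b1 -= lr * db1
            layer.W2 -= lr * dW2
            layer.b2 -= lr * db2
            total += loss
            seen += len(idx)
        trace.append(total / seen)
    return layer, trace


def _layer_seeds(seed: int, n_layers: int) -> list[np.random.SeedSequence]:
    """Deterministic per-layer seed sequences (init + training share one)."""
    return [np.random.SeedSequence(seed, spawn_key=(l,)) for l in range(n_layers)]


def pretrain_stack(
    X: np.ndarray, config: TrainConfig
) -> tuple[SdaeModel, list[list[float]]]:
    """Greedy layer-wise pretraining of the whole stack.

    Layer l+1 trains on the *clean* encodings of layer l's inputs; each
    layer re-corrupts its own input during its own training.  Returns the
    headless model and one loss trace per layer.
    """
    X = np.atleast_2d(np.asarray(X, dtype=config.dtype))
    layers: list[DaeLayer] = []
    traces: list[list[float]] = []
    H = X
    for l, (seed_seq, d_hidden) in enumerate(
        zip(_layer_seeds(config.seed, len(config.hidden_sizes)), config.hidden_sizes)
    ):
        rng = np.random.default_rng(seed_seq)
        layer = init_layer(H.shape[1], d_hidden, config.corruption, rng, config.dtype)
        layer, trace = pretrain_layer(H, layer, config, seed=rng)
        layers.append(layer)
        traces.append(trace)
        H = encode(layer, H)
    return SdaeModel(layers=layers), traces


def _forward_encoders(model: SdaeModel, X: np.ndarray) -> list[np.ndarray]:
    """Activations after each encoder layer; index 0 is the input itself."""
    acts = [np.atleast_2d(np.asarray(X))]
    for layer in model.layers:
        acts.append(encode(layer, acts[-1]))
    return acts


def classification_loss(model: SdaeModel, X: np.ndarray, y_idx: np.ndarray) -> float:
    """Summed categorical cross-entropy of the softmax head over a batch."""
    H = model.encode_stack(X)
    P = softmax(H @ model.head_W + model.head_b)
    p_true = np.clip(P[np.arange(len(y_idx)), y_idx], EPS, 1.0)
    return float(-np.sum(np.log(p_true)))


def classification_gradients(model: SdaeModel, X: np.ndarray, y_idx: np.ndarray):
    """Loss and gradients for all fine-tuned parameters (encoders + head).

    Batch-sum reduction, matching the reconstruction phase.
    """
    B = X.shape[0]
    acts = _forward_encoders(model, X)
    H = acts[-1]
    P = softmax(H @ model.head_W + model.head_b)
    p_true = np.clip(P[np.arange(B), y_idx], EPS, 1.0)
    loss = float(-np.sum(np.log(p_true)))

    dLogits = P.copy()
    dLogits[np.arange(B), y_idx] -= 1.0
    dHeadW = H.T @ dLogits
    dHeadB = dLogits.sum(axis=0)

    dH = dLogits @ model.head_W.T
    enc_grads = []
    for l in range(len(model.layers) - 1, -1, -1):
        A = acts[l + 1]
        dPre = dH * A * (1.0 - A)
        dW1 = acts[l].T @ dPre
        db1 = dPre.sum(axis=0)
        enc_grads.append((dW1, db1))
        if l > 0:
            dH = dPre @ model.layers[l].W1.T
    enc_grads.reverse()
    return loss, enc_grads, dHeadW, dHeadB


def fine_tune(
    model: SdaeModel,
    X: np.ndarray,
    y: Sequence[str],
    classes: Sequence[str],
    config: TrainConfig,
    X_val: np.ndarray | None = None,
    y_val: Sequence[str] | None = None,
) -> tuple[SdaeModel, dict[str, list[float]]]:
    """Append a softmax head and train the full encoder stack supervised.

    Mini-batch gradient descent on categorical cross-entropy for
    ``config.n_finetune_epochs`` epochs at the fine-tuning rate; no input
    corruption; decoder parameters are untouched.  Returns the model and the
    per-epoch ``train_loss`` (and ``val_accuracy`` when a validation set is
    given) traces.

    When a validation set is supplied and ``config.restore_best`` is true,
    the validation set plays its model-selection role: the parameters from
    the epoch with the highest validation accuracy are restored at the end
    (``history["best_epoch"]`` records which).
    """
    X = np.atleast_2d(np.asarray(X, dtype=config.dtype))
    classes = list(classes)
    class_to_idx = {c: i for i, c in enumerate(classes)}
    unknown = sorted({lbl for lbl in y if lbl not in class_to_idx})
    if unknown:
        raise ValueError(f"labels outside the configured class set: {unknown}")
    y_idx = np.asarray([class_to_idx[lbl] for lbl in y], dtype=int)

    ss = np.random.SeedSequence(config.seed, spawn_key=(10_000,))
    rng = np.random.default_rng(ss)
    d_last = model.layers[-1].d_hidden if model.layers else X.shape[1]
    model.classes = classes
    model.head_W = _glorot(rng, d_last, len(classes), config.dtype)
    model.head_b = np.zeros(len(classes), dtype=config.dtype)

    if X_val is not None:
        X_val = np.atleast_2d(np.asarray(X_val, dtype=config.dtype))
        y_val_idx = np.asarray([class_to_idx[lbl] for lbl in y_val], dtype=int)

    n = X.shape[0]
    lr = config.finetune_lr
    history: dict[str, list[float]] = {"train_loss": []}
    if X_val is not None:
        history["val_accuracy"] = []
    best_acc, best_state = -1.0, None
    for epoch in range(config.n_finetune_epochs):
        perm = rng.permutation(n)
        total, seen = 0.0, 0
        for lo in range(0, n, config.batch_size):
            idx = perm[lo: lo + config.batch_size]
            loss, enc_grads, dHW, dHb = classification_gradients(
                model, X[idx], y_idx[idx]
            )
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite classification loss at epoch {epoch}; "
                    f"finetune_lr={lr} is likely too high"
                )
            for layer, (dW1, db1) in zip(model.layers, enc_grads):
                layer.W1 -= lr * dW1
                layer.b1 -= lr * db1
            model.head_W -= lr * dHW
            model.head_b -= lr * dHb
            total += loss
            seen += len(idx)
        history["train_loss"].append(total / seen)
        if X_val is not None:
            pred, _ = predict(model, X_val)
            pred_idx = np.asarray([class_to_idx[p] for p in pred])
            acc = float(np.mean(pred_idx == y_val_idx))
            history["val_accuracy"].append(acc)
            if config.restore_best and acc > best_acc:
                best_acc = acc
                best_state = (
                    [(l.W1.copy(), l.b1.copy()) for l in model.layers],
                    model.head_W.copy(),
                    model.head_b.copy(),
                    epoch,
                )
    if best_state is not None:
        enc, head_W, head_b, best_epoch = best_state
        for layer, (W1, b1) in zip(model.layers, enc):
            layer.W1, layer.b1 = W1, b1
        model.head_W, model.head_b = head_W, head_b
        history["best_epoch"] = best_epoch
    return model, history


def predict(model: SdaeModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class labels and softmax probabilities for each instance.

    Ties in the posterior break toward the lowest class index.
    """
    if model.head_W is None:
        raise ValueError("model has no softmax head; fine-tune it first")
    H = model.encode_stack(X)
    P = softmax(H @ model.head_W + model.head_b)
    idx = P.argmax(axis=1)  # argmax returns the first (lowest) index on ties
    labels = np.asarray([model.classes[i] for i in idx], dtype=object)
    return labels, P


# ---------------------------------------------------------------------------
# serialization

FORMAT_VERSION = 1


def save_model(model: SdaeModel, config: TrainConfig | None, path) -> None:
    """Write the model to a single portable .npz (little-endian float64)."""
    arrays: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers):
        arrays[f"W1_{i}"] = np.asarray(layer.W1, dtype="<f8")
        arrays[f"b1_{i}"] = np.asarray(layer.b1, dtype="<f8")
        arrays[f"W2_{i}"] = np.asarray(layer.W2, dtype="<f8")
        arrays[f"b2_{i}"] = np.asarray(layer.b2, dtype="<f8")
    if model.head_W is not None:
        arrays["head_W"] = np.asarray(model.head_W, dtype="<f8")
        arrays["head_b"] = np.asarray(model.head_b, dtype="<f8")
    meta = {
        "format_version": FORMAT_VERSION,
        "n_layers": len(model.layers),
        "corruption": [l.corruption for l in model.layers],
        "classes": list(model.classes),
        "config": asdict(config) if config is not None else None,
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_model(path) -> tuple[SdaeModel, dict]:
    """Load a saved model; validates the layer shape chain."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta_json"].tolist()).decode("utf-8"))
        if meta.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {meta.get('format_version')}"
            )
        layers = [
            DaeLayer(
                W1=data[f"W1_{i}"], b1=data[f"b1_{i}"],
                W2=data[f"W2_{i}"], b2=data[f"b2_{i}"],
                corruption=meta["corruption"][i],
            )
            for i in range(meta["n_layers"])
        ]
        head_W = data["head_W"] if "head_W" in data else None
        head_b = data["head_b"] if "head_b" in data else None
    model = SdaeModel(
        layers=layers, head_W=head_W, head_b=head_b, classes=meta["classes"]
    )
    return model, meta
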