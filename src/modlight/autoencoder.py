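"""Dense sigmoid autoencoders: architecture, training, metrics, serialization.

Layers are numbered 1..L as in the forward recursion
``x^k = f^k(W^k x^{k-1} + b^k)`` with ``x^1`` the input expression vector;
the input and output layers both have one node per gene, and every hidden
layer of the canonical deep model has the same width H (three hidden layers;
the shallow model has one).  Training minimizes mean-squared reconstruction
error with the ADAM optimizer (learning rate 1e-4, beta1 0.9, beta2 0.999,
epsilon 1e-8, per-step decay 1e-6, batch size 256 by default).  Optional
variants: denoising (additive Gaussian corruption of inputs, clipped back to
[0, 1]) and sparsity (L1 penalty on the weight matrices).
"""

from __future__ import annotations

import copy
import io
import json
import zipfile
from dataclasses import dataclass, asdict

import numpy as np

from .expression import ExpressionMatrix

__all__ = [
    "AEArchitecture",
    "AEModel",
    "TrainConfig",
    "FitMetrics",
    "init_model",
    "forward",
    "train",
    "encode",
    "fit_metrics",
    "save_model",
    "load_model",
]

_ACTIVATIONS = {
    "sigmoid": (
        lambda z: 1.0 / (1.0 + np.exp(-z)),
        lambda a: a * (1.0 - a),  # derivative expressed via the activation value
    ),
    "linear": (lambda z: z, lambda a: np.ones_like(a)),
}


@dataclass
class AEArchitecture:
    """Symmetric encoder/decoder stack of dense layers.

    ``hidden_widths`` lists the hidden-layer widths N^2..N^{L-1} only; the
    input and output widths both equal ``n_features`` (the gene count).
    """

    n_features: int
    hidden_widths: tuple[int, ...]
    activation: str = "sigmoid"
    sparse_l1: float = 0.0
    denoising_sd: float = 0.0

    def __post_init__(self) -> None:
        self.hidden_widths = tuple(int(w) for w in self.hidden_widths)
        if self.n_features < 1:
            raise ValueError("n_features must be positive")
        if not self.hidden_widths:
            raise ValueError("need at least one hidden layer")
        if any(w < 1 for w in self.hidden_widths):
            raise ValueError("hidden widths must be positive")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.sparse_l1 < 0 or self.denoising_sd < 0:
            raise ValueError("sparse_l1 and denoising_sd must be non-negative")

    @property
    def layer_widths(self) -> tuple[int, ...]:
        """Widths N^1..N^L including input and output layers."""
        return (self.n_features, *self.hidden_widths, self.n_features)

    @property
    def n_layers(self) -> int:
        """L, counting input and output."""
        return len(self.hidden_widths) + 2


@dataclass
class AEModel:
    """Weights W^k (N^k × N^{k-1}) and biases b^k for k = 2..L."""

    architecture: AEArchitecture
    weights: list[np.ndarray]
    biases: list[np.ndarray]
    init_seed: int

    def __post_init__(self) -> None:
        widths = self.architecture.layer_widths
        if len(self.weights) != len(widths) - 1 or len(self.biases) != len(widths) - 1:
            raise ValueError("need one weight matrix and bias per layer k = 2..L")
        for k, (W, b) in enumerate(zip(self.weights, self.biases), start=2):
            if W.shape != (widths[k - 1], widths[k - 2]):
                raise ValueError(f"W^{k} has shape {W.shape}, expected "
                                 f"{(widths[k - 1], widths[k - 2])}")
            if b.shape != (widths[k - 1],):
                raise ValueError(f"b^{k} has shape {b.shape}, expected ({widths[k - 1]},)")

    @property
    def n_layers(self) -> int:
        return self.architecture.n_layers

    def copy(self) -> "AEModel":
        return AEModel(
            copy.deepcopy(self.architecture),
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            self.init_seed,
        )


@dataclass
class TrainConfig:
    learning_rate: float = 1.0e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1.0e-8
    decay: float = 1.0e-6
    batch_size: int = 256
    epochs: int = 100
    shuffle_seed: int = 0
    patience: int | None = None  # early stopping on validation loss; None = off
    min_delta: float = 0.0

    def __post_init__(self) -> None:
        for name in ("learning_rate", "beta1", "beta2", "epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.decay < 0:
            raise ValueError("decay must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass
class FitMetrics:
    """Reconstruction accuracy; ``error = 1 - R^2`` globally and per gene.

    The global R^2 uses the variance of all matrix entries around the global
    mean; gene-wise R^2 uses each gene's own mean and variance across
    samples.  Genes with zero variance have undefined gene-wise R^2 and are
    reported as NaN.
    """

    r2_global: float
    r2_genewise: np.ndarray

    @property
    def error_global(self) -> float:
        return 1.0 - self.r2_global

    @property
    def error_genewise(self) -> np.ndarray:
        return 1.0 - self.r2_genewise


def init_model(arch: AEArchitecture, seed: int) -> AEModel:
    """Seeded symmetric-uniform (Glorot) initialization of a dense stack."""
    rng = np.random.default_rng(seed)
    widths = arch.layer_widths
    weights, biases = [], []
    for k in range(1, len(widths)):
        fan_in, fan_out = widths[k - 1], widths[k]
        limit = np.sqrt(6.0 / (fan_in + fan_out))
        weights.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
    return AEModel(arch, weights, biases, seed)


def corrupt(batch: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Denoising corruption: additive N(0, sd) noise, clipped back to [0, 1]."""
    noisy = batch + rng.normal(0.0, sd, size=batch.shape)
    np.clip(noisy, 0.0, 1.0, out=noisy)
    return noisy


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, ExpressionMatrix):
        return X.values
    return np.asarray(X, dtype=float)


def forward(model: AEModel, X) -> list[np.ndarray]:
    """Per-layer activations x^1..x^L for a genes × samples input."""
    X = _as_matrix(X)
    if X.ndim == 1:
        X = X[:, np.newaxis]
    if X.shape[0] != model.architecture.n_features:
        raise ValueError(
            f"input has {X.shape[0]} rows, model expects {model.architecture.n_features}"
        )
    act, _ = _ACTIVATIONS[model.architecture.activation]
    xs = [X]
    for W, b in zip(model.weights, model.biases):
        xs.append(act(W @ xs[-1] + b[:, np.newaxis]))
    return xs


def encode(model: AEModel, X, layer: int) -> np.ndarray:
    """Hidden-layer activations x^layer (H × samples); 2 <= layer <= L-1."""
    if not 2 <= layer <= model.n_layers - 1:
        raise ValueError(f"layer must be in [2, {model.n_layers - 1}], got {layer}")
    return forward(model, X)[layer - 1]


def _loss_and_grads(model: AEModel, X: np.ndarray, target: np.ndarray):
    """MSE (plus L1 penalty) and its gradients via backpropagation."""
    act, dact = _ACTIVATIONS[model.architecture.activation]
    xs = [X]
    for W, b in zip(model.weights, model.biases):
        xs.append(act(W @ xs[-1] + b[:, np.newaxis]))
    out = xs[-1]
    n_entries = out.size
    resid = out - target
    mse = float(np.mean(resid**2))
    l1 = model.architecture.sparse_l1
    loss = mse + (l1 * sum(np.abs(W).sum() for W in model.weights) if l1 > 0 else 0.0)

    gW = [None] * len(model.weights)
    gb = [None] * len(model.biases)
    delta = (2.0 / n_entries) * resid * dact(out)
    for k in range(len(model.weights) - 1, -1, -1):
        gW[k] = delta @ xs[k].T
        gb[k] = delta.sum(axis=1)
        if l1 > 0:
            gW[k] += l1 * np.sign(model.weights[k])
        if k > 0:
            delta = (model.weights[k].T @ delta) * dact(xs[k])
    return loss, mse, gW, gb


def _mse(model: AEModel, X: np.ndarray) -> float:
    out = forward(model, X)[-1]
    return float(np.mean((out - X) ** 2))


def train(
    model: AEModel,
    X_train,
    X_valid=None,
    config: TrainConfig | None = None,
) -> tuple[AEModel, dict[str, list[float]]]:
    """Train the autoencoder in place with mini-batch ADAM.

    Inputs must already be normalized to [0, 1].  Returns the model and a
    history dict with per-epoch training loss (and validation loss when a
    validation matrix is given).  With ``denoising_sd > 0`` each batch input
    is corrupted with additive Gaussian noise and clipped back to [0, 1]
    while the reconstruction target stays clean.
    """
    if config is None:
        config = TrainConfig()
    X = _as_matrix(X_train)
    if X.min() < 0 or X.max() > 1:
        raise ValueError("training values must lie in [0, 1]; run min–max scaling first")
    Xv = _as_matrix(X_valid) if X_valid is not None else None

    rng = np.random.default_rng(config.shuffle_seed)
    arch = model.architecture
    params = model.weights + model.biases
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    history: dict[str, list[float]] = {"train_loss": [], "train_mse": []}
    if Xv is not None:
        history["valid_mse"] = []

    best_loss = np.inf
    best_state = None
    stale = 0
    n_samples = X.shape[1]

    for _epoch in range(config.epochs):
        order = rng.permutation(n_samples)
        epoch_loss = 0.0
        epoch_mse = 0.0
        n_batches = 0
        for start in range(0, n_samples, config.batch_size):
            cols = order[start:start + config.batch_size]
            batch = X[:, cols]
            noisy = corrupt(batch, arch.denoising_sd, rng) if arch.denoising_sd > 0 else batch
            loss, mse, gW, gb = _loss_and_grads(model, noisy, batch)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss {loss} at epoch {_epoch}, step {t}; "
                    "reduce the learning rate or check the input scaling"
                )
            grads = gW + gb
            t += 1
            lr_t = config.learning_rate / (1.0 + config.decay * t)
            b1t = 1.0 - config.beta1**t
            b2t = 1.0 - config.beta2**t
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = config.beta1 * m[i] + (1 - config.beta1) * g
                v[i] = config.beta2 * v[i] + (1 - config.beta2) * g * g
                p -= lr_t * (m[i] / b1t) / (np.sqrt(v[i] / b2t) + config.epsilon)
            epoch_loss += loss
            epoch_mse += mse
            n_batches += 1
        history["train_loss"].append(epoch_loss / n_batches)
        history["train_mse"].append(epoch_mse / n_batches)

        monitor = history["train_loss"][-1]
        if Xv is not None:
            vm = _mse(model, Xv)
            history["valid_mse"].append(vm)
            monitor = vm
        if config.patience is not None:
            if monitor < best_loss - config.min_delta:
                best_loss = monitor
                best_state = ([W.copy() for W in model.weights],
                              [b.copy() for b in model.biases])
                stale = 0
            else:
                stale += 1
                if stale > config.patience:
                    break
    if config.patience is not None and best_state is not None:
        model.weights[:] = best_state[0]
        model.biases[:] = best_state[1]
    return model, history


def fit_metrics(model: AEModel, X) -> FitMetrics:
    """Global and gene-wise R² of the reconstruction (error = 1 − R²)."""
    Xm = _as_matrix(X)
    recon = forward(model, Xm)[-1]
    sse = (recon - Xm) ** 2
    sst_global = float(np.sum((Xm - Xm.mean()) ** 2))
    if sst_global <= 0:
        raise ValueError("input matrix is constant; global R² undefined")
    r2_global = 1.0 - float(sse.sum()) / sst_global

    gene_mean = Xm.mean(axis=1, keepdims=True)
    sst_gene = np.sum((Xm - gene_mean) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2_gene = 1.0 - sse.sum(axis=1) / sst_gene
    r2_gene[sst_gene <= 0] = np.nan
    return FitMetrics(r2_global, r2_gene)


def save_model(model: AEModel, path) -> None:
    """Write a single archive: architecture JSON + float64 weight arrays.

    The round trip through :func:`load_model` is bit-exact.
    """
    meta = {
        "architecture": asdict(model.architecture),
        "init_seed": model.init_seed,
        "n_weight_layers": len(model.weights),
    }
    with zipfile.ZipFile(path, "w", compression=zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("architecture.json", json.dumps(meta, indent=1))
        for k, (W, b) in enumerate(zip(model.weights, model.biases), start=2):
            for name, arr in ((f"W{k}.npy", W), (f"b{k}.npy", b)):
                buf = io.BytesIO()
                np.save(buf, np.ascontiguousarray(arr))
                zf.writestr(name, buf.getvalue())


def load_model(path) -> AEModel:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("architecture.json"))
        arch_d = meta["architecture"]
        arch = AEArchitecture(
            n_features=arch_d["n_features"],
            hidden_widths=tuple(arch_d["hidden_widths"]),
            activation=arch_d["activation"],
            sparse_l1=arch_d["sparse_l1"],
            denoising_sd=arch_d["denoising_sd"],
        )
        weights, biases = [], []
        for k in range(2, meta["n_weight_layers"] + 2):
            weights.append(np.load(io.BytesIO(zf.read(f"W{k}.npy"))))
            biases.append(np.load(io.BytesIO(zf.read(f"b{k}.npy"))))
    return AEModel(arch, weights, biases, meta["init_seed"])
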