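"""Disease-gene prediction by reverse training on the compressed space.

The procedure, given a trained autoencoder:

1. compress the expression profiles at a chosen hidden layer;
2. train a one-hidden-layer supervised net *in reverse*: from phenotype
   indicator columns c_{i,j} = delta_{ip} (P × S) to the compressed
   representations (H × S), sigmoid hidden layer and linear output, both of
   width H;
3. stack the supervised net onto the remaining (decoder) part of the
   autoencoder, optionally moment-matching the supervised output layer's
   weights and bias to the autoencoder layer they replace;
4. feed the indicator vector r^p of phenotype p through the stacked net;
   the disease score is s^p = W^L x^{L-1} — the final weight matrix applied
   with no bias and no activation — and genes are ranked by |s^p|.

Steps 2–4 are repeated (default three times) with fresh seeds to give mean
and standard deviation of each gene's score; the aggregate ranking uses the
mean absolute score.  A naive supervised baseline trains phenotype →
expression directly and is scored identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .autoencoder import _ACTIVATIONS, AEModel, TrainConfig
from .expression import ExpressionMatrix, SampleAnnotation
from . import autoencoder as _ae

__all__ = [
    "PhenotypeDesign",
    "SupervisedNet",
    "StackedNet",
    "DiseaseScore",
    "build_phenotype_matrix",
    "train_reverse",
    "stack",
    "score_disease",
    "predict_disease_genes",
    "naive_baseline",
    "DiseasePrediction",
]


@dataclass
class PhenotypeDesign:
    """Phenotype indicator matrix c (P × S), c_{i,j} = 1 iff sample j has
    phenotype i; a column is all-zero for unannotated samples."""

    phenotypes: list[str]
    samples: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.phenotypes), len(self.samples)):
            raise ValueError("design matrix shape mismatch")
        if np.any(self.matrix.sum(axis=0) > 1):
            raise ValueError("a sample carries more than one phenotype label")

    def indicator(self, phenotype: str) -> np.ndarray:
        """r^p: one-hot column vector for phenotype p."""
        if phenotype not in self.phenotypes:
            raise KeyError(f"unknown phenotype {phenotype!r}")
        r = np.zeros(len(self.phenotypes))
        r[self.phenotypes.index(phenotype)] = 1.0
        return r


def build_phenotype_matrix(
    annotations: Sequence[SampleAnnotation],
    phenotypes: Sequence[str],
    samples: Sequence[str] | None = None,
) -> PhenotypeDesign:
    """Indicator design matrix from annotations for the chosen labels.

    Raises if a sample carries two of the chosen labels; samples with none
    get an all-zero column.
    """
    phenotypes = list(phenotypes)
    if len(set(phenotypes)) != len(phenotypes):
        raise ValueError("duplicate phenotype labels")
    if samples is None:
        seen: list[str] = []
        for a in annotations:
            if a.sample_id not in seen:
                seen.append(a.sample_id)
        samples = seen
    samples = list(samples)
    s_index = {s: j for j, s in enumerate(samples)}
    p_index = {p: i for i, p in enumerate(phenotypes)}
    c = np.zeros((len(phenotypes), len(samples)))
    for a in annotations:
        if a.phenotype in p_index and a.sample_id in s_index:
            i, j = p_index[a.phenotype], s_index[a.sample_id]
            if c[:, j].sum() and not c[i, j]:
                raise ValueError(
                    f"sample {a.sample_id!r} has two labels among the chosen phenotypes"
                )
            c[i, j] = 1.0
    return PhenotypeDesign(phenotypes, samples, c)


@dataclass
class SupervisedNet:
    """One-hidden-layer net: input P -> hidden H (sigmoid) -> output H (linear)."""

    W_hidden: np.ndarray
    b_hidden: np.ndarray
    W_out: np.ndarray
    b_out: np.ndarray
    train_seed: int = 0

    def __post_init__(self) -> None:
        if self.W_out.shape[1] != self.W_hidden.shape[0]:
            raise ValueError("hidden and output widths are inconsistent")

    @property
    def n_inputs(self) -> int:
        return self.W_hidden.shape[1]

    def forward(self, C: np.ndarray) -> np.ndarray:
        sig = _ACTIVATIONS["sigmoid"][0]
        h = sig(self.W_hidden @ C + self.b_hidden[:, np.newaxis])
        return self.W_out @ h + self.b_out[:, np.newaxis]


def train_reverse(
    compressed: np.ndarray,
    design: PhenotypeDesign,
    config: TrainConfig | None = None,
    seed: int = 0,
    hidden_width: int | None = None,
) -> SupervisedNet:
    """Fit phenotype indicators -> compressed representations by MSE.

    The hidden width defaults to H, the compressed dimension, matching the
    output width.  ADAM with the shared training defaults.
    """
    if config is None:
        config = TrainConfig()
    compressed = np.asarray(compressed, dtype=float)
    H, S = compressed.shape
    if len(design.samples) != S:
        raise ValueError(
            f"design has {len(design.samples)} samples, compressed matrix has {S}"
        )
    if hidden_width is None:
        hidden_width = H
    P = len(design.phenotypes)
    rng = np.random.default_rng(seed)

    def glorot(n_out, n_in):
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_out, n_in))

    net = SupervisedNet(
        glorot(hidden_width, P), np.zeros(hidden_width),
        glorot(H, hidden_width), np.zeros(H), train_seed=seed,
    )
    _adam_fit(net, design.matrix, compressed, config, rng)
    return net


def _adam_fit(
    net: SupervisedNet,
    C: np.ndarray,
    target: np.ndarray,
    config: TrainConfig,
    rng: np.random.Generator,
) -> list[float]:
    """Mini-batch ADAM on MSE for the two-layer supervised net, in place."""
    sig = _ACTIVATIONS["sigmoid"][0]
    params = [net.W_hidden, net.b_hidden, net.W_out, net.b_out]
    m = [np.zeros_like(p) for p in params]
    v = [np.zeros_like(p) for p in params]
    t = 0
    S = C.shape[1]
    history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(S)
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, S, config.batch_size):
            cols = order[start:start + config.batch_size]
            c, y = C[:, cols], target[:, cols]
            h = sig(net.W_hidden @ c + net.b_hidden[:, np.newaxis])
            out = net.W_out @ h + net.b_out[:, np.newaxis]
            resid = out - y
            loss = float(np.mean(resid**2))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at step {t}")
            d_out = (2.0 / resid.size) * resid
            gWo = d_out @ h.T
            gbo = d_out.sum(axis=1)
            d_h = (net.W_out.T @ d_out) * h * (1 - h)
            gWh = d_h @ c.T
            gbh = d_h.sum(axis=1)
            grads = [gWh, gbh, gWo, gbo]
            t += 1
            lr_t = config.learning_rate / (1.0 + config.decay * t)
            b1t, b2t = 1.0 - config.beta1**t, 1.0 - config.beta2**t
            for i, (p, g) in enumerate(zip(params, grads)):
                m[i] = config.beta1 * m[i] + (1 - config.beta1) * g
                v[i] = config.beta2 * v[i] + (1 - config.beta2) * g * g
                p -= lr_t * (m[i] / b1t) / (np.sqrt(v[i] / b2t) + config.epsilon)
            epoch_loss += loss
            n_batches += 1
        history.append(epoch_loss / n_batches)
    return history


def _moment_match(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Elementwise affine transform of ``source`` to the mean/variance of
    ``target``; returns (transformed, scale, shift).  Matching a matrix onto
    itself is the identity."""
    s_mean, s_sd = float(source.mean()), float(source.std())
    t_mean, t_sd = float(target.mean()), float(target.std())
    scale = t_sd / s_sd if s_sd > 0 else 1.0
    shift = t_mean - scale * s_mean
    return scale * source + shift, scale, shift


@dataclass
class StackedNet:
    """Supervised net stacked onto the decoder tail of the autoencoder.

    ``layers`` hold (W, b, activation) for the stacked layers 1 < k <= L-1;
    ``final_W`` is the last autoencoder weight matrix W^L applied with no
    bias and no activation to produce the score.
    """

    phenotypes: list[str]
    gene_ids: list[str]
    layers: list[tuple[np.ndarray, np.ndarray, str]]
    final_W: np.ndarray
    rescaling: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.final_W.shape[0] != len(self.gene_ids):
            raise ValueError("final weight matrix rows must equal gene count")


def stack(
    sup: SupervisedNet,
    ae: AEModel,
    layer: int,
    gene_ids: Sequence[str],
    phenotypes: Sequence[str],
    rescale: bool = False,
) -> StackedNet:
    """Compose the supervised net with autoencoder layers layer+1 .. L.

    ``layer`` is the absolute hidden-layer index p at which the supervised
    net was trained.  With ``rescale`` the supervised output layer's weight
    matrix and bias are affinely moment-matched (elementwise mean and
    variance) to the autoencoder's W^p and b^p, the layer they stand in
    for; the transform is recorded.  Rescaling is off by default: the
    elementwise shift adds a rank-one perturbation (uniform across output
    nodes) to the predicted code, which empirically degrades the gene
    ranking; the supervised net's own output already lives on the scale of
    the compressed representations it was fitted to.
    """
    L = ae.n_layers
    widths = ae.architecture.layer_widths
    if not 2 <= layer <= L - 1:
        raise ValueError(f"layer must be in [2, {L - 1}], got {layer}")
    if sup.W_out.shape[0] != widths[layer - 1]:
        raise ValueError(
            f"supervised output width {sup.W_out.shape[0]} != layer width "
            f"{widths[layer - 1]}"
        )
    W_out, b_out = sup.W_out, sup.b_out
    rescaling: dict[str, float] = {}
    if rescale:
        W_target, b_target = ae.weights[layer - 2], ae.biases[layer - 2]
        W_out, w_scale, w_shift = _moment_match(W_out, W_target)
        b_out, b_scale, b_shift = _moment_match(b_out, b_target)
        rescaling = {"W_scale": w_scale, "W_shift": w_shift,
                     "b_scale": b_scale, "b_shift": b_shift}

    act = ae.architecture.activation
    layers: list[tuple[np.ndarray, np.ndarray, str]] = [
        (sup.W_hidden, sup.b_hidden, "sigmoid"),
        (W_out, b_out, "linear"),
    ]
    # decoder layers p+1 .. L-1 keep their activation; layer L is scored bare
    for k in range(layer + 1, L):
        layers.append((ae.weights[k - 2], ae.biases[k - 2], act))
    return StackedNet(list(phenotypes), list(gene_ids), layers, ae.weights[L - 2],
                      rescaling)


@dataclass
class DiseaseScore:
    """Per-gene scores s^p for one phenotype; ranking uses |s^p|."""

    phenotype: str
    scores: np.ndarray
    gene_ids: list[str]

    @property
    def abs_scores(self) -> np.ndarray:
        return np.abs(self.scores)

    @property
    def ranked_genes(self) -> list[str]:
        order = np.argsort(-self.abs_scores, kind="stable")
        return [self.gene_ids[i] for i in order]


def score_disease(stacked: StackedNet, phenotype: str) -> DiseaseScore:
    """s^p = W^L x^{L-1} for the indicator input r^p of the phenotype."""
    if phenotype not in stacked.phenotypes:
        raise KeyError(f"unknown phenotype {phenotype!r}")
    x = np.zeros(len(stacked.phenotypes))
    x[stacked.phenotypes.index(phenotype)] = 1.0
    for W, b, act_name in stacked.layers:
        x = _ACTIVATIONS[act_name][0](W @ x + b)
    s = stacked.final_W @ x
    return DiseaseScore(phenotype, s, stacked.gene_ids)


@dataclass
class DiseasePrediction:
    """Aggregate of repeated reverse trainings for one phenotype."""

    phenotype: str
    gene_ids: list[str]
    per_repeat: np.ndarray          # R × genes signed scores
    mean_abs_score: np.ndarray
    sd_score: np.ndarray

    @property
    def ranked_genes(self) -> list[str]:
        order = np.argsort(-self.mean_abs_score, kind="stable")
        return [self.gene_ids[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        order = np.argsort(-self.mean_abs_score, kind="stable")
        return pd.DataFrame({
            "rank": np.arange(1, len(order) + 1),
            "gene_id": [self.gene_ids[i] for i in order],
            "mean_abs_score": self.mean_abs_score[order],
            "sd_score": self.sd_score[order],
        })


def predict_disease_genes(
    E: ExpressionMatrix,
    annotations: Sequence[SampleAnnotation],
    ae: AEModel,
    layer: int,
    phenotypes: Sequence[str],
    config: TrainConfig | None = None,
    repeats: int = 3,
    seeds: Sequence[int] | None = None,
    rescale: bool = False,
) -> dict[str, DiseasePrediction]:
    """Full reverse-training pipeline at one hidden layer.

    The autoencoder stays fixed; the supervised net is retrained ``repeats``
    times with fresh seeds and the per-gene scores are aggregated as mean
    absolute score (ranking) and standard deviation.  Phenotypes with no
    annotated sample are skipped with a warning.
    """
    if seeds is None:
        seeds = list(range(repeats))
    if len(seeds) != repeats:
        raise ValueError("need one seed per repeat")
    counts = {p: 0 for p in phenotypes}
    for a in annotations:
        if a.phenotype in counts:
            counts[a.phenotype] += 1
    usable = [p for p in phenotypes if counts[p] >= 1]
    for p in phenotypes:
        if counts[p] < 1:
            warnings.warn(f"phenotype {p!r} has no annotated sample; skipped")
    if not usable:
        return {}

    design = build_phenotype_matrix(annotations, usable, samples=E.sample_ids)
    compressed = _ae.encode(ae, E, layer)
    per_repeat = {p: [] for p in usable}
    for seed in seeds:
        sup = train_reverse(compressed, design, config=config, seed=int(seed))
        stacked = stack(sup, ae, layer, E.gene_ids, usable, rescale=rescale)
        for p in usable:
            per_repeat[p].append(score_disease(stacked, p).scores)
    out: dict[str, DiseasePrediction] = {}
    for p in usable:
        R = np.vstack(per_repeat[p])
        out[p] = DiseasePrediction(
            p, list(E.gene_ids), R,
            mean_abs_score=np.abs(R).mean(axis=0),
            sd_score=R.std(axis=0, ddof=1) if R.shape[0] > 1 else np.zeros(R.shape[1]),
        )
    return out


def naive_baseline(
    E: ExpressionMatrix,
    design: PhenotypeDesign,
    hidden: int = 512,
    config: TrainConfig | None = None,
    seed: int = 0,
) -> dict[str, DiseaseScore]:
    """Supervised reference: phenotype indicators -> expression directly.

    A one-hidden-layer net (sigmoid hidden of the given width, linear
    output over genes) is trained on the same design matrix, and scored
    exactly like the stacked net: s^p = W_out x_hidden with no bias.
    """
    if config is None:
        config = TrainConfig()
    if len(design.samples) != E.n_samples:
        raise ValueError("design samples must match the expression matrix")
    rng = np.random.default_rng(seed)
    P, n_genes = len(design.phenotypes), E.n_genes

    def glorot(n_out, n_in):
        lim = np.sqrt(6.0 / (n_in + n_out))
        return rng.uniform(-lim, lim, size=(n_out, n_in))

    net = SupervisedNet(
        glorot(hidden, P), np.zeros(hidden),
        glorot(n_genes, hidden), np.zeros(n_genes), train_seed=seed,
    )
    _adam_fit(net, design.matrix, E.values, config, rng)
    stacked = StackedNet(
        list(design.phenotypes), list(E.gene_ids),
        [(net.W_hidden, net.b_hidden, "sigmoid")],
        net.W_out,
    )
    return {p: score_disease(stacked, p) for p in design.phenotypes}
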