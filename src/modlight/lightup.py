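"""Light-up interpretation of hidden autoencoder nodes.

A hidden node is interpreted by setting its activation to the activation
function's maximum (1.0 for sigmoid), clamping every other node of that
layer to zero, and forward-propagating through the remaining layers to the
output gene space:

    x^k = f^k(W^k x^{k-1} + b^k)   for p < k <= L,    x^p = amax * e_h.

The output activation vector x^L ranks the genes most influenced by the
node (descending activation; ties broken by ascending gene index so the
ranking is deterministic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autoencoder import _ACTIVATIONS, AEModel

__all__ = ["LightUpResult", "light_up_node", "light_up_all", "top_genes",
           "results_to_frame"]


@dataclass
class LightUpResult:
    """Output-space response to maximally activating one hidden node."""

    layer: int                      # absolute layer index p (2..L-1)
    node: int                       # node index h within the layer
    output_activation: np.ndarray   # x^L over genes
    ranked_genes: list[str]         # descending activation, tie -> gene index

    def __post_init__(self) -> None:
        if len(self.ranked_genes) != len(self.output_activation):
            raise ValueError("ranked_genes must be a permutation of all genes")


def _rank_genes(activation: np.ndarray, gene_ids: list[str]) -> list[str]:
    # stable argsort on -activation keeps ascending gene index among ties
    order = np.argsort(-activation, kind="stable")
    return [gene_ids[i] for i in order]


def light_up_node(
    model: AEModel,
    gene_ids: list[str],
    layer: int,
    node: int,
    activation_max: float = 1.0,
    subtract_baseline: bool = False,
) -> LightUpResult:
    """Forward-propagate a maximal single-node activation to the genes.

    ``layer`` is the absolute index p of a hidden layer (2 <= p <= L-1).
    With ``subtract_baseline`` the response to an all-zero input at the same
    layer is subtracted before ranking (off by default: genes are ranked on
    the raw output activation).
    """
    L = model.n_layers
    widths = model.architecture.layer_widths
    if not 2 <= layer <= L - 1:
        raise ValueError(f"layer must be a hidden layer in [2, {L - 1}], got {layer}")
    if not 0 <= node < widths[layer - 1]:
        raise ValueError(f"node must be in [0, {widths[layer - 1]}), got {node}")
    if len(gene_ids) != model.architecture.n_features:
        raise ValueError("gene_ids length must equal the model's feature count")

    x = np.zeros(widths[layer - 1])
    x[node] = activation_max
    out = _propagate_from(model, x, layer)
    if subtract_baseline:
        out = out - _propagate_from(model, np.zeros(widths[layer - 1]), layer)
    return LightUpResult(layer, node, out, _rank_genes(out, list(gene_ids)))


def _propagate_from(model: AEModel, x: np.ndarray, layer: int) -> np.ndarray:
    """Apply layers layer+1..L of the model to an activation vector x^layer."""
    act, _ = _ACTIVATIONS[model.architecture.activation]
    # weights[k-2], biases[k-2] map layer k-1 -> k
    for k in range(layer + 1, model.n_layers + 1):
        x = act(model.weights[k - 2] @ x + model.biases[k - 2])
    return x


def light_up_all(
    model: AEModel,
    gene_ids: list[str],
    layer: int,
    activation_max: float = 1.0,
    subtract_baseline: bool = False,
) -> list[LightUpResult]:
    """Light-up of every node of one hidden layer, in node order."""
    width = model.architecture.layer_widths[layer - 1] if 2 <= layer < model.n_layers \
        else 0
    return [
        light_up_node(model, gene_ids, layer, h, activation_max, subtract_baseline)
        for h in range(width)
    ]


def top_genes(result: LightUpResult, cutoff: int) -> list[str]:
    """The ``cutoff`` highest-ranked genes of a light-up result."""
    if not 1 <= cutoff <= len(result.ranked_genes):
        raise ValueError(
            f"cutoff must be in [1, {len(result.ranked_genes)}], got {cutoff}"
        )
    return result.ranked_genes[:cutoff]


def results_to_frame(results: list[LightUpResult]) -> pd.DataFrame:
    """Long-format table (layer, node, rank, gene_id, activation)."""
    rows = []
    for res in results:
        order = np.argsort(-res.output_activation, kind="stable")
        for rank, i in enumerate(order, start=1):
            rows.append((res.layer, res.node, rank, res.ranked_genes[rank - 1],
                         res.output_activation[i]))
    return pd.DataFrame(rows, columns=["layer", "node", "rank", "gene_id", "activation"])
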