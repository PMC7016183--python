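"""Phenotype coherence of embeddings: 2-PC projections and silhouettes.

The compressed representation of a hidden layer is visualized through its
first two principal components ("deepAE-PCA") and compared against a plain
PCA of the full gene space.  For each phenotype group the silhouette index
is computed one-vs-rest on the 2-D coordinates; groups where the
autoencoder embedding beats plain PCA by at least a margin (default 0.1)
are counted and tested with an exact binomial test against chance (0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .enrichment import binomial_comparison

__all__ = [
    "EmbeddingCoords",
    "SilhouetteComparison",
    "pca2",
    "silhouette_group",
    "compare_embeddings",
]


@dataclass
class EmbeddingCoords:
    """2-D coordinates per sample with a provenance tag."""

    sample_ids: list[str]
    coords: np.ndarray
    source: str = "raw_PCA"

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.sample_ids), 2):
            raise ValueError("coords must be n_samples × 2")


def pca2(X, sample_ids: Sequence[str] | None = None, source: str = "raw_PCA") -> EmbeddingCoords:
    """Project samples × features data onto the first two principal axes.

    Data are mean-centered (not scaled).  Sign convention: the loading with
    the largest magnitude on each axis is positive, so the projection is
    deterministic.  Rank-deficient input (< 2 informative directions)
    yields a zero second coordinate with a warning.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 features")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(X.shape[0])]
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    coords = np.zeros((X.shape[0], 2))
    tol = max(X.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    n_informative = int(np.sum(s > tol))
    if n_informative < 2:
        warnings.warn("input has rank < 2; second principal coordinate is zero")
    for c in range(min(2, n_informative)):
        v = Vt[c]
        sign = np.sign(v[np.argmax(np.abs(v))]) or 1.0
        coords[:, c] = sign * (Xc @ v)
    return EmbeddingCoords(list(sample_ids), coords, source)


def silhouette_group(
    coords: EmbeddingCoords, labels: Sequence[str], group: str
) -> float:
    """One-vs-rest silhouette of one phenotype group on 2-D coordinates.

    For each member, a = mean distance to the other members and b = mean
    distance to all non-members; its silhouette is (b - a) / max(a, b),
    with 0/0 treated as 0.  The group value is the mean over members; a
    singleton group scores 0 by convention.
    """
    labels = np.asarray([str(l) for l in labels])
    if len(labels) != len(coords.sample_ids):
        raise ValueError("one label per sample required")
    in_group = labels == group
    if not in_group.any():
        raise ValueError(f"empty group {group!r}")
    if in_group.all():
        raise ValueError("need at least one non-group sample")
    A = coords.coords[in_group]
    B = coords.coords[~in_group]
    if len(A) == 1:
        return 0.0
    d_in = cdist(A, A)
    a = d_in.sum(axis=1) / (len(A) - 1)
    b = cdist(A, B).mean(axis=1)
    denom = np.maximum(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(denom > 0, (b - a) / denom, 0.0)
    return float(s.mean())


@dataclass
class SilhouetteComparison:
    """Per-group silhouettes of two embeddings and the binomial summary."""

    table: pd.DataFrame   # group, si_ae, si_pca, delta, favored
    margin: float
    n_favored: int
    n_groups: int
    p_value: float
    odds: float


def compare_embeddings(
    ae_coords: EmbeddingCoords,
    pca_coords: EmbeddingCoords,
    labels: Sequence[str],
    margin: float = 0.1,
    tail: str = "geq",
    groups: Sequence[str] | None = None,
) -> SilhouetteComparison:
    """Count groups where the compressed embedding wins by >= margin.

    Both embeddings must cover the same samples in the same order.  Groups
    default to every distinct label.  The count of favored groups among all
    N groups is referred to an exact binomial(N, 0.5) tail; the odds are
    n / (N - n).
    """
    if ae_coords.sample_ids != pca_coords.sample_ids:
        raise ValueError("embeddings must cover the same samples in the same order")
    labels = [str(l) for l in labels]
    if len(labels) != len(ae_coords.sample_ids):
        raise ValueError("one label per sample required")
    if groups is None:
        groups = sorted(set(labels))
    rows = []
    for g in groups:
        si_ae = silhouette_group(ae_coords, labels, g)
        si_pca = silhouette_group(pca_coords, labels, g)
        rows.append((g, si_ae, si_pca, si_ae - si_pca, si_ae - si_pca >= margin))
    table = pd.DataFrame(rows, columns=["group", "si_ae", "si_pca", "delta", "favored"])
    n_fav = int(table["favored"].sum())
    n_groups = len(table)
    p, odds = binomial_comparison(n_fav, n_groups, tail=tail)
    return SilhouetteComparison(table, margin, n_fav, n_groups, p, odds)
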