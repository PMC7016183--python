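"""Expression-matrix container, normalization and train/test partitioning.

The container holds a genes × samples real matrix.  Upstream of the
autoencoder two normalizations are applied: upper-quartile scaling with a
log2(1+x) transform and a noise floor (RNA-seq style counts), and a min–max
rescaling of the whole matrix onto [0, 1] (both microarray and RNA-seq),
e_ij = (E_ij - min(E)) / (max(E) - min(E)).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "DataSplit",
    "read_annotations",
    "write_annotations",
    "normalize_upper_quartile_log",
    "minmax_scale",
    "split_train_test",
]


@dataclass
class ExpressionMatrix:
    """Genes × samples expression matrix with ordered, unique identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes × {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy(dtype=float))

    @classmethod
    def from_tsv(cls, path) -> "ExpressionMatrix":
        """Read a TSV with gene ids in the first column and a sample header.

        Gzip-compressed files are handled transparently (by extension).
        """
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        return cls.from_frame(df)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])


@dataclass(frozen=True)
class SampleAnnotation:
    """One phenotype label attached to one sample.

    A sample may carry several annotations (e.g. a cell type and a disease);
    ``phenotype_class`` distinguishes them.
    """

    sample_id: str
    phenotype: str
    phenotype_class: Literal["disease", "cell_type", "control"]

    def __post_init__(self) -> None:
        if self.phenotype_class not in ("disease", "cell_type", "control"):
            raise ValueError(f"unknown phenotype_class {self.phenotype_class!r}")


def read_annotations(path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "phenotype", "phenotype_class"}
    if not required.issubset(df.columns):
        raise ValueError(f"annotation TSV must have columns {sorted(required)}")
    return [
        SampleAnnotation(r.sample_id, r.phenotype, r.phenotype_class)
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations: Sequence[SampleAnnotation], path) -> None:
    pd.DataFrame(
        [(a.sample_id, a.phenotype, a.phenotype_class) for a in annotations],
        columns=["sample_id", "phenotype", "phenotype_class"],
    ).to_csv(path, sep="\t", index=False)


def check_annotations(annotations: Sequence[SampleAnnotation], matrix: ExpressionMatrix) -> None:
    """Every annotated sample must exist in the matrix it annotates."""
    known = set(matrix.sample_ids)
    missing = sorted({a.sample_id for a in annotations} - known)
    if missing:
        raise ValueError(f"annotated samples absent from matrix: {missing[:5]}")


@dataclass(frozen=True)
class DataSplit:
    train_sample_ids: tuple[str, ...]
    test_sample_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_sample_ids) & set(self.test_sample_ids):
            raise ValueError("train and test sample sets overlap")


def normalize_upper_quartile_log(
    raw: ExpressionMatrix,
    floor: float = 3.0,
    reference: float | None = None,
) -> ExpressionMatrix:
    """Upper-quartile normalization, log2(1+x) transform and noise floor.

    Each sample is scaled so that its upper quartile (75th percentile of the
    sample's nonzero values) equals ``reference``; by default the reference
    is the mean of the per-sample upper quartiles, so a sample whose values
    already sit at the across-sample mean quartile gets scaling factor 1.
    Values are then log2(1 + x) transformed, and entries below ``floor`` are
    set to 0 (the matrix keeps its shape; low log-scale values are treated
    as noise).
    """
    X = raw.values
    if np.any(X < 0):
        raise ValueError("raw expression values must be non-negative")
    uq = np.empty(raw.n_samples)
    for j, sid in enumerate(raw.sample_ids):
        col = X[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise ValueError(f"sample {sid!r} has all-zero expression")
        uq[j] = np.percentile(nz, 75)
    if reference is None:
        reference = float(uq.mean())
    scaled = X * (reference / uq)[np.newaxis, :]
    logged = np.log2(1.0 + scaled)
    logged[logged < floor] = 0.0
    return ExpressionMatrix(list(raw.gene_ids), list(raw.sample_ids), logged)


def minmax_scale(
    E: ExpressionMatrix, mode: Literal["global", "per_gene"] = "global"
) -> ExpressionMatrix:
    """Affine rescaling onto [0, 1].

    ``global`` uses the matrix-wide min and max (the formula above);
    ``per_gene`` rescales each gene across its samples independently.
    """
    X = E.values
    if mode == "global":
        lo, hi = X.min(), X.max()
        if hi <= lo:
            raise ValueError("matrix is constant; min–max scaling undefined")
        out = (X - lo) / (hi - lo)
    elif mode == "per_gene":
        lo = X.min(axis=1, keepdims=True)
        hi = X.max(axis=1, keepdims=True)
        flat = np.nonzero((hi - lo).ravel() <= 0)[0]
        if flat.size:
            raise ValueError(
                f"constant gene(s) cannot be min–max scaled per gene: "
                f"{[E.gene_ids[i] for i in flat[:5]]}"
            )
        out = (X - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ExpressionMatrix(list(E.gene_ids), list(E.sample_ids), out)


def split_train_test(E: ExpressionMatrix, n_train: int, seed: int) -> DataSplit:
    """Uniform random train/test partition of the samples, seeded."""
    if not 0 < n_train < E.n_samples:
        raise ValueError(f"n_train must be in (0, {E.n_samples}), got {n_train}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(E.n_samples)
    train = tuple(E.sample_ids[i] for i in sorted(perm[:n_train]))
    test = tuple(E.sample_ids[i] for i in sorted(perm[n_train:]))
    return DataSplit(train, test, seed)
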