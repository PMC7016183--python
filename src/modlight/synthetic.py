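"""Synthetic expression compendium with planted modules, phenotypes and PPI.

The generator emulates the statistical structure the pipeline assumes in
real compendia: groups of co-expressed genes (modules) whose activity varies
with cell type, diseases that shift the activity of specific modules, and a
protein-interaction graph that is denser inside modules than between them.

Sample j of cell type t and disease d has a module-activity vector

    z_j = base(t) + delta * mask(d) + jitter_j

and gene g of module M has expression logistic(loading_g * z_j[M]) plus
Gaussian noise, clipped to [0, 1].  Genes outside any module have a constant
logistic baseline plus noise.  The planted disease gene set of d is exactly
the genes of the modules its mask perturbs, so recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .expression import ExpressionMatrix, SampleAnnotation, minmax_scale
from .network import GeneNetwork

__all__ = [
    "SyntheticConfig",
    "SyntheticCompendium",
    "generate",
    "recovery_metrics",
]


@dataclass
class SyntheticConfig:
    """Study conditions for a planted-module compendium.

    Defaults are sized so that a [32, 32, 32] deep autoencoder trains in
    minutes on one CPU while keeping eight well-populated modules, four cell
    types, three diseases and a clearly modular interactome.
    """

    n_genes: int = 2000
    n_samples: int = 600
    n_modules: int = 8
    genes_per_module: int = 100
    n_cell_types: int = 4
    n_diseases: int = 3
    disease_effect: float = 1.5   # shift of perturbed-module activity, dimensionless
    noise_sd: float = 0.05
    jitter_sd: float = 0.25       # per-sample activity jitter around the cell-type base
    control_fraction: float = 0.5
    ppi_p_in: float = 0.2
    ppi_p_out: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.genes_per_module * self.n_modules > self.n_genes:
            raise ValueError("module genes exceed n_genes")
        if not 0 <= self.ppi_p_out <= self.ppi_p_in <= 1:
            raise ValueError("need 0 <= ppi_p_out <= ppi_p_in <= 1")
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise_sd and jitter_sd must be non-negative")
        if self.n_diseases > self.n_modules:
            raise ValueError("each disease perturbs a distinct module")
        if not 0 < self.control_fraction < 1:
            raise ValueError("control_fraction must be in (0, 1)")


@dataclass
class SyntheticCompendium:
    expression: ExpressionMatrix        # normalized to [0, 1]
    annotations: list[SampleAnnotation]
    network: GeneNetwork
    disease_gene_sets: dict[str, set[str]]
    gene_module: dict[str, int]         # gene id -> module index (module genes only)
    phenotype_activity: dict[str, np.ndarray]  # label -> module-activity vector
    config: SyntheticConfig


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate(config: SyntheticConfig) -> SyntheticCompendium:
    """Draw one compendium; bitwise reproducible from the config's seed."""
    rng = np.random.default_rng(config.seed)
    n_g, n_s, m = config.n_genes, config.n_samples, config.n_modules
    gpm = config.genes_per_module

    gene_ids = [f"G{i:05d}" for i in range(n_g)]
    sample_ids = [f"S{j:04d}" for j in range(n_s)]
    # genes 0..m*gpm-1 belong to modules, in blocks; the rest are background
    module_of_gene = np.full(n_g, -1, dtype=int)
    for mod in range(m):
        module_of_gene[mod * gpm:(mod + 1) * gpm] = mod

    cell_types = [f"celltype_{t}" for t in range(config.n_cell_types)]
    diseases = [f"disease_{d}" for d in range(config.n_diseases)]
    perturbed = rng.choice(m, size=config.n_diseases, replace=False)
    mask = {dis: np.eye(m)[perturbed[d]] for d, dis in enumerate(diseases)}
    # Cell-type identity programs vary freely across cell types; disease-response
    # modules are quiescent at baseline (near-zero activity in every healthy
    # state) and activated by delta in the disease state, mirroring the
    # disease-module premise that disease programs are off in controls.
    base = {}
    quiescent = np.isin(np.arange(m), perturbed)
    for ct in cell_types:
        b = rng.normal(0.0, 1.0, size=m)
        b[quiescent] = rng.normal(0.0, 0.2, size=quiescent.sum())
        base[ct] = b

    # sample phenotypes: cell type uniform; disease or control
    ct_of_sample = rng.integers(0, config.n_cell_types, size=n_s)
    is_control = rng.random(n_s) < config.control_fraction
    dis_of_sample = rng.integers(0, config.n_diseases, size=n_s)

    Z = np.empty((m, n_s))
    annotations: list[SampleAnnotation] = []
    for j, sid in enumerate(sample_ids):
        ct = cell_types[ct_of_sample[j]]
        z = base[ct].copy()
        if not is_control[j]:
            dis = diseases[dis_of_sample[j]]
            z = z + config.disease_effect * mask[dis]
            annotations.append(SampleAnnotation(sid, dis, "disease"))
        else:
            annotations.append(SampleAnnotation(sid, "control", "control"))
        annotations.append(SampleAnnotation(sid, ct, "cell_type"))
        Z[:, j] = z
    Z += rng.normal(0.0, config.jitter_sd, size=Z.shape)

    loadings = rng.uniform(0.5, 1.5, size=n_g) * rng.choice([-1.0, 1.0], size=n_g)
    X = np.empty((n_g, n_s))
    in_module = module_of_gene >= 0
    X[in_module, :] = _logistic(
        loadings[in_module, np.newaxis] * Z[module_of_gene[in_module], :]
    )
    # background genes: constant logistic baseline
    bg_baseline = rng.normal(0.0, 0.5, size=(~in_module).sum())
    X[~in_module, :] = _logistic(bg_baseline)[:, np.newaxis]
    if config.noise_sd > 0:
        X += rng.normal(0.0, config.noise_sd, size=X.shape)
    np.clip(X, 0.0, 1.0, out=X)
    expr = minmax_scale(ExpressionMatrix(gene_ids, sample_ids, X), mode="global")

    network = _module_ppi(gene_ids, module_of_gene, config, rng)

    disease_gene_sets = {
        dis: {gene_ids[i] for i in np.nonzero(module_of_gene == perturbed[d])[0]}
        for d, dis in enumerate(diseases)
    }
    gene_module = {
        gene_ids[i]: int(module_of_gene[i]) for i in np.nonzero(in_module)[0]
    }
    phenotype_activity = {ct: base[ct] for ct in cell_types}
    phenotype_activity.update(
        {dis: config.disease_effect * mask[dis] for dis in diseases}
    )
    phenotype_activity["control"] = np.zeros(m)

    return SyntheticCompendium(
        expr, annotations, network, disease_gene_sets, gene_module,
        phenotype_activity, config,
    )


def _module_ppi(
    gene_ids: list[str],
    module_of_gene: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> GeneNetwork:
    """Planted-partition interactome: dense within modules, sparse elsewhere."""
    n_g = len(gene_ids)
    edges: list[tuple[int, int]] = []
    # within-module pairs, explicit Bernoulli draws
    for mod in range(config.n_modules):
        members = np.nonzero(module_of_gene == mod)[0]
        iu, ju = np.triu_indices(len(members), k=1)
        keep = rng.random(iu.size) < config.ppi_p_in
        edges.extend(zip(members[iu[keep]], members[ju[keep]]))
    # cross pairs: draw the count, then sample pairs uniformly with rejection
    n_pairs_total = n_g * (n_g - 1) // 2
    gpm = config.genes_per_module
    n_within = config.n_modules * gpm * (gpm - 1) // 2
    n_cross_pairs = n_pairs_total - n_within
    n_cross_edges = rng.binomial(n_cross_pairs, config.ppi_p_out)
    seen: set[tuple[int, int]] = set()
    while len(seen) < n_cross_edges:
        draw = rng.integers(0, n_g, size=(n_cross_edges - len(seen) + 16, 2))
        for a, b in draw:
            if a == b:
                continue
            if module_of_gene[a] >= 0 and module_of_gene[a] == module_of_gene[b]:
                continue
            pair = (int(min(a, b)), int(max(a, b)))
            if pair in seen:
                continue
            seen.add(pair)
            if len(seen) == n_cross_edges:
                break
    edges.extend(seen)
    named = [(gene_ids[a], gene_ids[b], 1.0) for a, b in edges]
    return GeneNetwork.from_edges(named, nodes=gene_ids, score_threshold=0.0)


def recovery_metrics(
    predicted: list[str], truth: set[str], k: int
) -> tuple[float, float]:
    """precision@k and recall@k of a ranked prediction against a planted set."""
    if not truth:
        raise ValueError("empty truth set")
    if k > len(predicted):
        raise ValueError(f"k={k} exceeds prediction length {len(predicted)}")
    hits = len(set(predicted[:k]) & set(truth))
    return hits / k, hits / len(truth)
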