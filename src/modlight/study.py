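"""Reference studies on synthetic compendia.

Each function runs one self-contained experiment on a planted-module
compendium and returns plain numbers: disease-gene recovery by reverse
training, interactome localization of light-up gene lists, phenotype
coherence of the compressed embedding, and reconstruction capacity as a
function of width.  The test suite and the acceptance script both call
these runners so the measured quantities are computed in exactly one place.

Problem sizes are chosen so each study runs in minutes on one CPU: the
default compendium (2000 genes, 600 samples, eight 100-gene modules) for
the recovery/localization/embedding studies, and a reduced compendium
(600 genes, 300 samples, eight 60-gene modules) for the width sweep.  The
autoencoder is trained with ADAM at learning rate 1e-3 for these
problem sizes (the compendium-scale default of 1e-4 is tuned for matrices
two orders of magnitude larger); all other optimizer settings keep their
defaults.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .autoencoder import (
    AEArchitecture,
    AEModel,
    TrainConfig,
    encode,
    fit_metrics,
    init_model,
    train,
)
from .disease import predict_disease_genes
from .embedding import compare_embeddings, pca2
from .enrichment import GeneSet, hypergeom_enrichment
from .lightup import light_up_all
from .network import localization_sweep
from .synthetic import SyntheticCompendium, SyntheticConfig, generate, recovery_metrics

__all__ = [
    "train_default_ae",
    "recovery_study",
    "localization_study",
    "embedding_study",
    "capacity_study",
    "SYNTH_TRAIN_CONFIG",
]

#: Training settings for the synthetic problem sizes used throughout.
SYNTH_TRAIN_CONFIG = TrainConfig(learning_rate=1e-3, epochs=1500)

#: Reduced compendium for the width sweep (still eight modules).
CAPACITY_CONFIG = SyntheticConfig(
    n_genes=600, n_samples=300, genes_per_module=60,
)


def train_default_ae(
    comp: SyntheticCompendium,
    seed: int,
    hidden_widths: tuple[int, ...] = (32, 32, 32),
    config: TrainConfig | None = None,
) -> AEModel:
    """Train the canonical deep autoencoder on a compendium."""
    if config is None:
        config = replace(SYNTH_TRAIN_CONFIG, shuffle_seed=seed)
    arch = AEArchitecture(n_features=comp.expression.n_genes,
                          hidden_widths=hidden_widths)
    model = init_model(arch, seed=seed)
    train(model, comp.expression, config=config)
    return model


def recovery_study(
    seed: int,
    comp: SyntheticCompendium | None = None,
    model: AEModel | None = None,
    layer: int = 4,
    top_enrich: int = 100,
) -> dict:
    """Reverse-training recovery of planted disease genes at one layer.

    Returns per-disease precision@50 and hypergeometric enrichment p of the
    top 100 predicted genes against the planted set, plus the trained
    model's global R².
    """
    if comp is None:
        comp = generate(SyntheticConfig(seed=seed))
    if model is None:
        model = train_default_ae(comp, seed)
    X = comp.expression
    diseases = sorted(comp.disease_gene_sets)
    preds = predict_disease_genes(
        X, comp.annotations, model, layer, diseases + ["control"],
        config=replace(SYNTH_TRAIN_CONFIG, shuffle_seed=seed),
        repeats=3, seeds=[seed * 1000 + r for r in range(3)],
    )
    precision, enrichment_p = {}, {}
    for d in diseases:
        truth = comp.disease_gene_sets[d]
        ranked = preds[d].ranked_genes
        precision[d], _ = recovery_metrics(ranked, truth, 50)
        enr = hypergeom_enrichment(ranked[:top_enrich], GeneSet(d, truth), X.gene_ids)
        enrichment_p[d] = enr.p_value
    return {
        "r2_global": fit_metrics(model, X).r2_global,
        "precision_at_50": precision,
        "mean_precision_at_50": float(np.mean(list(precision.values()))),
        "enrichment_p": enrichment_p,
        "max_enrichment_p": max(enrichment_p.values()),
    }


def localization_study(
    seed: int,
    comp: SyntheticCompendium | None = None,
    model: AEModel | None = None,
    cutoff: int = 100,
    null_samples: int = 30,
) -> dict:
    """Harmonic-distance localization of light-up top genes, layers 1 vs 3.

    Layer indices follow the hidden-layer numbering (first = absolute
    layer 2, third = absolute layer 4 of the five-layer deep model).
    """
    if comp is None:
        comp = generate(SyntheticConfig(seed=seed))
    if model is None:
        model = train_default_ae(comp, seed)
    X = comp.expression
    res1 = light_up_all(model, X.gene_ids, 2)
    res3 = light_up_all(model, X.gene_ids, 4)
    profiles = localization_sweep(
        comp.network, res1 + res3, cutoffs=(cutoff,), null_samples=null_samples,
        seed=seed, with_betweenness=False,
    )
    d1 = np.array([p.harmonic_distance for p in profiles if p.layer == 2])
    d3 = np.array([p.harmonic_distance for p in profiles if p.layer == 4])
    null_mean = profiles[0].null_mean
    return {
        "layer1_mean_distance": float(d1.mean()),
        "layer3_mean_distance": float(d3.mean()),
        "null_mean_distance": float(null_mean),
        "frac_layer1_below_null": float(np.mean(d1 < null_mean)),
        "frac_layer3_below_null": float(np.mean(d3 < null_mean)),
        "frac_layer1_below_layer3_mean": float(np.mean(d1 < d3.mean())),
    }


def embedding_study(
    seed: int,
    comp: SyntheticCompendium | None = None,
    model: AEModel | None = None,
    layer: int = 4,
) -> dict:
    """Silhouette comparison: layer-3 compressed PCA vs raw PCA.

    Cell-type groups are evaluated on control samples only (mirroring the
    normal-cell-type filter); disease groups on all samples.  Counts groups
    where the compressed embedding's silhouette is at least the raw one.
    """
    if comp is None:
        comp = generate(SyntheticConfig(seed=seed))
    if model is None:
        model = train_default_ae(comp, seed)
    X = comp.expression
    Z = encode(model, X, layer)
    sid = {s: j for j, s in enumerate(X.sample_ids)}
    ct = {a.sample_id: a.phenotype for a in comp.annotations
          if a.phenotype_class == "cell_type"}
    status = {a.sample_id: a.phenotype for a in comp.annotations
              if a.phenotype_class in ("disease", "control")}
    favored = 0
    groups = 0
    deltas = {}
    # cell types among control samples
    ctrl = [s for s in X.sample_ids if status[s] == "control"]
    idx = [sid[s] for s in ctrl]
    labels = [ct[s] for s in ctrl]
    ae_c = pca2(Z[:, idx].T, ctrl, source=f"deepAE_layer_{layer - 1}_PCA")
    raw_c = pca2(X.values[:, idx].T, ctrl, source="raw_PCA")
    res = compare_embeddings(ae_c, raw_c, labels, margin=0.0)
    favored += res.n_favored
    groups += res.n_groups
    deltas.update(dict(zip(res.table["group"], res.table["delta"])))
    # diseases among all samples
    all_labels = [status[s] for s in X.sample_ids]
    ae_a = pca2(Z.T, X.sample_ids, source=f"deepAE_layer_{layer - 1}_PCA")
    raw_a = pca2(X.values.T, X.sample_ids, source="raw_PCA")
    dis = sorted(comp.disease_gene_sets)
    res_d = compare_embeddings(ae_a, raw_a, all_labels, margin=0.0, groups=dis)
    favored += res_d.n_favored
    groups += res_d.n_groups
    deltas.update(dict(zip(res_d.table["group"], res_d.table["delta"])))
    return {
        "n_favored": int(favored),
        "n_groups": int(groups),
        "fraction_favored": favored / groups,
        "delta_by_group": deltas,
    }


def capacity_study(
    seeds: tuple[int, ...] = (0, 1, 2),
    widths: tuple[int, ...] = (4, 8, 16, 32),
    config: SyntheticConfig | None = None,
    epochs: int = 1000,
) -> dict:
    """Global R² of the deep autoencoder as a function of hidden width.

    Runs on the reduced rank-8 compendium; returns the per-width R² mean
    across seeds (the capacity curve) and the full seed × width table.
    """
    base = config if config is not None else CAPACITY_CONFIG
    r2 = np.zeros((len(seeds), len(widths)))
    for i, seed in enumerate(seeds):
        comp = generate(replace(base, seed=seed))
        for j, w in enumerate(widths):
            model = train_default_ae(
                comp, seed, hidden_widths=(w, w, w),
                config=replace(SYNTH_TRAIN_CONFIG, epochs=epochs, shuffle_seed=seed),
            )
            r2[i, j] = fit_metrics(model, comp.expression).r2_global
    return {
        "widths": list(widths),
        "mean_r2": [float(v) for v in r2.mean(axis=0)],
        "r2_table": r2.tolist(),
    }
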