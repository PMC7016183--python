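"""End-to-end workflow orchestration.

Composes the full analysis on user or synthetic data: normalization →
autoencoder training → light-up of every hidden layer → interactome
localization sweep → reverse-training disease-gene prediction →
enrichment against disease gene sets → embedding comparison.  Every stage
writes plain TSV/JSON artifacts into the output directory together with a
run manifest (package version, seeds, configuration hash) so any number in
a report is traceable to a (seed, config) pair.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .autoencoder import (
    AEArchitecture,
    TrainConfig,
    encode,
    fit_metrics,
    init_model,
    save_model,
    train,
)
from .disease import predict_disease_genes
from .embedding import compare_embeddings, pca2
from .enrichment import hypergeom_enrichment, fisher_combined, read_gmt
from .expression import (
    ExpressionMatrix,
    minmax_scale,
    normalize_upper_quartile_log,
    read_annotations,
)
from .lightup import light_up_all, results_to_frame
from .network import DEFAULT_CUTOFFS, load_network, localization_sweep

log = logging.getLogger("modlight")

__all__ = ["PipelineConfig", "run_pipeline", "load_pipeline_config"]

EXIT_CONFIG_ERROR = 2
EXIT_DATA_ERROR = 3
EXIT_NUMERIC_ERROR = 4


@dataclass
class PipelineConfig:
    """Paths, architecture, training and analysis settings for one run."""

    expression: str
    output_dir: str
    annotations: str | None = None
    network: str | None = None
    gene_sets: str | None = None
    network_score_threshold: float = 0.0
    normalize: str = "minmax"          # none | minmax | uqua_log_minmax
    hidden_widths: tuple[int, ...] = (32, 32, 32)
    activation: str = "sigmoid"
    sparse_l1: float = 0.0
    denoising_sd: float = 0.0
    train: dict = field(default_factory=dict)   # TrainConfig overrides
    layers: tuple[int, ...] = (1, 2, 3)         # hidden-layer numbers
    phenotype_classes: tuple[str, ...] = ("disease",)
    repeats: int = 3
    top_k: int = 1000
    cutoffs: tuple[int, ...] = DEFAULT_CUTOFFS
    null_samples: int = 30
    with_betweenness: bool = False
    embedding_margin: float = 0.1
    seed: int = 0

    def train_config(self) -> TrainConfig:
        return TrainConfig(**{"shuffle_seed": self.seed, **self.train})

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    try:
        cfg = PipelineConfig(**raw)
    except TypeError as exc:
        raise ValueError(f"invalid pipeline config: {exc}") from exc
    cfg.hidden_widths = tuple(cfg.hidden_widths)
    cfg.layers = tuple(cfg.layers)
    cfg.cutoffs = tuple(cfg.cutoffs)
    cfg.phenotype_classes = tuple(cfg.phenotype_classes)
    return cfg


def _hidden_to_absolute(layer: int, n_hidden: int) -> int:
    if not 1 <= layer <= n_hidden:
        raise ValueError(f"hidden layer must be in [1, {n_hidden}], got {layer}")
    return layer + 1


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full workflow; returns the manifest dictionary.

    Partial outputs are kept on failure and the manifest records the stage
    that failed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": _version,
        "seed": config.seed,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": [],
        "status": "running",
    }

    def checkpoint(stage: str) -> None:
        manifest["stages"].append(stage)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    try:
        log.info("reading expression matrix from %s", config.expression)
        E = ExpressionMatrix.from_tsv(config.expression)
        if config.normalize == "uqua_log_minmax":
            E = minmax_scale(normalize_upper_quartile_log(E))
        elif config.normalize == "minmax":
            E = minmax_scale(E)
        elif config.normalize != "none":
            raise ValueError(f"unknown normalize mode {config.normalize!r}")
        if E.values.min() < 0 or E.values.max() > 1:
            raise ValueError("expression values must lie in [0, 1] after normalization")
        checkpoint("normalize")

        arch = AEArchitecture(
            n_features=E.n_genes,
            hidden_widths=config.hidden_widths,
            activation=config.activation,
            sparse_l1=config.sparse_l1,
            denoising_sd=config.denoising_sd,
        )
        model = init_model(arch, seed=config.seed)
        tc = config.train_config()
        log.info("training %s autoencoder for %d epochs", arch.hidden_widths, tc.epochs)
        model, history = train(model, E, config=tc)
        metrics = fit_metrics(model, E)
        save_model(model, out / "model.modlight.zip")
        pd.DataFrame(history).to_csv(out / "training_history.tsv", sep="\t", index=False)
        json.dump(
            {"r2_global": metrics.r2_global,
             "error_global": metrics.error_global,
             "r2_genewise_median": float(np.nanmedian(metrics.r2_genewise))},
            open(out / "fit_metrics.json", "w"), indent=1,
        )
        checkpoint("train_ae")

        n_hidden = len(config.hidden_widths)
        lightups = {}
        for layer in config.layers:
            abs_layer = _hidden_to_absolute(layer, n_hidden)
            results = light_up_all(model, E.gene_ids, abs_layer)
            lightups[layer] = results
            results_to_frame(results).to_csv(
                out / f"lightup_layer{layer}.tsv", sep="\t", index=False
            )
        checkpoint("light_up")

        if config.network:
            net = load_network(config.network, config.network_score_threshold)
            all_results = [r for rs in lightups.values() for r in rs]
            profiles = localization_sweep(
                net, all_results, cutoffs=config.cutoffs,
                null_samples=config.null_samples, seed=config.seed,
                with_betweenness=config.with_betweenness,
            )
            pd.DataFrame([
                {"layer": p.layer - 1, "node": p.node, "cutoff": p.cutoff,
                 "harmonic_distance": p.harmonic_distance,
                 "mean_betweenness": p.mean_betweenness,
                 "null_mean": p.null_mean, "null_sd": p.null_sd, "z": p.z}
                for p in profiles
            ]).to_csv(out / "localization.tsv", sep="\t", index=False)
            checkpoint("localization")
        else:
            log.warning("no PPI network given; localization sweep skipped")

        predictions = {}
        if config.annotations:
            annotations = read_annotations(config.annotations)
            phenotypes = sorted({
                a.phenotype for a in annotations
                if a.phenotype_class in config.phenotype_classes
            })
            if not phenotypes:
                raise ValueError(
                    f"no phenotypes of class {config.phenotype_classes} in annotations"
                )
            for layer in config.layers:
                abs_layer = _hidden_to_absolute(layer, n_hidden)
                preds = predict_disease_genes(
                    E, annotations, model, abs_layer, phenotypes,
                    config=tc, repeats=config.repeats,
                    seeds=[config.seed * 100 + r for r in range(config.repeats)],
                )
                predictions[layer] = preds
                for p, pred in preds.items():
                    pred.to_frame().head(config.top_k).to_csv(
                        out / f"disease_genes_layer{layer}_{p}.tsv",
                        sep="\t", index=False,
                    )
            checkpoint("predict_disease")

            if config.gene_sets:
                gene_sets = {gs.name: gs for gs in read_gmt(config.gene_sets)}
                rows = []
                for layer, preds in predictions.items():
                    for p, pred in preds.items():
                        if p not in gene_sets:
                            continue
                        enr = hypergeom_enrichment(
                            pred.ranked_genes[:config.top_k], gene_sets[p], E.gene_ids
                        )
                        rows.append({
                            "layer": layer, "phenotype": p, "k": enr.k, "n": enr.n,
                            "K": enr.K, "N": enr.N, "p_value": enr.p_value,
                            "odds_ratio": enr.odds_ratio,
                            "enrichment_score": enr.enrichment_score,
                        })
                enrich = pd.DataFrame(rows)
                enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
                combined = {
                    str(layer): fisher_combined(list(g["p_value"]))
                    for layer, g in enrich.groupby("layer")
                } if len(enrich) else {}
                json.dump(combined, open(out / "fisher_combined.json", "w"), indent=1)
                checkpoint("enrichment")

            # embedding comparison on the deepest requested layer
            layer = max(config.layers)
            Z = encode(model, E, _hidden_to_absolute(layer, n_hidden))
            labels_map = {
                a.sample_id: a.phenotype for a in annotations
                if a.phenotype_class in config.phenotype_classes
            }
            labelled = [s for s in E.sample_ids if s in labels_map]
            if len(set(labels_map[s] for s in labelled)) >= 2:
                idx = [E.sample_ids.index(s) for s in labelled]
                labels = [labels_map[s] for s in labelled]
                ae_c = pca2(Z[:, idx].T, labelled, source=f"deepAE_layer_{layer}_PCA")
                raw_c = pca2(E.values[:, idx].T, labelled, source="raw_PCA")
                cmpres = compare_embeddings(
                    ae_c, raw_c, labels, margin=config.embedding_margin
                )
                cmpres.table.to_csv(out / "silhouette.tsv", sep="\t", index=False)
                json.dump(
                    {"margin": cmpres.margin, "n_favored": cmpres.n_favored,
                     "n_groups": cmpres.n_groups, "p_value": cmpres.p_value,
                     "odds": cmpres.odds},
                    open(out / "silhouette_summary.json", "w"), indent=1,
                )
                checkpoint("embedding")
        else:
            log.warning("no annotations given; disease prediction skipped")

        manifest["status"] = "ok"
        checkpoint("done")
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise
    return manifest
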