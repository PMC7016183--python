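# modlight

**Disease-module discovery from the compressed transcriptional space of a
deep autoencoder.**

Disease genes tend to be functionally related and their protein products
interconnected — they form *disease modules*. Classical module discovery
leans on protein–protein interaction (PPI) networks, which are incomplete
and biased toward well-studied genes. `modlight` takes the data-driven
route: train a compressing autoencoder on a large expression compendium,
then interrogate the learned representation —

- **light-up** — interpret each hidden node by setting its activation to
  the sigmoid's maximum (others zero) and forward-propagating to the gene
  space, `x^k = f^k(W^k x^{k-1} + b^k)`, ranking genes by the output
  response;
- **reverse training** — fit a small supervised network from phenotype
  indicator vectors to the compressed codes, stack it onto the decoder,
  and score genes for phenotype *p* as `s^p = W^L x^{L-1}` (final weight
  matrix, no bias, no activation), ranking by `|s^p|`;
- **evaluation** — PPI localization of light-up lists (harmonic mean
  shortest-path distance, betweenness centrality, random-set nulls),
  hypergeometric enrichment of predicted genes against disease gene sets
  (with Fisher's combined p across diseases), and silhouette comparison of
  the compressed embedding against plain PCA with exact binomial tests.

The package is aimed at computational biologists who want to run the
method on their own gene × sample matrices (TSV), annotations (TSV),
STRING-style edge lists and GMT gene sets — or reproduce its behaviour on
fully synthetic compendia with planted modules, phenotypes and
interactomes (`modlight.synthetic`), which is how the test suite
exercises every stage without downloads.

## Worked example

Simulate a compendium, train a deep autoencoder, and recover the planted
disease genes:

```python
from modlight import (SyntheticConfig, generate, AEArchitecture, TrainConfig,
                      init_model, train, fit_metrics, predict_disease_genes,
                      hypergeom_enrichment, GeneSet)

comp = generate(SyntheticConfig(seed=1))          # 2000 genes × 600 samples
X = comp.expression

model = init_model(AEArchitecture(n_features=X.n_genes,
                                  hidden_widths=(32, 32, 32)), seed=1)
train(model, X, config=TrainConfig(learning_rate=1e-3, epochs=1500,
                                   shuffle_seed=1))
print(f"global R2 = {fit_metrics(model, X).r2_global:.3f}")

diseases = sorted(comp.disease_gene_sets)
preds = predict_disease_genes(X, comp.annotations, model, layer=4,
                              phenotypes=diseases + ["control"],
                              config=TrainConfig(learning_rate=1e-3,
                                                 epochs=1500),
                              repeats=3, seeds=[11, 12, 13])
for d in diseases:
    truth = comp.disease_gene_sets[d]
    top100 = preds[d].ranked_genes[:100]
    enr = hypergeom_enrichment(top100, GeneSet(d, truth), X.gene_ids)
    print(f"{d}: {enr.k}/100 planted genes in top 100, p = {enr.p_value:.2e}")
```

Output:

```
global R2 = 0.890
disease_0: 81/100 planted genes in top 100, p = 1.80e-106
disease_1: 67/100 planted genes in top 100, p = 3.73e-74
disease_2: 61/100 planted genes in top 100, p = 2.05e-62
```

The deep autoencoder explains 89 % of the expression variance with 32
latent nodes per layer, and the reverse-training score places 61–81 of
each disease's 100 planted genes in its top-100 list (hypergeometric
p ≤ 1e-62 against a 2000-gene universe).

The same workflow runs from the shell:

```bash
modlight simulate --out sim/ --seed 1
modlight train-ae --expression sim/expression.tsv --model-out model.zip \
    --widths 32,32,32 --learning-rate 1e-3 --epochs 1500 --seed 1
modlight predict-disease --model model.zip --expression sim/expression.tsv \
    --annotations sim/annotations.tsv --layer 3 --out-dir predictions/
modlight run-all --config pipeline.yaml   # the whole pipeline from YAML
```

A complete pipeline configuration lives at `docs/pipeline.example.yaml`.

See `docs/methods.md` for the model, its assumptions, all tunable
parameters, and what the synthetic studies do and do not demonstrate.

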