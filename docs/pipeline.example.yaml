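# Example configuration for `modlight run-all --config pipeline.yaml`.
# Paths point at the artifacts written by `modlight simulate --out sim/`.
expression: sim/expression.tsv
annotations: sim/annotations.tsv
network: sim/network.tsv
gene_sets: sim/disease_genes.gmt
output_dir: run/
normalize: none            # simulate already writes [0, 1] values
hidden_widths: [32, 32, 32]
train:
  learning_rate: 1.0e-3    # synthetic-scale setting; compendium default 1.0e-4
  epochs: 1500
  batch_size: 256
layers: [1, 2, 3]          # hidden layers to light up and reverse-train
phenotype_classes: [disease]
repeats: 3
top_k: 1000
cutoffs: [100, 200, 400, 800, 1600]
null_samples: 30
embedding_margin: 0.1
seed: 1
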