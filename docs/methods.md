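# Methods

`modlight` implements a pipeline for discovering disease-associated gene
modules from bulk transcriptional compendia without using a biological
network as prior knowledge: a compressing autoencoder learns a low-
dimensional representation of expression, hidden nodes are interpreted by
forward-propagating maximal single-node activations ("light-up"), and
disease genes are prioritized by training a phenotype-to-code network in
reverse and stacking it onto the decoder. Interactome localization,
gene-set enrichment and embedding-coherence statistics quantify what each
layer of the representation has captured.

## Model

### Autoencoder

The autoencoder is a stack of dense layers with sigmoid activations
throughout (data live in [0, 1] after normalization, so a sigmoid output is
natural). Layers are numbered 1..L; the forward recursion is

    x^k = f^k(W^k x^{k-1} + b^k),   k = 2..L,

with x^1 the normalized expression vector of one sample. The *shallow*
model has one hidden layer (two weight matrices); the *deep* model has
three hidden layers of equal width H — encoder and decoder each contribute
two weight sets, so widths (H, H, H) over N genes give matrices of shapes
H×N, H×H, H×H, N×H. Weights are initialized with seeded symmetric-uniform
(Glorot) draws, biases at zero.

Training minimizes mean-squared reconstruction error with mini-batch ADAM
(learning rate 1e-4, β₁ 0.9, β₂ 0.999, ε 1e-8, per-step learning-rate decay
1e-6 in the Keras convention lr/(1+decay·t), batch size 256). Two variants:
*denoising* (inputs corrupted with additive N(0, σ) noise and clipped back
to [0, 1]; the target stays clean) and *sparse* (L1 penalty on all weight
matrices added to the loss). Epoch count is a free parameter with optional
early stopping on validation loss (patience-based, best weights restored);
reconstruction quality is summarized as R² both globally (variance of all
entries around the global mean) and per gene (each gene's own variance);
`error = 1 − R²`. Genes with zero variance have undefined gene-wise R² and
are reported as NaN.

The default learning rate is appropriate for compendium-scale data
(tens of thousands of genes and samples). For the synthetic problem sizes
used in the studies (≈2000 genes × 600 samples) the package trains with
learning rate 1e-3 for 1500 epochs (`modlight.study.SYNTH_TRAIN_CONFIG`):
at these sizes 1e-4 would need an order of magnitude more epochs to leave
the underfit regime (R² ≈ 0.82 versus ≈ 0.89 in a fraction of the time),
and underfit codes visibly degrade downstream gene recovery. All other
optimizer settings keep their defaults.

### Normalization

RNA-seq style counts are upper-quartile normalized per sample (75th
percentile of the sample's nonzero values, scaled to the mean of the
per-sample upper quartiles — the reference is configurable and can be
fixed externally, in which case the transform is exactly invariant to
rescaling any single sample), then log2(1+x) transformed; log values below
3.0 are treated as noise and set to zero, keeping the matrix dense and
shaped. Finally the whole matrix is min–max rescaled onto [0, 1] using the
global minimum and maximum; a per-gene mode is available. The global mode
is the default (min(E), max(E) of the whole matrix), keeping relative
magnitudes between genes intact.

### Light-up

A hidden node h of layer p is interpreted by setting x^p = e_h (the
activation function's supremum, 1.0 for sigmoid, at position h; zero
elsewhere) and applying the recursion for k = p+1..L. Genes are ranked by
the output activation x^L, descending, ties broken by ascending gene index
for determinism. An optional mode subtracts the response to an all-zero
input at the same layer before ranking; it is off by default (the raw
output is what the procedure ranks by definition), but it is useful
diagnostically because the raw response of a deep layer carries each
gene's baseline reconstruction, which can pull non-specific,
high-baseline genes into the top of the list.

Rank cutoffs are swept by powers of two from 100 (100, 200, …, 6400;
10,000 is the stated upper bound but is not itself a power-of-two step, so
the sweep stops at 6400).

### Reverse training and disease scores

Given a trained autoencoder and phenotype annotations:

1. Expression is compressed at a chosen hidden layer p into codes
   s_{k,j} (H × S).
2. A one-hidden-layer supervised net — input width P (number of
   phenotypes), sigmoid hidden layer and linear output both of width H —
   is trained by ADAM/MSE from the indicator design matrix
   c_{i,j} = δ_{ip} to the codes. Samples carrying none of the chosen
   phenotypes contribute all-zero input columns, so the net's bias path
   absorbs the background state and the weights carry phenotype-specific
   structure.
3. The supervised net is stacked onto the decoder layers p+1..L. An
   optional moment-matching step affinely rescales the supervised output
   layer's weights and bias to the elementwise mean/variance of the
   autoencoder's W^p and b^p. It is **off by default**: the elementwise
   shift adds a rank-one term (uniform across code dimensions) to the
   predicted code that measurably scrambles downstream gene rankings,
   and the supervised output already lives on the scale of the codes it
   was fitted to. The transform is recorded in the stacked model when
   used.
4. The phenotype indicator r^p is propagated through the stacked net with
   activations applied for 1 < k ≤ L−1; the score is s^p = W^L x^{L−1} —
   the final weight matrix applied with **no bias and no activation** —
   and genes are ranked by |s^p|.

Omitting the final bias removes each gene's bias-driven baseline from the
score, but not the part of the baseline that the decoder carries through
the mean code (sigmoid codes are positive, so W^L·mean-code is a
substantial common component). The score therefore measures the decoded
*absolute activity* of the phenotype state, not a contrast against
controls; it identifies genes whose modules are distinctively active (or
suppressed) in the phenotype. Steps 2–4 are repeated (default three
times) with fresh seeds; the aggregate ranking uses the mean absolute
score, with per-gene standard deviations reported.

A naive supervised baseline trains the same one-hidden-layer architecture
directly from phenotype indicators to expression (hidden width 512 at
compendium scale, configurable) and is scored identically
(s^p = W_out · hidden, no bias).

### Localization statistics

Gene lists are assessed in an interaction network (STRING-style edge list,
thresholded on confidence; unweighted shortest paths). The *harmonic
average distance* of a set is (number of unordered pairs) / Σ 1/d(u,v),
with disconnected pairs — including genes absent from the network, which
are treated as isolated rather than dropped — contributing zero reciprocal
distance; +∞ when no pair connects. *Mean betweenness* averages
pair-normalized shortest-path betweenness (normalization (n−1)(n−2)/2;
pivot-sampled approximation available for large graphs) over the set, with
missing genes counted at zero. Null distributions come from equal-size
uniform draws of network nodes, seeded, shared per cutoff.

### Embedding coherence

A hidden layer's codes are visualized by their first two principal
components (mean-centered, unscaled; deterministic sign convention —
largest-magnitude loading positive). For each phenotype group the
silhouette index is computed one-vs-rest on the 2-D coordinates: for each
member a = mean distance to other members, b = mean distance to all
non-members, silhouette (b−a)/max(a,b), group value the member mean;
singleton groups score 0 by convention, as does the 0/0 case of coincident
points. The one-vs-rest reading is a design choice — no partner
clustering is defined for a single phenotype group — and is what the
comparison statistics are computed on. Groups where the compressed
embedding beats the raw-expression PCA by at least a margin (default 0.1)
are counted, and the count among N groups is referred to an exact binomial
tail with success probability 0.5, with simple odds n/(N−n). Both tail
conventions are implemented (inclusive `geq` default, strict `gt`); the
reference cell-type comparison statistics follow the strict tail and the
disease comparisons the inclusive one, so which convention a comparison
uses is an explicit argument.

### Enrichment

Predicted gene lists are validated against disease gene sets with the
upper-tail hypergeometric (Fisher) test, with the gene set intersected
with the universe first. The universe defaults to all genes present in
the trained model. The odds ratio is the 2×2 cross-product with a Haldane
0.5 continuity correction when a denominator cell is empty. P-values
combine across diseases with Fisher's method (−2Σln p ~ χ² with 2m df).
Disease gene sets can be built from SNP and gene intervals (BED,
half-open 0-based): each SNP maps to its closest gene (gap
max(0, s₁−e₂, s₂−e₁); distance 0 when overlapping; ties keep all genes).

## Synthetic compendia

The generator plants the structure the method assumes so every stage is
testable without downloads. Sample j of cell type t and disease d has
module-activity vector z_j = base(t) + δ·mask(d) + jitter (jitter sd 0.25);
gene g of module M has expression logistic(loading_g · z_j[M]) with
loadings uniform in ±[0.5, 1.5], plus N(0, σ) noise, clipped to [0, 1] and
globally min–max rescaled. Genes outside modules sit at a constant
logistic baseline (logit ~ N(0, 0.5)) plus noise. The interactome is a
planted partition: edge probability 0.2 within modules, 0.002 elsewhere,
over all genes. Defaults: 2000 genes, 600 samples, eight 100-gene
modules, four cell types, three diseases (each perturbing one distinct
module, δ = 1.5), σ = 0.05, half the samples controls — sized so a
(32, 32, 32) deep autoencoder trains in about a minute on one CPU.

Cell-type identity programs draw base(t) ~ N(0, 1) per module;
disease-response modules instead have near-zero baseline activity in every
healthy state (base ~ N(0, 0.2)) and are activated by δ in disease. This
mirrors the disease-module premise the scoring relies on — disease
programs largely off in controls, distinctively active in cases. It
matters because |s^p| measures absolute decoded activity: a disease whose
module already had strong negative baseline activity and was merely
*shifted toward zero* would be invisible to the score even though the
shift itself is large (a mean-code-subtracted contrast recovers such
planted signals perfectly, but that is not the method's scoring rule).

What the generator does **not** emulate: hierarchical pathway structure
(modules are flat and disjoint), platform/batch effects, count noise,
correlated loadings, overlapping disease programs, or realistic interactome
topology (degree heterogeneity, hubs). Two consequences observed in the
studies: (i) planted-gene recovery and embedding-coherence results
transfer qualitatively to this world; (ii) the *depth gradient* of
interactome localization does not — with flat modules and no hierarchy,
light-up lists of the layer nearest the decoder output are the most
module-pure (its nodes are one linear map from the genes), whereas on real
compendia the first hidden layer is reported as the most localized. Both
first- and third-layer lists localize far below random nulls in the
synthetic world; only their relative order differs from the real-data
observation. Passing synthetic tests therefore demonstrates correctness of
the machinery and of the recovery/coherence properties, not the real-data
layer ordering.

## Numerical choices and degenerate inputs

- Gene rankings break ties by ascending gene index (stable argsort);
  results are deterministic given seeds everywhere (data generation,
  initialization, batch shuffling, null draws).
- Training aborts with a diagnostic on non-finite loss.
- Min–max scaling refuses constant matrices (or constant genes in
  per-gene mode), naming the offender; upper-quartile normalization
  refuses all-zero samples.
- Harmonic distance returns +∞ when no pair of the set is connected;
  localization nulls average over finite draws.
- Model serialization stores the architecture as JSON plus raw float64
  arrays in a zip; round trips are bit-exact.
- The capacity study uses a reduced compendium (600 genes × 300 samples,
  eight 60-gene modules, widths 4–32, 1000 epochs) so the 12 trainings
  finish in a few minutes.

## Known limitations

- CPU-only dense numpy training; no GPU, convolutional or variational
  variants, no transfer learning.
- The disease score is an absolute-activity readout (see above); diseases
  manifesting only as suppression toward the dataset mean are hard to
  rank by design of the scoring rule.
- The moment-matching stacking variant is retained for completeness but
  is a speculative reading of an underspecified step.
- Multi-label phenotypes and covariate adjustment are out of scope; the
  hypergeometric p-values are reported raw (no multiple-testing
  correction across diseases).
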