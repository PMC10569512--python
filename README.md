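# critix

Explainable autoencoder analysis of gene-expression matrices: learn a
low-dimensional representation of a transcriptome (or of a single pathway's
genes) with a symmetric autoencoder, attribute each latent variable back to
the input genes with tree-ensemble surrogates and Shapley values, and
aggregate the attributions into a per-gene **critical index** that
prioritises the genes driving the learned representation.

## Who this is for

Transcriptomics researchers who use representation learning (autoencoders)
on bulk or single-cell expression data and need *gene-level* output:
ranked candidate genes rather than uninterpretable latent coordinates.
Critical genes complement the classical prioritisations — differentially
expressed genes (marginal effects), differentially co-expressed genes and
hub genes (pairwise correlations) — by capturing genes that contribute to
non-linear, multi-gene structure.

## The method

1. **Preprocess.** Keep genes with median expression > 1 (TPM-like input),
   transform to log2(x+1), rescale each gene to [0, 1], and split samples
   8:2 into training and test sets.
2. **Autoencoder.** A symmetric fully connected autoencoder
   r = g(f(x)) with L coding layers and H latent variables (sigmoid
   activations) is trained with Adam on the loss
   MSE(x, r) + λ·mean(|h|), full-batch, with step learning-rate decay and
   early stopping on held-out reconstruction R². Presets: L=5, H=32 for a
   whole transcriptome; H=8 with L=2 (< 100 genes) or L=3 for a pathway.
3. **Explain.** One XGBoost regressor per latent variable learns
   h_j ≈ m_j(x); path-dependent tree-Shapley values (TreeSHAP) give an
   attribution φ for every [gene i, latent h, sample s] triple.
4. **Aggregate.** SV_{h,i} = (1/n) Σ_s |φ_{i,h,s}| and the critical index
   WSV_i = Σ_h w_h · SV_{h,i}, where w_h is the surrogate R² of latent h.
   Critical genes are the top ⌈1% · G⌉ by WSV (ceiling rule: ⌈0.2⌉ = 1,
   ⌈1.8⌉ = 2).
5. **Downstream.** Hypergeometric over-representation of prioritised genes
   in GMT gene sets; differential co-expression between two conditions via
   the adjacency difference d_ij = (½|sign(c^case)(c^case)² −
   sign(c^control)(c^control)²|)^β and its topological-overlap
   dissimilarity, with module detection and signed-network hub genes;
   confusion-matrix evaluation against gold-standard gene lists; and a
   classifier feature-importance baseline.

The tree-Shapley attribution engine is implemented in-package (exact
path-dependent values, validated against a brute-force subset-enumeration
oracle and against XGBoost's native `pred_contribs`), as is the
autoencoder (numpy, hand-written backpropagation — exactly reproducible
from a seed).

## Worked example

```python
from critix import CriticalGeneModel, SyntheticSpec, simulate_factor_expression
from critix.autoencoder import AEConfig

spec = SyntheticSpec(seed=7)                      # 200 samples x 100 genes,
matrix, truth = simulate_factor_expression(spec)  # 4 factors, 4 planted genes

config = AEConfig(n_coding_layers=3, n_latent=8,
                  learning_rate=1e-2, patience_epochs=50, seed=7)
results = CriticalGeneModel(matrix, config=config, seed=7).fit()
print(results.summary())
```

```
Critical-gene analysis
==========================================================
samples (train/test):   160/40
genes after filtering:  100
architecture:           widths [100, 43, 19, 8] (L=3, H=8)
epochs trained:         628
test reconstruction R2: 0.2450
surrogate R2 (w_h):     min 0.998, median 1.000, max 1.000
critical fraction:      1.00% -> 1 genes
----------------------------------------------------------
top critical genes (gene, WSV, rank):
  G0053            0.203217  1
```

The single selected gene (⌈1% · 100⌉ = 1) is one of the four planted
signal carriers (`truth["planted_genes"]` is
`['G0007', 'G0014', 'G0053', 'G0069']`); inspecting
`results.table` shows all four occupying ranks 1–4. The held-out
reconstruction R² of 0.245 is close to the ceiling for these data, in
which the four factors explain about a quarter of the total variance.

The same analysis is available from the shell:

```bash
critix simulate --seed 7 --out sim/
critix run sim/expression.tsv --mode pathway --seed 7 --out run/
critix run sim/expression.tsv --mode pathway --gmt sim/blocks.gmt --seed 7 --out runs/
```

`DiffCoExModel(x_case, x_control).fit()` exposes the differential
co-expression side: correlation matrices, the β-selected adjacency
difference, TOM dissimilarity, modules, hub genes, and per-gene
Kolmogorov–Smirnov comparisons of tumour/normal correlation profiles.

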