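# spanmf

Spatial metagene pattern recognition for spatially resolved transcriptomics
and spatial multi-omics, via graph-regularized non-negative matrix
factorization.

Spot-based and imaging platforms (Visium, Stereo-seq, MERFISH, osmFISH,
spatial CITE-seq, MISAR-seq, ...) measure a non-negative expression matrix
over spatial locations.  Most pipelines cluster spots into global domains and
stop; `spanmf` instead decomposes the tissue into *spatial metagenes* —
coordinated gene programs with smooth spatial activity maps — and derives the
standard downstream products from that decomposition: pattern-specific
genes, spatially variable genes (SVGs), spatial domains and denoised
expression.  It is a library first (see `examples/`), with a thin `spanmf`
command-line interface on top.

## Model

Given the `n x p` expression matrix `X` (spots x genes), the method solves

```
min_{W>=0, H>=0}  ||X - WH||_F^2  +  alpha * tr(Omega W^T L W)
                  +  beta * ||W||_1  +  (gamma/2) * sum_{i<j} <h_i, h_j>^2
```

* columns of `W` (`n x r`) are spatial metagene expression patterns;
* rows of `H` (`r x p`) are metagene signatures over genes;
* `L = D - A` is the Laplacian of a spatial neighborhood graph whose edges
  connect spots closer than a radius `r* = lambda * sqrt(area/n)` and are
  weighted by a Gaussian kernel on expression cosine distance;
* `Omega = diag(PSS)` weights the smoothing of each pattern by its *pattern
  significance score* — the cosine similarity between the pattern's observed
  mean expression profile `p_i = X^T w_i / ||w_i||_1` and its signature
  `h_i` — so dubious patterns are smoothed less;
* the `l1` term sparsifies patterns, and the pairwise `<h_i, h_j>^2` penalty
  keeps metagenes distinct.

Optimization is by multiplicative updates whose fixed points are the KKT
points of the objective; with the PSS weights frozen, each step is
non-increasing.  Defaults follow closed forms: `beta = alpha/15`,
`gamma = 1.5e-4 * p`, `lambda = 1.2`, `r = 30`.  A multislice variant fits
slice-specific `W_s` against one shared `H`; multi-omics data are integrated
by per-modality normalization followed by feature-wise concatenation.

Downstream, signatures are rescaled by pattern magnitudes and column-
normalized into contributions `Pr`; genes with `Pr_ij > 0.3` are
pattern-specific, genes with relative reconstruction error
`||X_j - (WH)_j|| / ||X_j|| < 0.7` are SVGs, domains come from k-means on
the pattern loadings after dropping low-norm and low-significance patterns,
and `WH` itself is the denoised expression.

## Worked example

`python examples/01_fit_planted_patterns.py` generates a 30x30 lattice with
6 planted laminar bands plus spot-permuted background genes, fits 10
patterns, and prints:

```
dataset: 900 spots x 300 genes (240 structured, 60 background)
graph: radius 1.160, mean neighbors 3.87
converged after 200 iterations; final objective 18014.0
pattern significance scores: [0.875 0.872 0.843 0.84 0.836 0.834 0.463 0.399 0.396 0.387]
matched cosine similarity to the 6 planted patterns: 0.992
```

Six patterns with high significance scores correspond one-to-one to the six
planted bands (matched cosine 0.992 under Hungarian assignment); the four
low-score patterns absorb noise and are filtered before domain clustering.
Continuing with `examples/02` and `examples/03` on the same data: SVG recall
1.000 and precision 0.972 at the default error threshold, domain ARI 1.000
against the planted layers, and the mean Moran's I across genes rises from
0.536 to 0.837 after denoising with 98.7% of genes improved.

The same pipeline runs from the shell:

```
spanmf simulate --out data/ --seed 0
spanmf fit --expression data/matrix.mtx --out model/ --r 10 --n-cluster 6 --seed 0
spanmf svg --model model/ --expression data/matrix.mtx --out svg.tsv
spanmf domains --model model/ --n-cluster 6 --out domains.csv
spanmf graph-stats --expression data/matrix.mtx
```

Every run resolves parameters with precedence CLI > `--config` file >
defaults and records them in `params_resolved.json`.

## Layout

* `src/spanmf/` — library: `datatypes`, `graph`, `preprocess`, `factorize`,
  `downstream`, `synthetic`, `io`, `cli`.
* `examples/` — one short narrative script per capability.
* `docs/methods.md` — model, parameters, numerical choices, limitations.
* `tests/` — unit, property and end-to-end suites.
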