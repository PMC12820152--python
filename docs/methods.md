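# Methods

## Model and assumptions

`spanmf` models a non-negative spot-by-gene expression matrix `X` (n x p) as
`X ~ W H` with non-negative factors: columns of `W` are spatial metagene
expression patterns, rows of `H` metagene signatures.  The fit minimizes

```
f(W, H) = ||X - WH||_F^2
        + alpha * tr(Omega W^T L W)        (weighted spatial smoothness)
        + beta  * ||W||_1                  (pattern sparsity)
        + (gamma/2) * sum_{i<j} <h_i,h_j>^2  (metagene distinctness)
```

The model assumes (i) expression is a non-negative mixture of a modest
number of programs, (ii) program activity varies smoothly over the tissue at
the scale of the neighbor graph, and (iii) different programs engage largely
different genes.  Violations degrade gracefully: unsmooth programs receive a
low pattern significance score (PSS) and hence little smoothing; overlapping
gene programs are tolerated (SVG detection explicitly allows genes spanning
several patterns) but weaken the orthogonality penalty's interpretation.

### Spatial graph

Spots closer than `r*` are connected; `r*` is user-supplied or
`lambda * sqrt(bounding-box area / n)` — the natural nearest-neighbor length
scale of a roughly uniform point cloud.  Edges are weighted by
`exp(-d_cos^2 / (2 d*^2))`, where `d_cos` is the cosine distance between the
two spots' expression profiles and the bandwidth `d*` is the `1/n_c`
quantile of the cosine-distance population, so that within-cluster profile
differences map to weights near 1.  Up to 5000 spots the quantile uses all
off-diagonal pairs; beyond that it uses spatially adjacent pairs only
(`quantile_mode` forces either).  Conventions: the distance cutoff is strict
(`d_euc < r*`); co-located spot pairs and self-pairs are not connected;
all-zero expression profiles get cosine distance 1 to everything; a zero
quantile falls back to the smallest positive distance, or to 1 if every
distance is zero (weights degenerate to a radius indicator, with a warning);
cosine distances within 1e-12 of zero are snapped to zero so duplicated
profiles behave exactly.

### Pattern significance and the weighted penalty

For pattern i, `p_i = X^T w_i / ||w_i||_1` is the average expression profile
over the locations where the pattern is active, and
`PSS_i = cos(p_i, h_i) in [0, 1]` measures whether the signature matches what
is actually expressed there.  `Omega = diag(PSS)` scales the spatial penalty
per pattern, protecting weak-but-real programs from over-smoothing and
denying noise components the smoothing that would make them look spatial.
Degenerate patterns (`w_i = 0`, `h_i = 0`, or `p_i = 0`) score 0.

### Updates and their fixed points

Optimization alternates multiplicative steps

```
W <- W * (X H^T + alpha * (A W) Omega) / (W H H^T + alpha * (D W) Omega + beta/2 + delta)
H <- H * (W^T X) / (W^T W H + (gamma/2) * (HH^T - diag) H + delta)
```

with PSS recomputed once per outer iteration before the W-step.  The
gradient of `f` carries a factor 2 on the quadratic terms but not on the
`l1` term, and a factor `gamma` (not `gamma/2`) on the orthogonality
gradient; the denominators above carry `beta/2` and `gamma/2` so that the
fixed points are exactly the KKT points of `f` (verified in the tests
against central finite differences).  With `Omega` frozen, both steps are
non-increasing — the standard majorization argument for graph-regularized
NMF applies column-wise because `Omega` is diagonal and non-negative.
Across PSS refreshes the classical monotonicity proof does not apply; in
practice the recorded totals still decrease, and the per-step guarantee is
what the tests assert.  The trace records
(total, reconstruction, spatial, sparsity, orthogonality) each iteration.

Numerical choices: `delta = 1e-12` floors every denominator (zeros in W/H
are absorbing, as in all multiplicative schemes); initialization draws W and
H from `U(0,1) * sqrt(mean(X)/r)` with a seeded generator, so equal seeds
give bit-identical fits; convergence is declared when the relative change
of the total objective drops below `tol` (default 1e-5) or after `max_iter`
(default 200) iterations.  Patterns are reported in descending-PSS order.
A and L stay sparse throughout; `X` may be sparse; `W`, `H` are dense.

### Multislice and multi-omics

For M slices with a common feature axis, each slice keeps its own graph,
pattern matrix `W_s` and PSS vector (the spatial penalty is written per
slice, so per-slice weighting is the faithful reading), while the H-step
aggregates `sum_s W_s^T X_s` over `sum_s W_s^T W_s H` plus the orthogonality
term.  With M = 1 the code path is literally the single-slice fit, so the
reduction is bit-exact.  Multi-omics integration is deliberately minimal,
matching the protocol it implements: normalize and select features per
modality, then concatenate columns over the shared spots and fit once.

## Downstream operators

* **Pattern contributions**: `Lambda = diag(||w_1||, ..., ||w_r||)`,
  `H' = Lambda H`, `Pr_ij = H'_ij / sum_k |H'_kj|`.  Columns of `Pr` over
  patterns sum to 1 (all-zero columns stay 0, flagged); `Pr` is invariant to
  the W/H scale ambiguity.  Genes with `Pr_ij > eps_pattern` (strict,
  default 0.3) are pattern-specific, reported in descending contribution and
  split by modality for multi-omics runs.
* **SVGs**: `err_j = ||X_j - (WH)_j||_2 / ||X_j||_2`; genes with
  `err_j < eps_svg` (strict, default 0.7) are spatially variable, returned
  in ascending error.  All-zero columns get a +inf sentinel, never selected.
* **Domains**: drop the `N1` patterns with smallest `||w_i||_2`, then the
  `N2` lowest-PSS survivors (ties drop the lower index), and k-means the
  remaining loadings with 10 seeded restarts.  Defaults
  `N1 = r - 5 - n_cluster` (clamped at 0) and `N2 = 3` (clamped so that at
  least one pattern survives when r is small).
* **Denoising**: `X_hat = W H`.  The refinement report computes Moran's I
  per gene on `X` and `X_hat` with the same graph and the fraction of genes
  improved; co-expression reports Pearson correlations over spots within a
  gene subset, excluding zero-variance genes.

Moran's I uses the analysis graph's weighted adjacency as its weight matrix
(one convention for the whole package) and returns 0 for constant signals —
detected by an exact range test, immune to roundoff in the variance.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 1.0 | spatial-regularization weight; 0.3-1.0 for tissue-level domains, 0.1-0.3 to preserve small niches |
| `beta` | `alpha/15` | sparsity of W, fixed relative to the spatial weight |
| `gamma` | `1.5e-4 * p` | metagene orthogonality; scales with p because inner products do |
| `r` | 30 | pattern count; over-complete on purpose, filtering prunes it |
| `lambda` | 1.2 | graph radius scale; tune until the mean neighbor count reported by `neighbor_stats` lands in 6-10 |
| `n_c` | `n_cluster` (8) | quantile order for the kernel bandwidth |
| `eps_pattern` | 0.3 | pattern-specific contribution threshold (strict) |
| `eps_svg` | 0.7 | SVG relative-error threshold (strict) |
| `N1`, `N2` | `r-5-n_cluster`, 3 | patterns removed by norm, then by PSS, before clustering |
| `max_iter`, `tol` | 200, 1e-5 | outer-loop budget and relative convergence tolerance |
| `target_sum` | 1e4 | library size after normalization (the standard single-cell convention) |

Preprocessing order is normalize -> Moran's-I feature selection -> neighbor
averaging (closed neighborhood, equal weights), each step optional and
exposed separately; imaging panels with few genes typically skip selection.
All-zero features are flagged by validation and must be dropped before
fitting (the SVG error is undefined for them); duplicate coordinates are
flagged but never merged.

## Synthetic data: what it emulates, what it does not

`make_layered_dataset` plants laminar, cortex-like structure: spots on an
`n_side x n_side` lattice, `r_true` horizontal bands whose smoothed
indicators (Gaussian decay, length `n_side/(4 r_true)`, measured to the
band's own rows so each spot's strongest pattern equals its label) form
`W_true`; disjoint uniform loadings on `p - n_background` structured genes
form `H_true`; background genes are spot-permuted copies of structured genes
— same marginal distribution, destroyed spatial signal — and Gaussian noise
(optionally Poisson resampling for counts) corrupts the sum.  A `bumps`
geometry provides non-laminar patterns.  `make_multislice` shares `H_true`
across slices with jittered coordinates and independent noise;
`make_multiomics` shares `W_true` across modalities with modality-specific
signature blocks and noise scales.

The versioned benchmark configuration is `n_side=30, r_true=6, p=300,
n_background=60, noise_sd=0.3`, seeds 0-4, fitted at `r=10, alpha=1` with
derived defaults and scored at `n_cluster=6`.  These problem sizes keep a
full five-seed pipeline run under half a minute while leaving the recovery
task non-trivial (noise at ~30% of a typical loading, 20% decoy genes).

What passing these tests shows: the optimizer descends, reaches KKT points,
and the full pipeline recovers planted smooth patterns, their genes and
domains under iid noise and marginal-matched decoys.  What it does not
show: robustness to platform-specific artifacts absent from the generator —
zero inflation and over-dispersion calibrated to real counts, segmentation
errors, batch effects between slices, spatially correlated noise, or domains
with curved geometry.  Real-data performance must be judged on real data.

## Design choices where the design was open

* **KKT-consistent denominators** (`beta/2`, `gamma/2`) rather than the
  plain `beta`, `gamma`: makes the update fixed points coincide exactly with
  the stationary points of the stated objective; the alternative optimizes
  the same objective with doubled sparsity/orthogonality weights.
* **PSS refresh schedule**: once per outer iteration, before the W-step —
  the weights adapt while each step retains its descent guarantee.
* **Per-slice PSS** in the multislice model, since the penalty is a sum of
  per-slice terms with the weight matrix inside.
* **Quantile population** for the bandwidth: exact (all pairs) at desk
  scale, neighbor pairs beyond 5000 spots for linear scaling.
* **Strict thresholds** everywhere (`>`, `<`), with documented tie-breaks
  (ascending index for equal Moran's I; lower index dropped first in
  pattern filtering) so every selection is deterministic.
* **Moran's weights = analysis adjacency**: one graph, one convention,
  rather than a second binary graph.
* **CLI is a thin shell** over the library; every computational error maps
  to a non-zero exit and all randomness flows from `--seed`.

## Known limitations

Objective descent across PSS refreshes is empirical, not proven.  The
orthogonality term is quartic in H, so the H-step's descent relies on the
penalty being small relative to the quadratic terms (the default `gamma`
keeps it so; extreme user-set values may oscillate).  k-means assumes
roughly isotropic clusters in loading space; strongly unbalanced domains may
need a different clusterer on `W*`.  Multislice fitting assumes shared
programs — sections differing by batch or biology violate it, and no batch
correction is attempted.  Rank selection is left to the user (`r = 30`
default, 40-50 for very heterogeneous samples); enrichment analysis of the
emitted gene/peak lists is out of scope.
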