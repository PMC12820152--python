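"""Fit spatial metagene patterns on a planted laminar dataset.

Generates a 30x30 lattice with 6 smooth banded patterns, fits the
graph-regularized factorization with 10 patterns, and scores how well the
recovered pattern maps match the planted ones (Hungarian-matched cosine
similarity; 1.0 = perfect recovery).
"""

import numpy as np
from scipy.optimize import linear_sum_assignment

import spanmf

ds, truth = spanmf.make_layered_dataset(seed=0)
print(f"dataset: {ds.n_spots} spots x {ds.n_features} genes "
      f"({truth.svg_true.size} structured, {ds.n_features - truth.svg_true.size} background)")

graph = spanmf.build_graph(ds)
stats = spanmf.neighbor_stats(graph)
print(f"graph: radius {graph.radius:.3f}, mean neighbors {stats['mean_neighbors']:.2f}")

model = spanmf.fit(ds, graph, spanmf.FactorParams(r=10, n_cluster=6, seed=0))
print(f"converged after {len(model.objective_trace)} iterations; "
      f"final objective {model.objective_trace[-1, 0]:.1f}")
print("pattern significance scores:", np.round(model.pss, 3))

Wt = truth.W_true / np.linalg.norm(truth.W_true, axis=0)
Wr = model.W / np.maximum(np.linalg.norm(model.W, axis=0), 1e-12)
S = Wt.T @ Wr
ri, ci = linear_sum_assignment(-S)
print(f"matched cosine similarity to the 6 planted patterns: {S[ri, ci].mean():.3f}")
print("(values near 1 mean each planted band was recovered as one pattern;")
print(" the remaining low-PSS patterns absorb noise and are filtered downstream)")
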