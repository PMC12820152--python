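"""Spatial multi-omics integration by feature-wise concatenation.

Two modalities (RNA-like and protein-like) measured on the same spots share
the planted spatial patterns.  Each modality is normalized independently,
the matrices are concatenated, and one factorization is fitted on the joint
matrix; pattern-specific features are then reported per modality, revealing
co-localized gene-protein pairs.
"""

import numpy as np

import spanmf

datasets, truth = spanmf.make_multiomics(p_per_modality=(200, 60), seed=0)
merged = spanmf.concat_modalities([spanmf.normalize_log_libsize(d) for d in datasets])
print(f"integrated matrix: {merged.n_spots} spots x {merged.n_features} features "
      f"({merged.modality_tags.count('rna')} rna + "
      f"{merged.modality_tags.count('protein')} protein)")

graph = spanmf.build_graph(merged)
model = spanmf.fit(merged, graph, spanmf.FactorParams(r=10, n_cluster=6, seed=0))
annotation = spanmf.annotate(merged.X, model)

for pattern, feats in annotation.pattern_genes.items():
    if not feats:
        continue
    by_mod = {}
    for f in feats:
        by_mod.setdefault(f.split("_")[0], []).append(f)
    counts = {m: len(v) for m, v in by_mod.items()}
    print(f"pattern {pattern} (PSS {model.pss[pattern]:.2f}): "
          f"specific features per modality {counts}")

X_hat = spanmf.denoise(model)
pairs, _ = spanmf.coexpression_pairs(X_hat, np.arange(merged.n_features),
                                     threshold=0.9, feature_ids=merged.feature_ids)
cross = pairs[[a.split("_")[0] != b.split("_")[0]
               for a, b in zip(pairs["feature_a"], pairs["feature_b"])]]
print(f"cross-modality pairs with refined correlation > 0.9: {len(cross)}")
print(cross.head(5).to_string(index=False))
print("(features loading on the same spatial pattern co-localize across")
print(" modalities, mimicking coordinated gene-protein expression)")
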