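"""Normalization, spatial feature selection, neighbor smoothing and
multi-omics concatenation.

The sequencing-platform protocol is: library-size normalize + log1p, keep the
features with highest spatial autocorrelation (Moran's I on the analysis
graph), then average each spot with its adjacent neighbors.  Imaging
platforms with small panels typically skip selection.  Multi-omics modalities
are preprocessed independently and concatenated feature-wise over the shared
spots.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .datatypes import SpatialDataset, SpatialGraph

__all__ = [
    "normalize_log_libsize",
    "morans_i",
    "morans_i_features",
    "select_spatial_features",
    "neighbor_average",
    "concat_modalities",
]


def normalize_log_libsize(ds: SpatialDataset, target_sum: float = 1e4) -> SpatialDataset:
    """Scale each spot to a common library size, then log(1 + x).

    Zeros stay zeros and the output is non-negative.  Spots with zero total
    expression cannot be scaled and are rejected with their indices listed.
    """
    if target_sum <= 0:
        raise ValueError("target_sum must be positive")
    X = ds.X
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        ids = [ds.spot_ids[i] for i in zero[:10]]
        raise ValueError(
            f"{zero.size} spot(s) have zero library size and cannot be normalized: "
            f"indices {zero[:10].tolist()} ids {ids}"
        )
    scale = target_sum / totals
    if sp.issparse(X):
        Xn = sp.diags(scale) @ X.tocsr()
        Xn.data = np.log1p(Xn.data)
    else:
        Xn = np.log1p(X * scale[:, None])
    return SpatialDataset(
        X=Xn, coords=ds.coords.copy(), spot_ids=list(ds.spot_ids),
        feature_ids=list(ds.feature_ids), modality_tags=list(ds.modality_tags),
    )


def morans_i(values, g: SpatialGraph) -> float:
    """Moran's spatial autocorrelation I of one signal on the analysis graph.

    I = (n / S0) * sum_ij A_ij (v_i - vbar)(v_j - vbar) / sum_i (v_i - vbar)^2
    with S0 the total edge weight.  A constant signal has no autocorrelation
    and returns 0 by convention; an edgeless graph has S0 = 0 and is an error.
    """
    v = np.asarray(values, dtype=float).ravel()
    n = v.size
    if n != g.n_spots:
        raise ValueError(f"signal length {n} does not match graph size {g.n_spots}")
    s0 = float(g.A.sum())
    if s0 == 0:
        raise ValueError("graph has no edges (S0 = 0); Moran's I is undefined")
    if v.max() == v.min():  # constant signal: zero by convention
        return 0.0
    z = v - v.mean()
    denom = float(z @ z)
    if denom == 0:
        return 0.0
    num = float(z @ (g.A @ z))
    return (n / s0) * num / denom


def morans_i_features(X, g: SpatialGraph) -> np.ndarray:
    """Moran's I for every column of X at once (same conventions as morans_i)."""
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n != g.n_spots:
        raise ValueError(f"matrix has {n} rows but graph has {g.n_spots} spots")
    s0 = float(g.A.sum())
    if s0 == 0:
        raise ValueError("graph has no edges (S0 = 0); Moran's I is undefined")
    Z = X - X.mean(axis=0, keepdims=True)
    denom = np.einsum("ij,ij->j", Z, Z)
    num = np.einsum("ij,ij->j", Z, g.A @ Z)
    out = np.zeros(X.shape[1])
    # constant features score 0 by convention (exact range test beats a
    # roundoff-contaminated variance test)
    nz = (denom > 0) & (X.max(axis=0) != X.min(axis=0))
    out[nz] = (n / s0) * num[nz] / denom[nz]
    return out


def select_spatial_features(ds: SpatialDataset, g: SpatialGraph, k: int) -> np.ndarray:
    """Indices of the k most spatially autocorrelated features.

    Output is ordered by descending Moran's I; exact ties are broken by
    ascending original index so selection is deterministic.
    """
    p = ds.n_features
    if not (1 <= k <= p):
        raise ValueError(f"k must be in [1, {p}], got {k}")
    scores = morans_i_features(ds.X, g)
    order = np.lexsort((np.arange(p), -scores))
    return order[:k]


def neighbor_average(ds: SpatialDataset, g: SpatialGraph) -> SpatialDataset:
    """Replace each spot by the unweighted mean over its closed neighborhood.

    The closed neighborhood is the spot itself plus every j with A_ij > 0;
    isolated spots therefore pass through unchanged.
    """
    if g.n_spots != ds.n_spots:
        raise ValueError("graph and dataset have different numbers of spots")
    adj = (g.A > 0).astype(float)
    M = adj + sp.eye(ds.n_spots, format="csr")
    sizes = np.asarray(M.sum(axis=1)).ravel()
    Xs = M @ ds.X
    if sp.issparse(Xs):
        Xs = sp.diags(1.0 / sizes) @ Xs
    else:
        Xs = np.asarray(Xs) / sizes[:, None]
    return SpatialDataset(
        X=Xs, coords=ds.coords.copy(), spot_ids=list(ds.spot_ids),
        feature_ids=list(ds.feature_ids), modality_tags=list(ds.modality_tags),
    )


def concat_modalities(datasets: list[SpatialDataset]) -> SpatialDataset:
    """Feature-wise concatenation of modalities measured on the same spots.

    Each modality is expected to have been preprocessed independently.  Spot
    ids must match exactly in order; feature ids must remain unique after
    concatenation (prefix them per modality if they collide).
    """
    if not datasets:
        raise ValueError("no datasets to concatenate")
    ref = datasets[0]
    for m, ds in enumerate(datasets[1:], start=1):
        if ds.n_spots != ref.n_spots:
            raise ValueError(
                f"modality {m} has {ds.n_spots} spots but modality 0 has {ref.n_spots}"
            )
        for i, (a, b) in enumerate(zip(ref.spot_ids, ds.spot_ids)):
            if a != b:
                raise ValueError(
                    f"spot id mismatch between modality 0 and {m} at position {i}: "
                    f"{a!r} != {b!r}"
                )
    any_sparse = any(sp.issparse(ds.X) for ds in datasets)
    if any_sparse:
        X = sp.hstack([sp.csr_matrix(ds.X) for ds in datasets], format="csr")
    else:
        X = np.hstack([ds.dense() for ds in datasets])
    feature_ids = [f for ds in datasets for f in ds.feature_ids]
    if len(set(feature_ids)) != len(feature_ids):
        raise ValueError(
            "feature ids collide across modalities; rename (e.g. prefix with the "
            "modality tag) before concatenating"
        )
    tags = [t for ds in datasets for t in ds.modality_tags]
    return SpatialDataset(
        X=X, coords=ref.coords.copy(), spot_ids=list(ref.spot_ids),
        feature_ids=feature_ids, modality_tags=tags,
    )
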