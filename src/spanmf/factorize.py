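"""Graph-regularized non-negative matrix factorization with pattern
significance weighting.

The model factorizes a non-negative spot-by-feature matrix X as X ~ W H with
W >= 0 (spatial metagene expression patterns, one per column) and H >= 0
(metagene signatures, one per row), minimizing

    ||X - WH||_F^2 + alpha * tr(Omega W^T L W) + beta * ||W||_1
        + (gamma/2) * sum_{i<j} <h_i, h_j>^2

where L is the spatial graph Laplacian and Omega = diag(PSS) adaptively
weights the smoothing of each pattern by its pattern significance score.
Optimization uses multiplicative updates whose fixed points are exactly the
KKT points of the objective above; with the PSS weights held fixed, each W-
and H-step is non-increasing.  A multislice variant fits one W_s per tissue
section against a shared H.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .datatypes import FactorModel, FactorParams, MultisliceModel, SpatialDataset, SpatialGraph

__all__ = [
    "ObjectiveTerms",
    "objective",
    "compute_pss",
    "update_w",
    "update_h",
    "fit",
    "fit_multislice",
]


@dataclass
class ObjectiveTerms:
    total: float
    recon: float
    spatial: float
    sparsity: float
    ortho: float

    def as_tuple(self):
        return (self.total, self.recon, self.spatial, self.sparsity, self.ortho)


def _recon_sq(X, W, H) -> float:
    """||X - WH||_F^2 without materializing WH when X is sparse."""
    if sp.issparse(X):
        xx = float((X.multiply(X)).sum())
        wtx = W.T @ X  # r x p, dense
        cross = float(np.einsum("ij,ij->", np.asarray(wtx), H))
        gram = float(np.einsum("ij,ij->", W.T @ W, H @ H.T))
        return xx - 2.0 * cross + gram
    R = X - W @ H
    return float(np.einsum("ij,ij->", R, R))


def _ortho_sq(H) -> float:
    """sum_{i<j} <h_i, h_j>^2."""
    G = H @ H.T
    return 0.5 * (float(np.einsum("ij,ij->", G, G)) - float(np.sum(np.diag(G) ** 2)))


def objective(
    X,
    W: np.ndarray,
    H: np.ndarray,
    g: SpatialGraph | None,
    params: FactorParams,
    pss: np.ndarray,
) -> ObjectiveTerms:
    """Evaluate every term of the objective for the current factors.

    The spatial term is alpha * sum_i pss_i * (W^T L W)_ii; it requires a
    graph unless alpha = 0.
    """
    beta = params.beta if params.beta is not None else params.alpha / 15.0
    gamma = params.gamma if params.gamma is not None else 1.5e-4 * H.shape[1]
    recon = _recon_sq(X, W, H)
    if params.alpha > 0:
        if g is None:
            raise ValueError("a spatial graph is required when alpha > 0")
        LW = g.L @ W
        spatial = params.alpha * float(np.sum(np.asarray(pss) * np.einsum("ij,ij->j", W, LW)))
    else:
        spatial = 0.0
    sparsity = beta * float(np.abs(W).sum())
    ortho = (gamma / 2.0) * _ortho_sq(H)
    total = recon + spatial + sparsity + ortho
    return ObjectiveTerms(total=total, recon=recon, spatial=spatial, sparsity=sparsity, ortho=ortho)


def compute_pss(X, W: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Pattern significance scores in [0, 1].

    For pattern i, p_i = X^T w_i / ||w_i||_1 is the mean expression profile
    over the locations where the pattern is active, and PSS_i is the cosine
    similarity between p_i and the signature h_i.  Degenerate patterns
    (w_i = 0, h_i = 0 or p_i = 0) score 0 by convention.
    """
    w_l1 = np.abs(W).sum(axis=0)
    P = np.asarray(X.T @ W if not sp.issparse(X) else (X.T @ W))
    P = np.asarray(P, dtype=float)
    r = W.shape[1]
    pss = np.zeros(r)
    p_norm = np.linalg.norm(P, axis=0)
    h_norm = np.linalg.norm(H, axis=1)
    for i in range(r):
        if w_l1[i] == 0 or h_norm[i] == 0:
            continue
        pn = p_norm[i] / w_l1[i]
        if pn == 0:
            continue
        inner = float(P[:, i] @ H[i]) / w_l1[i]
        pss[i] = inner / (pn * h_norm[i])
    return np.clip(pss, 0.0, 1.0)


def update_w(
    X,
    W: np.ndarray,
    H: np.ndarray,
    g: SpatialGraph | None,
    params: FactorParams,
    pss: np.ndarray,
) -> np.ndarray:
    """One multiplicative W-step; zeros are absorbing and the result is >= 0.

    W_ij <- W_ij * (X H^T + alpha pss_j (A W))_ij
                 / ((W H H^T)_ij + alpha pss_j (D W)_ij + beta/2 + delta).
    The beta/2 in the denominator makes the fixed points exactly the KKT
    points of the objective (its gradient carries a factor 2 on the smooth
    terms but not on the l1 term).
    """
    beta = params.beta if params.beta is not None else params.alpha / 15.0
    num = np.asarray(X @ H.T, dtype=float)
    den = W @ (H @ H.T)
    if params.alpha > 0:
        if g is None:
            raise ValueError("a spatial graph is required when alpha > 0")
        scaled = params.alpha * np.asarray(pss)[None, :]
        num = num + np.asarray(g.A @ W) * scaled
        den = den + np.asarray(g.D @ W) * scaled
    den = den + beta / 2.0 + params.delta
    Wn = W * (num / den)
    if not np.all(np.isfinite(Wn)):
        i, j = np.argwhere(~np.isfinite(Wn))[0]
        raise FloatingPointError(f"non-finite W update at entry ({i}, {j})")
    return Wn


def _h_numerator_denominator(Xs, Ws, H, gamma, delta):
    num = np.zeros_like(H)
    gram = np.zeros((H.shape[0], H.shape[0]))
    for X, W in zip(Xs, Ws):
        num += np.asarray(W.T @ X, dtype=float)
        gram += W.T @ W
    G = H @ H.T
    OH = (G - np.diag(np.diag(G))) @ H  # gradient of the pairwise-orthogonality term
    den = gram @ H + (gamma / 2.0) * OH + delta
    return num, den


def update_h(X, W: np.ndarray, H: np.ndarray, params: FactorParams) -> np.ndarray:
    """One multiplicative H-step; zeros are absorbing and the result is >= 0.

    H_ij <- H_ij * (W^T X)_ij
                 / ((W^T W H)_ij + (gamma/2) sum_{k!=i} <h_i, h_k> H_kj + delta),
    with gamma/2 for the same KKT consistency as in :func:`update_w`; with
    gamma = 0 this is the classical NMF H-update.
    """
    gamma = params.gamma if params.gamma is not None else 1.5e-4 * H.shape[1]
    num, den = _h_numerator_denominator([X], [W], H, gamma, params.delta)
    Hn = H * (num / den)
    if not np.all(np.isfinite(Hn)):
        i, j = np.argwhere(~np.isfinite(Hn))[0]
        raise FloatingPointError(f"non-finite H update at entry ({i}, {j})")
    return Hn


def _check_zero_features(X, feature_ids):
    col = np.asarray(X.sum(axis=0)).ravel()
    zero = np.flatnonzero(col == 0)
    if zero.size:
        names = [feature_ids[j] for j in zero[:5]] if feature_ids else zero[:5].tolist()
        raise ValueError(
            f"{zero.size} feature(s) have zero total expression ({names} ...); drop "
            "them before factorization (e.g. ds.subset_features on the nonzero columns)"
        )


def _fit_engine(Xs, graphs, params: FactorParams):
    """Shared optimization loop over one or more slices.

    Draws each slice's W then H from the seeded RNG, then alternates
    {per-slice PSS -> per-slice W-step -> shared H-step} until the relative
    change of the summed objective drops below tol.
    """
    p = Xs[0].shape[1]
    params = params.resolve(p)
    r = params.r
    rng = np.random.default_rng(params.seed)
    total_sum = sum(float(X.sum()) for X in Xs)
    total_size = sum(int(np.prod(X.shape)) for X in Xs)
    scale = np.sqrt(max(total_sum / total_size, np.finfo(float).tiny) / r)
    Ws = [rng.uniform(size=(X.shape[0], r)) * scale for X in Xs]
    H = rng.uniform(size=(r, p)) * scale

    trace = []
    prev_total = None
    pss_list = [np.zeros(r) for _ in Xs]
    gamma = params.gamma
    for it in range(params.max_iter):
        pss_list = [compute_pss(X, W, H) for X, W in zip(Xs, Ws)]
        Ws = [
            update_w(X, W, H, g, params, pss)
            for X, W, g, pss in zip(Xs, Ws, graphs, pss_list)
        ]
        num, den = _h_numerator_denominator(Xs, Ws, H, gamma, params.delta)
        H = H * (num / den)
        if not np.all(np.isfinite(H)):
            raise FloatingPointError(f"non-finite H at iteration {it}")
        terms = [
            objective(X, W, H, g, params, pss)
            for X, W, g, pss in zip(Xs, Ws, graphs, pss_list)
        ]
        rec = np.array([t.as_tuple() for t in terms])
        # the orthogonality term involves only the shared H: count it once
        row = rec.sum(axis=0)
        if len(Xs) > 1:
            row[4] = terms[0].ortho
            row[0] = row[1] + row[2] + row[3] + row[4]
        trace.append(tuple(row))
        if not np.isfinite(row[0]):
            raise FloatingPointError(f"objective diverged at iteration {it}")
        if prev_total is not None and abs(row[0] - prev_total) <= params.tol * abs(prev_total):
            prev_total = row[0]
            break
        prev_total = row[0]

    pss_list = [compute_pss(X, W, H) for X, W in zip(Xs, Ws)]
    # report patterns in descending significance order (stable on ties)
    mean_pss = np.mean(np.stack(pss_list), axis=0)
    order = np.lexsort((np.arange(r), -mean_pss))
    Ws = [W[:, order] for W in Ws]
    H = H[order, :]
    pss_list = [pss[order] for pss in pss_list]
    return Ws, H, pss_list, np.asarray(trace), params


def fit(ds: SpatialDataset, g: SpatialGraph, params: FactorParams | None = None) -> FactorModel:
    """Fit the factorization on a single slice.

    Runs the seeded multiplicative-update loop and returns the model with
    patterns ordered by descending PSS and the full objective trace
    (total, recon, spatial, sparsity, ortho) per iteration.
    """
    params = params or FactorParams()
    _check_zero_features(ds.X, ds.feature_ids)
    if g is not None and g.n_spots != ds.n_spots:
        raise ValueError("graph and dataset have different numbers of spots")
    Ws, H, pss_list, trace, resolved = _fit_engine([ds.X], [g], params)
    return FactorModel(
        W=Ws[0], H=H, pss=pss_list[0], objective_trace=trace, params=resolved,
        spot_ids=list(ds.spot_ids), feature_ids=list(ds.feature_ids),
        modality_tags=list(ds.modality_tags),
    )


def fit_multislice(
    datasets: list[SpatialDataset],
    graphs: list[SpatialGraph],
    params: FactorParams | None = None,
) -> MultisliceModel:
    """Joint fit of M slices with slice-specific W_s and a shared H.

    Each slice keeps its own spatial graph and PSS vector; the H-step
    aggregates sum_s W_s^T X_s over slices.  With M = 1 this reproduces
    :func:`fit` exactly (same seed, same draws, same updates).
    """
    params = params or FactorParams()
    if not datasets:
        raise ValueError("at least one slice is required")
    if len(graphs) != len(datasets):
        raise ValueError("one graph per slice is required")
    ref = datasets[0]
    for s, ds in enumerate(datasets[1:], start=1):
        if ds.feature_ids != ref.feature_ids:
            raise ValueError(
                f"slice {s} feature axis differs from slice 0; multislice fitting "
                "requires identical features in identical order"
            )
    for ds in datasets:
        _check_zero_features(ds.X, ds.feature_ids)
    Xs = [ds.X for ds in datasets]
    Ws, H, pss_list, trace, resolved = _fit_engine(Xs, graphs, params)
    return MultisliceModel(
        W_list=Ws, H=H, graphs=list(graphs), pss_list=pss_list,
        objective_trace=trace, params=resolved,
        spot_ids_list=[list(ds.spot_ids) for ds in datasets],
        feature_ids=list(ref.feature_ids),
    )
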