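"""Construction of the expression-weighted spatial neighborhood graph.

Spots closer than a radius r* are connected; each edge is weighted by a
Gaussian kernel on the cosine distance between the two spots' expression
profiles, so that spatial neighbors with dissimilar expression are weakly
coupled.  The radius is either user-supplied or derived from the density of
the spots, r* = lam * sqrt(area / n), with lam = 1.2 by default; the kernel
bandwidth d* is the 1/n_c quantile of the cosine-distance population.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .datatypes import SpatialDataset, SpatialGraph

__all__ = ["compute_radius", "build_graph", "neighbor_stats", "write_edge_list"]

# above this many spots the full pairwise cosine-distance population is not
# materialized; the bandwidth quantile falls back to spatially adjacent pairs
_FULL_QUANTILE_MAX_N = 5000


def compute_radius(coords, lam: float = 1.2, predefined: float | None = None) -> float:
    """Neighborhood radius r* = lam * sqrt(bounding-box area / n).

    ``predefined`` short-circuits the formula and is returned unchanged.
    A degenerate (zero-area) bounding box has no meaningful density and
    raises unless a predefined radius is given.
    """
    if predefined is not None:
        if predefined <= 0:
            raise ValueError("predefined radius must be positive")
        return float(predefined)
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("at least two spots are required to compute a radius")
    dx = coords[:, 0].max() - coords[:, 0].min()
    dy = coords[:, 1].max() - coords[:, 1].min()
    area = dx * dy
    if area <= 0:
        raise ValueError(
            "degenerate bounding box (zero area): coordinates are collinear or "
            "identical; pass a predefined radius instead"
        )
    return float(lam * np.sqrt(area / n))


def _row_normalize(X) -> np.ndarray:
    """Unit-l2-normalize rows; all-zero rows are returned as zero rows."""
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    return X / safe[:, None]


def _cosine_distance_pairs(Xn: np.ndarray, zero_rows: np.ndarray, ii, jj) -> np.ndarray:
    """Cosine distances for the spot pairs (ii, jj); zero rows are maximally distant."""
    sims = np.einsum("ij,ij->i", Xn[ii], Xn[jj])
    d = 1.0 - sims
    d[np.abs(d) < 1e-12] = 0.0  # snap roundoff so identical profiles are exactly 0
    # convention: an all-zero profile is maximally dissimilar to everything
    bad = zero_rows[ii] | zero_rows[jj]
    d[bad] = 1.0
    return np.clip(d, 0.0, 2.0)


def _bandwidth(dist_population: np.ndarray, n_c: int) -> float:
    """1/n_c quantile of the distance population, floored away from zero.

    Duplicated expression profiles can drive the quantile to 0, which would
    make the kernel degenerate; fall back to the smallest positive distance,
    or to 1 (pure radius-indicator weights) if every distance is zero.
    """
    q = float(np.quantile(dist_population, 1.0 / n_c))
    if q > 0:
        return q
    positive = dist_population[dist_population > 0]
    if positive.size:
        warnings.warn(
            "cosine-distance quantile is 0 (duplicated profiles); using the "
            "smallest positive distance as kernel bandwidth"
        )
        return float(positive.min())
    warnings.warn("all pairwise cosine distances are 0; edge weights fall back to 1")
    return 1.0


def build_graph(
    ds: SpatialDataset,
    lam: float = 1.2,
    n_c: int = 8,
    predefined_radius: float | None = None,
    quantile_mode: str = "auto",
) -> SpatialGraph:
    """Build the weighted adjacency A, degree D and Laplacian L = D - A.

    A_ij = exp(-d_cos(X_i., X_j.)^2 / (2 d*^2)) for spot pairs with Euclidean
    distance strictly between 0 and r*, and 0 otherwise.  ``quantile_mode``
    selects the population for the bandwidth quantile d*: ``"all"`` uses every
    off-diagonal pair, ``"neighbors"`` only spatially adjacent pairs, and
    ``"auto"`` switches from the former to the latter above 5000 spots.
    """
    if n_c < 1:
        raise ValueError("n_c must be a positive integer")
    if quantile_mode not in ("auto", "all", "neighbors"):
        raise ValueError(f"unknown quantile_mode {quantile_mode!r}")
    coords = np.asarray(ds.coords, dtype=float)
    n = coords.shape[0]
    radius = compute_radius(coords, lam=lam, predefined=predefined_radius)

    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if pairs.size:
        d_euc = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = (d_euc > 0) & (d_euc < radius)  # strict cutoff; co-located spots excluded
        pairs = pairs[keep]
    if pairs.size == 0:
        raise ValueError(
            f"the graph has no edges at radius {radius:.4g}; increase lam or pass "
            "a larger predefined radius"
        )

    Xn = _row_normalize(ds.X)
    zero_rows = ~np.any(Xn != 0, axis=1)
    ii, jj = pairs[:, 0], pairs[:, 1]
    d_cos = _cosine_distance_pairs(Xn, zero_rows, ii, jj)

    if quantile_mode == "all" or (quantile_mode == "auto" and n <= _FULL_QUANTILE_MAX_N):
        iu, ju = np.triu_indices(n, k=1)
        population = _cosine_distance_pairs(Xn, zero_rows, iu, ju)
    else:
        population = d_cos
    bandwidth = _bandwidth(population, n_c)

    w = np.exp(-(d_cos**2) / (2.0 * bandwidth**2))
    A = sp.coo_matrix(
        (np.concatenate([w, w]), (np.concatenate([ii, jj]), np.concatenate([jj, ii]))),
        shape=(n, n),
    ).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    D = sp.diags(deg, format="csr")
    L = (D - A).tocsr()
    return SpatialGraph(A=A, D=D, L=L, radius=radius, lam=lam, bandwidth=bandwidth, n_c=n_c)


def neighbor_stats(g: SpatialGraph) -> dict:
    """Neighbor-count summary with the 6-10 neighbors-per-spot guidance flag.

    Returns mean neighbor count, a degree histogram, and ``in_range`` —
    whether the mean falls in the recommended [6, 10] connectivity band (tune
    lam when it does not).
    """
    counts = np.diff(g.A.indptr)  # number of stored (nonzero) entries per row
    mean = float(counts.mean()) if counts.size else 0.0
    hist = np.bincount(counts) if counts.size else np.array([0])
    return {
        "mean_neighbors": mean,
        "histogram": {int(k): int(v) for k, v in enumerate(hist) if v},
        "in_range": bool(6.0 <= mean <= 10.0),
    }


def write_edge_list(g: SpatialGraph, path) -> None:
    """Export the upper-triangular edge list as TSV columns (i, j, weight)."""
    coo = sp.triu(g.A, k=1).tocoo()
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{w:.12g}\n")
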