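"""Domain types shared by every stage of the pipeline.

The central container is :class:`SpatialDataset`: a non-negative spot-by-feature
expression matrix together with 2-D spot coordinates and feature/modality
metadata.  Graphs, fitted factor models and planted-truth records are thin
dataclasses around numpy/scipy arrays; validation is reported, not raised, so
that malformed inputs can be inspected (see :func:`validate_dataset`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "SpatialDataset",
    "SpatialGraph",
    "FactorParams",
    "FactorModel",
    "MultisliceModel",
    "PatternAnnotation",
    "SyntheticTruth",
    "validate_dataset",
]


def _as_matrix(X):
    """Return X as a 2-D ndarray or CSR sparse matrix, without copying when possible."""
    if sp.issparse(X):
        return X.tocsr()
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expression matrix must be 2-D, got shape {arr.shape}")
    return arr


@dataclass
class SpatialDataset:
    """Spot/cell × feature expression with spatial coordinates.

    Parameters
    ----------
    X
        Non-negative expression, shape ``(n_spots, n_features)``; dense or
        scipy sparse.  Raw counts or library-normalized values.
    coords
        Spatial positions, shape ``(n_spots, 2)``, in arbitrary length units.
    spot_ids, feature_ids
        Unique string identifiers; generated (``spot_0`` / ``gene_0`` ...)
        when omitted.
    modality_tags
        One tag per feature (e.g. ``"rna"``, ``"protein"``, ``"atac"``); a
        single shared tag for unimodal data.
    """

    X: np.ndarray | sp.spmatrix
    coords: np.ndarray
    spot_ids: list[str] | None = None
    feature_ids: list[str] | None = None
    modality_tags: list[str] | None = None

    def __post_init__(self):
        self.X = _as_matrix(self.X)
        self.coords = np.asarray(self.coords, dtype=float)
        n, p = self.X.shape
        if self.coords.shape != (n, 2):
            raise ValueError(
                f"coords shape {self.coords.shape} does not match (n_spots, 2) = {(n, 2)}"
            )
        if self.spot_ids is None:
            self.spot_ids = [f"spot_{i}" for i in range(n)]
        else:
            self.spot_ids = [str(s) for s in self.spot_ids]
        if self.feature_ids is None:
            self.feature_ids = [f"gene_{j}" for j in range(p)]
        else:
            self.feature_ids = [str(f) for f in self.feature_ids]
        if self.modality_tags is None:
            self.modality_tags = ["rna"] * p
        elif len(self.modality_tags) == 1 and p != 1:
            self.modality_tags = list(self.modality_tags) * p
        else:
            self.modality_tags = [str(t) for t in self.modality_tags]
        if len(self.spot_ids) != n:
            raise ValueError(f"{len(self.spot_ids)} spot_ids for {n} spots")
        if len(self.feature_ids) != p:
            raise ValueError(f"{len(self.feature_ids)} feature_ids for {p} features")
        if len(self.modality_tags) != p:
            raise ValueError(f"{len(self.modality_tags)} modality_tags for {p} features")

    @property
    def n_spots(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def dense(self) -> np.ndarray:
        """Expression as a dense ndarray (copy only if sparse)."""
        return self.X.toarray() if sp.issparse(self.X) else self.X

    def subset_features(self, idx) -> "SpatialDataset":
        """New dataset restricted to the given feature indices, order preserved."""
        idx = np.asarray(idx, dtype=int)
        X = self.X[:, idx]
        return SpatialDataset(
            X=X,
            coords=self.coords.copy(),
            spot_ids=list(self.spot_ids),
            feature_ids=[self.feature_ids[j] for j in idx],
            modality_tags=[self.modality_tags[j] for j in idx],
        )


def validate_dataset(ds: SpatialDataset) -> list[str]:
    """Check every dataset invariant; return human-readable issue strings.

    An empty list means the dataset is well formed.  Each issue names the
    violated invariant and the offending index so callers can locate it.
    Checks: non-negativity and finiteness of X, n >= 2, finite coordinates,
    unique spot/feature ids, duplicate coordinates (flagged, not merged) and
    all-zero features (flagged; drop before factorization).
    """
    issues: list[str] = []
    X = ds.X
    if sp.issparse(X):
        data = X.data
    else:
        data = X
    if data.size and not np.all(np.isfinite(data)):
        if sp.issparse(X):
            bad = np.flatnonzero(~np.isfinite(X.tocoo().data))
            coo = X.tocoo()
            for b in bad[:5]:
                issues.append(f"non-finite expression entry at ({coo.row[b]}, {coo.col[b]})")
        else:
            for i, j in zip(*np.where(~np.isfinite(X))):
                issues.append(f"non-finite expression entry at ({i}, {j})")
                if len(issues) >= 5:
                    break
    if data.size and np.any(data < 0):
        if sp.issparse(X):
            coo = X.tocoo()
            neg = np.flatnonzero(coo.data < 0)
            for b in neg[:5]:
                issues.append(f"negative expression entry at ({coo.row[b]}, {coo.col[b]})")
        else:
            locs = np.argwhere(X < 0)
            for i, j in locs[:5]:
                issues.append(f"negative expression entry at ({i}, {j})")
    if ds.n_spots < 2:
        issues.append(f"dataset has {ds.n_spots} spots; at least 2 required")
    if not np.all(np.isfinite(ds.coords)):
        rows = np.unique(np.where(~np.isfinite(ds.coords))[0])
        issues.append(f"non-finite coordinates for spots {rows[:5].tolist()}")
    seen: dict[str, int] = {}
    for j, fid in enumerate(ds.feature_ids):
        if fid in seen:
            issues.append(f"duplicate feature id {fid!r} at indices {seen[fid]} and {j}")
        else:
            seen[fid] = j
    seen.clear()
    for i, sid in enumerate(ds.spot_ids):
        if sid in seen:
            issues.append(f"duplicate spot id {sid!r} at indices {seen[sid]} and {i}")
        else:
            seen[sid] = i
    # duplicate coordinates are legal but suspicious: flag, never merge
    if np.all(np.isfinite(ds.coords)):
        _, inv, counts = np.unique(ds.coords, axis=0, return_inverse=True, return_counts=True)
        if np.any(counts > 1):
            dup = np.flatnonzero(counts[inv] > 1)
            issues.append(f"duplicate coordinates for spots {dup[:6].tolist()}")
    col_sums = np.asarray(X.sum(axis=0)).ravel()
    zero_cols = np.flatnonzero(col_sums == 0)
    for j in zero_cols[:10]:
        issues.append(
            f"feature {j} ({ds.feature_ids[j]!r}) has zero total expression; drop before factorization"
        )
    return issues


@dataclass
class SpatialGraph:
    """Expression-weighted spatial neighborhood graph.

    ``A`` is symmetric with zero diagonal and weights in (0, 1]; ``D`` holds
    the degrees (row sums of ``A``) and ``L = D - A`` is the combinatorial
    Laplacian used for spatial smoothing.
    """

    A: sp.csr_matrix
    D: sp.csr_matrix
    L: sp.csr_matrix
    radius: float
    lam: float
    bandwidth: float
    n_c: int

    @property
    def n_spots(self) -> int:
        return self.A.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.A.sum(axis=1)).ravel()


@dataclass
class FactorParams:
    """Hyperparameters of the graph-regularized factorization.

    ``alpha`` is the spatial-regularization weight (recommended 0.3-1.0 for
    tissue-level domains, 0.1-0.3 for fine niches).  ``beta`` (sparsity) and
    ``gamma`` (metagene orthogonality) default to the derived values
    ``alpha/15`` and ``1.5e-4 * p``; ``gamma`` therefore needs the feature
    count and is filled in by :meth:`resolve`.
    """

    alpha: float = 1.0
    beta: float | None = None
    gamma: float | None = None
    r: int = 30
    max_iter: int = 200
    tol: float = 1e-5
    seed: int = 0
    eps_pattern: float = 0.3
    eps_svg: float = 0.7
    n_cluster: int = 8
    N1: int | None = None
    N2: int | None = None
    lam: float = 1.2
    n_c: int | None = None
    delta: float = 1e-12

    def resolve(self, p: int) -> "FactorParams":
        """Fill derived defaults for a dataset with ``p`` features and validate."""
        beta = self.alpha / 15.0 if self.beta is None else self.beta
        gamma = 1.5e-4 * p if self.gamma is None else self.gamma
        n1 = max(0, self.r - 5 - self.n_cluster) if self.N1 is None else self.N1
        n1 = min(n1, self.r - 1) if self.N1 is None else n1
        # derived default N2 = 3, clamped so that N1 + N2 < r holds for small r
        n2 = min(3, self.r - 1 - n1) if self.N2 is None else self.N2
        n_c = self.n_cluster if self.n_c is None else self.n_c
        out = FactorParams(
            alpha=self.alpha, beta=beta, gamma=gamma, r=self.r,
            max_iter=self.max_iter, tol=self.tol, seed=self.seed,
            eps_pattern=self.eps_pattern, eps_svg=self.eps_svg,
            n_cluster=self.n_cluster, N1=n1, N2=n2, lam=self.lam,
            n_c=n_c, delta=self.delta,
        )
        out.validate()
        return out

    def validate(self) -> None:
        if self.alpha < 0 or (self.beta is not None and self.beta < 0) or (
            self.gamma is not None and self.gamma < 0
        ):
            raise ValueError("alpha, beta, gamma must be non-negative")
        if self.r < 1:
            raise ValueError("pattern number r must be >= 1")
        if not (0 < self.eps_pattern < 1):
            raise ValueError("eps_pattern must lie in (0, 1)")
        if not (0 < self.eps_svg < 1):
            raise ValueError("eps_svg must lie in (0, 1)")
        if (self.N1 is not None and self.N1 < 0) or (self.N2 is not None and self.N2 < 0):
            raise ValueError("N1 and N2 must be non-negative")
        if self.N1 is not None and self.N2 is not None and self.N1 + self.N2 >= self.r:
            raise ValueError(
                f"N1 + N2 = {self.N1 + self.N2} must be smaller than r = {self.r}"
            )
        if self.max_iter < 1:
            raise ValueError("max_iter must be positive")

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


@dataclass
class FactorModel:
    """Fitted factor pair.

    Columns of ``W`` (n × r) are the spatial metagene expression patterns;
    rows of ``H`` (r × p) the metagene signatures.  ``pss`` holds the pattern
    significance score of each pattern (cosine similarity between the
    pattern's observed mean expression profile and its signature, in [0, 1]);
    patterns are reported in descending-PSS order.  ``objective_trace`` has
    one row per outer iteration: (total, reconstruction, spatial, sparsity,
    orthogonality).
    """

    W: np.ndarray
    H: np.ndarray
    pss: np.ndarray
    objective_trace: np.ndarray
    params: FactorParams
    spot_ids: list[str] | None = None
    feature_ids: list[str] | None = None
    modality_tags: list[str] | None = None

    @property
    def r(self) -> int:
        return self.W.shape[1]


@dataclass
class MultisliceModel:
    """Joint fit over M tissue sections: slice-specific patterns, shared signatures."""

    W_list: list[np.ndarray]
    H: np.ndarray
    graphs: list[SpatialGraph]
    pss_list: list[np.ndarray]
    objective_trace: np.ndarray
    params: FactorParams
    spot_ids_list: list[list[str]] | None = None
    feature_ids: list[str] | None = None

    @property
    def n_slices(self) -> int:
        return len(self.W_list)

    def slice_model(self, s: int) -> FactorModel:
        """View slice ``s`` as a single-slice :class:`FactorModel`."""
        return FactorModel(
            W=self.W_list[s], H=self.H, pss=self.pss_list[s],
            objective_trace=self.objective_trace, params=self.params,
            spot_ids=None if self.spot_ids_list is None else self.spot_ids_list[s],
            feature_ids=self.feature_ids,
        )


@dataclass
class PatternAnnotation:
    """Downstream annotation of a fitted model.

    ``Pr`` is the r × p normalized pattern-contribution matrix (columns over
    patterns sum to 1 for expressed features); ``pattern_genes`` maps pattern
    index -> feature ids ordered by descending contribution; ``svg_err`` holds
    per-feature relative reconstruction errors and ``svg_set`` the selected
    spatially-variable features.
    """

    Pr: np.ndarray
    Lambda_norms: np.ndarray
    pattern_genes: Mapping[int, Sequence[str]]
    svg_err: np.ndarray
    svg_set: np.ndarray


@dataclass
class SyntheticTruth:
    """Planted ground truth attached to a generated dataset."""

    W_true: np.ndarray
    H_true: np.ndarray
    domain_labels: np.ndarray
    svg_true: np.ndarray
    generator_params: dict = field(default_factory=dict)
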