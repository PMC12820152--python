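"""Downstream operators on a fitted factor model: pattern-specific genes,
spatially variable genes (SVGs), spatial domains, expression denoising and
refinement diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .datatypes import FactorModel, PatternAnnotation, SpatialGraph
from .preprocess import morans_i_features

__all__ = [
    "pattern_contributions",
    "pattern_specific_genes",
    "svg_scores",
    "select_svgs",
    "annotate",
    "filter_patterns",
    "cluster_domains",
    "denoise",
    "RefinementReport",
    "refinement_report",
    "coexpression_pairs",
]


def pattern_contributions(model: FactorModel) -> np.ndarray:
    """Normalized pattern-contribution matrix Pr (r x p).

    Two-step normalization of H: rows are first scaled by the spatial
    pattern magnitudes, H' = diag(||w_1||_2, ..., ||w_r||_2) H, then each
    column is divided by its l1 norm, so Pr_ij is the fraction of feature j's
    fitted signal attributable to pattern i.  Columns with no signal at all
    (||H'_.j||_1 = 0) are left at 0.  Pr is invariant to the W/H scale
    ambiguity (w_i -> c w_i, h_i -> h_i / c).
    """
    norms = np.linalg.norm(model.W, axis=0)
    Hp = norms[:, None] * model.H
    col = np.abs(Hp).sum(axis=0)
    Pr = np.zeros_like(Hp)
    nz = col > 0
    Pr[:, nz] = Hp[:, nz] / col[nz]
    return Pr


def pattern_specific_genes(
    Pr: np.ndarray,
    eps_pattern: float = 0.3,
    feature_ids: list[str] | None = None,
) -> dict[int, list]:
    """Features whose contribution from a pattern strictly exceeds eps_pattern.

    Returns pattern index -> features ordered by descending contribution.
    A feature may appear under several patterns; a contribution exactly equal
    to the threshold is excluded.
    """
    if not (0 < eps_pattern < 1):
        raise ValueError("eps_pattern must lie in (0, 1)")
    r, p = Pr.shape
    out: dict[int, list] = {}
    for i in range(r):
        hits = np.flatnonzero(Pr[i] > eps_pattern)
        hits = hits[np.argsort(-Pr[i, hits], kind="stable")]
        if feature_ids is not None:
            out[i] = [feature_ids[j] for j in hits]
        else:
            out[i] = hits.tolist()
    return out


def svg_scores(X, model: FactorModel) -> np.ndarray:
    """Relative reconstruction error per feature: err_j = ||X_.j - (WH)_.j|| / ||X_.j||.

    Features the pattern basis explains well score near 0; features with no
    spatial structure score near (or above) 1.  All-zero columns have an
    undefined ratio and get +inf so they can never be selected.
    """
    if sp.issparse(X):
        X = X.toarray()
    X = np.asarray(X, dtype=float)
    R = X - model.W @ model.H
    num = np.linalg.norm(R, axis=0)
    den = np.linalg.norm(X, axis=0)
    err = np.full(X.shape[1], np.inf)
    nz = den > 0
    err[nz] = num[nz] / den[nz]
    return err


def select_svgs(err: np.ndarray, eps_svg: float = 0.7) -> np.ndarray:
    """Feature indices with err strictly below eps_svg, ordered by ascending err."""
    if eps_svg <= 0:
        raise ValueError("eps_svg must be positive")
    err = np.asarray(err, dtype=float)
    hits = np.flatnonzero(err < eps_svg)
    return hits[np.argsort(err[hits], kind="stable")]


def annotate(X, model: FactorModel) -> PatternAnnotation:
    """Bundle contributions, pattern-specific features and SVG scores."""
    Pr = pattern_contributions(model)
    genes = pattern_specific_genes(Pr, model.params.eps_pattern, model.feature_ids)
    err = svg_scores(X, model)
    svg = select_svgs(err, model.params.eps_svg)
    return PatternAnnotation(
        Pr=Pr, Lambda_norms=np.linalg.norm(model.W, axis=0),
        pattern_genes=genes, svg_err=err, svg_set=svg,
    )


def filter_patterns(model: FactorModel, N1: int | None = None, N2: int | None = None):
    """Drop low-abundance and low-significance patterns before clustering.

    First the N1 columns of W with the smallest l2 norms are removed (low
    abundance), then from the remainder the N2 with the lowest PSS (noisy
    components).  Defaults follow N1 = max(0, r - 5 - n_cluster), N2 = 3.
    Ties drop the lower index first.  Returns (W_star, kept_indices) with
    surviving columns in their original order.
    """
    r = model.r
    if N1 is None:
        N1 = model.params.N1
        if N1 is None:
            N1 = max(0, r - 5 - model.params.n_cluster)
    if N2 is None:
        N2 = model.params.N2
    if N1 < 0 or N2 < 0:
        raise ValueError("N1 and N2 must be non-negative")
    if N1 + N2 >= r:
        raise ValueError(f"N1 + N2 = {N1 + N2} must be smaller than r = {r}")
    norms = np.linalg.norm(model.W, axis=0)
    drop_norm = np.lexsort((np.arange(r), norms))[:N1]
    keep = np.setdiff1d(np.arange(r), drop_norm)
    pss = model.pss[keep]
    drop_pss = keep[np.lexsort((np.arange(keep.size), pss))[:N2]]
    keep = np.setdiff1d(keep, drop_pss)
    return model.W[:, keep], keep


def cluster_domains(W_star: np.ndarray, n_cluster: int, seed: int = 0) -> np.ndarray:
    """Spatial domains by k-means on the filtered pattern loadings.

    Uses 10 seeded restarts and keeps the best inertia; labels are 0-based
    and arbitrary.  Requires at least n_cluster distinct rows.
    """
    W_star = np.asarray(W_star, dtype=float)
    if n_cluster > W_star.shape[0]:
        raise ValueError("more clusters requested than spots")
    distinct = np.unique(W_star, axis=0).shape[0]
    if distinct < n_cluster:
        raise ValueError(
            f"only {distinct} distinct loading rows for {n_cluster} clusters"
        )
    km = KMeans(n_clusters=n_cluster, n_init=10, random_state=seed)
    return km.fit_predict(W_star)


def denoise(model: FactorModel) -> np.ndarray:
    """Reconstructed (refined) expression X_hat = W H; non-negative by construction."""
    return model.W @ model.H


@dataclass
class RefinementReport:
    """Per-feature Moran's I before/after refinement plus the improved fraction."""

    per_feature: pd.DataFrame
    fraction_improved: float
    mean_before: float
    mean_after: float


def refinement_report(X, X_hat, g: SpatialGraph, feature_ids=None) -> RefinementReport:
    """Paired spatial-autocorrelation comparison of raw vs refined expression.

    Moran's I is computed feature-wise on X and X_hat with the same graph;
    constant features score 0 on both sides by convention.
    """
    before = morans_i_features(X, g)
    after = morans_i_features(X_hat, g)
    if before.shape != after.shape:
        raise ValueError("X and X_hat have different numbers of features")
    df = pd.DataFrame({"morans_before": before, "morans_after": after})
    if feature_ids is not None:
        df.index = pd.Index(feature_ids, name="feature_id")
    return RefinementReport(
        per_feature=df,
        fraction_improved=float(np.mean(after > before)),
        mean_before=float(before.mean()),
        mean_after=float(after.mean()),
    )


def coexpression_pairs(X_hat, feature_subset, threshold: float = 0.5, feature_ids=None):
    """Highly correlated feature pairs within a subset of the refined matrix.

    Pearson correlation over spots for every unordered pair in
    ``feature_subset``; pairs with correlation strictly above ``threshold``
    are returned sorted descending.  Zero-variance features cannot be
    correlated and are excluded; their indices are reported alongside.
    Returns ``(pairs_df, excluded)``.
    """
    idx = np.asarray(feature_subset, dtype=int)
    if idx.size < 2:
        raise ValueError("at least two features are required")
    if sp.issparse(X_hat):
        X_hat = X_hat.toarray()
    sub = np.asarray(X_hat, dtype=float)[:, idx]
    std = sub.std(axis=0)
    keep = std > 0
    excluded = idx[~keep]
    idx = idx[keep]
    sub = sub[:, keep]
    if idx.size < 2:
        return pd.DataFrame(columns=["feature_a", "feature_b", "correlation"]), excluded
    C = np.corrcoef(sub, rowvar=False)
    iu, ju = np.triu_indices(idx.size, k=1)
    corr = C[iu, ju]
    hit = corr > threshold
    order = np.argsort(-corr[hit], kind="stable")
    a, b, c = idx[iu[hit]][order], idx[ju[hit]][order], corr[hit][order]
    if feature_ids is not None:
        a = [feature_ids[j] for j in a]
        b = [feature_ids[j] for j in b]
    df = pd.DataFrame({"feature_a": a, "feature_b": b, "correlation": c})
    return df, excluded
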