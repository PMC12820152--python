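"""Readers and writers for datasets, fitted models and downstream tables.

On-disk conventions: sparse expression is Matrix Market (``matrix.mtx``)
stored features x spots with ``features.tsv`` / ``barcodes.tsv`` sidecars
(the common trio convention) and transposed to spots x features on load;
dense expression is CSV with spot ids as the index and feature ids as the
header.  Coordinates are a CSV with columns ``spot_id, x, y``.  Every
written dataset carries a ``manifest.json`` with shapes, modality tags and
sha256 checksums.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .datatypes import FactorModel, FactorParams, SpatialDataset

__all__ = [
    "read_dataset",
    "write_dataset",
    "save_model",
    "load_model",
    "write_pattern_genes",
    "write_svg_table",
    "write_domains",
    "to_anndata",
    "from_anndata",
]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_sidecar(path: Path, what: str):
    if not path.exists():
        raise FileNotFoundError(f"missing {what} sidecar: {path}")
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    ids = df[0].tolist()
    tags = df[1].tolist() if df.shape[1] > 1 else None
    return ids, tags


def _read_coords(coords_path: Path, spot_ids: list[str]) -> np.ndarray:
    df = pd.read_csv(coords_path, float_precision="round_trip")
    cols = {c.lower(): c for c in df.columns}
    for needed in ("x", "y"):
        if needed not in cols:
            raise ValueError(f"coords file {coords_path} is missing column {needed!r}")
    if "spot_id" in cols:
        df = df.set_index(df[cols["spot_id"]].astype(str))
    else:
        df = df.set_index(df.columns[0])
        df.index = df.index.astype(str)
    missing = [s for s in spot_ids if s not in df.index]
    if missing:
        raise ValueError(
            f"{len(missing)} spot id(s) in the expression matrix are absent from "
            f"{coords_path}: first missing {missing[0]!r}"
        )
    sub = df.loc[spot_ids]
    return np.column_stack([sub[cols["x"]].to_numpy(float), sub[cols["y"]].to_numpy(float)])


def read_dataset(expression_path, coords_path=None, fmt: str | None = None) -> SpatialDataset:
    """Load a dataset from MTX-with-sidecars or a dense CSV/TSV matrix.

    ``expression_path`` is the ``.mtx`` file (or the directory containing
    ``matrix.mtx``) for sparse input, or the CSV/TSV matrix (spot ids in the
    first column, feature ids in the header).  ``coords_path`` defaults to
    ``coords.csv`` next to the expression file.  Negative entries and
    expression/coordinate id mismatches are rejected.
    """
    path = Path(expression_path)
    if path.is_dir():
        path = path / "matrix.mtx"
    if fmt is None:
        fmt = {".mtx": "mtx", ".csv": "csv", ".tsv": "tsv"}.get(path.suffix.lower())
        if fmt is None:
            raise ValueError(f"cannot infer format from {path.name!r}; pass fmt=")
    if coords_path is None:
        coords_path = path.parent / "coords.csv"
    coords_path = Path(coords_path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if not coords_path.exists():
        raise FileNotFoundError(f"coordinates file not found: {coords_path}")

    if fmt == "mtx":
        M = sio.mmread(path)  # features x spots on disk
        X = sp.csr_matrix(M).T.tocsr()
        feature_ids, tags = _read_sidecar(path.parent / "features.tsv", "features.tsv")
        spot_ids, _ = _read_sidecar(path.parent / "barcodes.tsv", "barcodes.tsv")
        if len(feature_ids) != X.shape[1]:
            raise ValueError(
                f"features.tsv lists {len(feature_ids)} features but the matrix has {X.shape[1]}"
            )
        if len(spot_ids) != X.shape[0]:
            raise ValueError(
                f"barcodes.tsv lists {len(spot_ids)} spots but the matrix has {X.shape[0]}"
            )
    elif fmt in ("csv", "tsv"):
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t", index_col=0,
                         float_precision="round_trip")
        X = df.to_numpy(dtype=float)
        spot_ids = [str(s) for s in df.index]
        feature_ids = [str(f) for f in df.columns]
        tags = None
    else:
        raise ValueError(f"unknown format {fmt!r}; expected mtx, csv or tsv")

    data = X.data if sp.issparse(X) else X
    if data.size and np.any(data < 0):
        raise ValueError(f"expression matrix {path} contains negative entries")
    coords = _read_coords(coords_path, spot_ids)
    return SpatialDataset(X=X, coords=coords, spot_ids=spot_ids,
                          feature_ids=feature_ids, modality_tags=tags)


def write_dataset(ds: SpatialDataset, out_dir, fmt: str = "mtx") -> dict[str, Path]:
    """Write expression + coords + manifest; returns the emitted paths.

    MTX output stores the matrix features x spots (transposed back on load);
    integer-valued matrices are written with an integer field so counts
    round-trip bit-exactly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if fmt == "mtx":
        X = sp.coo_matrix(ds.X)
        if X.data.size == 0 or np.all(X.data == np.floor(X.data)):
            X = X.astype(np.int64)
            sio.mmwrite(out / "matrix.mtx", X.T)
        else:
            sio.mmwrite(out / "matrix.mtx", X.T, precision=17)
        paths["matrix"] = out / "matrix.mtx"
        with open(out / "features.tsv", "w") as fh:
            for fid, tag in zip(ds.feature_ids, ds.modality_tags):
                fh.write(f"{fid}\t{tag}\n")
        paths["features"] = out / "features.tsv"
        with open(out / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(ds.spot_ids) + "\n")
        paths["barcodes"] = out / "barcodes.tsv"
    elif fmt == "csv":
        df = pd.DataFrame(ds.dense(), index=ds.spot_ids, columns=ds.feature_ids)
        df.index.name = "spot_id"
        df.to_csv(out / "expression.csv")
        paths["matrix"] = out / "expression.csv"
    else:
        raise ValueError(f"unknown format {fmt!r}; expected mtx or csv")

    coords = pd.DataFrame(
        {"spot_id": ds.spot_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]}
    )
    coords.to_csv(out / "coords.csv", index=False)
    paths["coords"] = out / "coords.csv"

    manifest = {
        "format": fmt,
        "n_spots": ds.n_spots,
        "n_features": ds.n_features,
        "modality_tags": sorted(set(ds.modality_tags)),
        "mtx_orientation": "features_x_spots" if fmt == "mtx" else None,
        "files": {p.name: _sha256(p) for p in paths.values()},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    paths["manifest"] = out / "manifest.json"
    return paths


def save_model(model: FactorModel, out_dir) -> dict[str, Path]:
    """Persist a fitted model as W.csv / H.csv / pss.csv / trace.csv / params.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    r = model.r
    pat = [f"pattern_{i}" for i in range(r)]
    spot_ids = model.spot_ids or [f"spot_{i}" for i in range(model.W.shape[0])]
    feat_ids = model.feature_ids or [f"gene_{j}" for j in range(model.H.shape[1])]
    paths = {}
    dfw = pd.DataFrame(model.W, index=spot_ids, columns=pat)
    dfw.index.name = "spot_id"
    dfw.to_csv(out / "W.csv")
    paths["W"] = out / "W.csv"
    dfh = pd.DataFrame(model.H, index=pat, columns=feat_ids)
    dfh.index.name = "pattern"
    dfh.to_csv(out / "H.csv")
    paths["H"] = out / "H.csv"
    dfp = pd.DataFrame({"pattern": pat, "pss": model.pss})
    dfp.to_csv(out / "pss.csv", index=False)
    paths["pss"] = out / "pss.csv"
    dft = pd.DataFrame(
        model.objective_trace,
        columns=["total", "recon", "spatial", "sparsity", "ortho"],
    )
    dft.index.name = "iteration"
    dft.to_csv(out / "trace.csv")
    paths["trace"] = out / "trace.csv"
    meta = {"params": model.params.to_dict(), "modality_tags": model.modality_tags}
    with open(out / "params.json", "w") as fh:
        json.dump(meta, fh, indent=2)
    paths["params"] = out / "params.json"
    return paths


def load_model(model_dir) -> FactorModel:
    """Load a model previously written by :func:`save_model`."""
    d = Path(model_dir)
    for name in ("W.csv", "H.csv", "pss.csv", "params.json"):
        if not (d / name).exists():
            raise FileNotFoundError(
                f"missing model artifact {name!r} in {d}; run the fit command first"
            )
    W = pd.read_csv(d / "W.csv", index_col=0)
    H = pd.read_csv(d / "H.csv", index_col=0)
    pss = pd.read_csv(d / "pss.csv")["pss"].to_numpy(float)
    trace_path = d / "trace.csv"
    trace = (
        pd.read_csv(trace_path, index_col=0).to_numpy(float)
        if trace_path.exists() else np.zeros((0, 5))
    )
    with open(d / "params.json") as fh:
        meta = json.load(fh)
    params = FactorParams(**meta["params"])
    return FactorModel(
        W=W.to_numpy(float), H=H.to_numpy(float), pss=pss, objective_trace=trace,
        params=params, spot_ids=[str(s) for s in W.index],
        feature_ids=[str(f) for f in H.columns],
        modality_tags=meta.get("modality_tags"),
    )


def write_pattern_genes(Pr, genes: dict, feature_ids, modality_tags, path) -> None:
    """pattern_genes.tsv: one row per (pattern, feature) with contribution and modality."""
    fid_to_col = {f: j for j, f in enumerate(feature_ids)}
    rows = []
    for pat, feats in genes.items():
        for f in feats:
            j = fid_to_col[f] if isinstance(f, str) else int(f)
            rows.append((pat, feature_ids[j], modality_tags[j], Pr[pat, j]))
    df = pd.DataFrame(rows, columns=["pattern", "feature_id", "modality", "contribution"])
    df.to_csv(path, sep="\t", index=False)


def write_svg_table(err, svg_set, feature_ids, path) -> None:
    """svg.tsv: per-feature reconstruction error and selection flag."""
    selected = np.zeros(len(feature_ids), dtype=bool)
    selected[np.asarray(svg_set, dtype=int)] = True
    df = pd.DataFrame({"feature_id": feature_ids, "err": err, "selected": selected})
    df.to_csv(path, sep="\t", index=False)


def write_domains(labels, spot_ids, path) -> None:
    """domains.csv: spot id and integer domain label."""
    pd.DataFrame({"spot_id": spot_ids, "label": labels}).to_csv(path, index=False)


def to_anndata(ds: SpatialDataset):
    """Optional adapter: dataset -> AnnData (coords in obsm['spatial'])."""
    import anndata as ad

    adata = ad.AnnData(X=ds.X if sp.issparse(ds.X) else np.asarray(ds.X))
    adata.obs_names = ds.spot_ids
    adata.var_names = ds.feature_ids
    adata.var["modality"] = ds.modality_tags
    adata.obsm["spatial"] = ds.coords.copy()
    return adata


def from_anndata(adata) -> SpatialDataset:
    """Optional adapter: AnnData with obsm['spatial'] -> dataset."""
    if "spatial" not in adata.obsm:
        raise ValueError("AnnData has no obsm['spatial'] coordinates")
    tags = (
        [str(t) for t in adata.var["modality"]]
        if "modality" in adata.var else None
    )
    return SpatialDataset(
        X=adata.X, coords=np.asarray(adata.obsm["spatial"], dtype=float),
        spot_ids=[str(s) for s in adata.obs_names],
        feature_ids=[str(f) for f in adata.var_names],
        modality_tags=tags,
    )
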