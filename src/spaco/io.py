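"""Readers and writers: MTX triplet directories, delimited tables, Visium
coordinate files, and the model archive.

Conventions: on-disk MatrixMarket triplets are genes x spots and 1-based
(the 10x convention) and are transposed to spots x genes on read; spot
order is always defined by the expression matrix, and coordinates are
joined to it by spot id, never by file order.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from . import __version__
from .core import SpacoModel
from .moran import MoranOperator
from .preprocess import ExpressionMatrix
from .weights import Coordinates

__all__ = [
    "read_matrix", "write_matrix", "read_coordinates", "align_coordinates",
    "save_model", "load_model",
]


def read_matrix(path, format: str, layer: str = "counts") -> ExpressionMatrix:
    """Read a spots x genes matrix from an MTX directory or a delimited table.

    ``mtx_dir`` expects ``matrix.mtx`` plus gene and barcode lists
    (``features.tsv``/``genes.tsv`` and ``barcodes.tsv``); the triplet file
    is genes x spots and is transposed.  ``tsv`` expects spots as rows
    (index column = spot id, header = gene ids).
    """
    path = Path(path)
    if format == "mtx_dir":
        mtx = _find(path, ["matrix.mtx"])
        genes = _find(path, ["features.tsv", "genes.tsv", "features.txt", "genes.txt"])
        barcodes = _find(path, ["barcodes.tsv", "barcodes.txt"])
        M = mmread(str(mtx))
        gene_ids = pd.read_csv(genes, sep="\t", header=None)[0].astype(str).tolist()
        spot_ids = pd.read_csv(barcodes, sep="\t", header=None)[0].astype(str).tolist()
        X = np.asarray(sp.csr_matrix(M).T.todense())  # genes x spots -> spots x genes
        if X.shape != (len(spot_ids), len(gene_ids)):
            raise ValueError(
                f"matrix shape {M.shape} (genes x spots) does not match "
                f"{len(gene_ids)} genes x {len(spot_ids)} barcodes"
            )
        return ExpressionMatrix(X, spot_ids, gene_ids, layer=layer)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return ExpressionMatrix(
            df.to_numpy(dtype=float),
            df.index.astype(str).tolist(),
            df.columns.astype(str).tolist(),
            layer=layer,
        )
    raise ValueError(f"unknown matrix format {format!r}")


def _find(directory: Path, names: list[str]) -> Path:
    for name in names:
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"none of {names} found in {directory}")


def write_matrix(X: ExpressionMatrix, path, format: str) -> None:
    """Write a matrix as an MTX directory (genes x spots triplet) or a TSV."""
    path = Path(path)
    if format == "mtx_dir":
        path.mkdir(parents=True, exist_ok=True)
        mmwrite(str(path / "matrix.mtx"), sp.coo_matrix(X.X.T))
        pd.Series(X.gene_ids).to_csv(
            path / "features.tsv", sep="\t", index=False, header=False
        )
        pd.Series(X.spot_ids).to_csv(
            path / "barcodes.tsv", sep="\t", index=False, header=False
        )
    elif format == "tsv":
        pd.DataFrame(X.X, index=X.spot_ids, columns=X.gene_ids).to_csv(
            path, sep="\t"
        )
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_coordinates(path, dialect: str = "simple") -> Coordinates:
    """Read spot coordinates.

    ``simple``: a delimited file with columns (spot_id, x, y), header
    optional.  ``visium_positions``: the 10x tissue_positions CSV (barcode,
    in_tissue, array_row, array_col, pixel row, pixel col), with or without
    a header line; rows with in_tissue = 0 are dropped and array_col /
    array_row are used as x / y.
    """
    path = Path(path)
    if dialect == "simple":
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 3:
            raise ValueError("simple coordinate file needs columns spot_id, x, y")
        first = str(df.columns[0])
        try:  # headerless file: the "header" row is data
            float(str(df.columns[1]))
            df = pd.read_csv(path, sep=None, engine="python", header=None)
        except ValueError:
            pass
        df = df.iloc[:, :3]
        df.columns = ["spot_id", "x", "y"]
        return Coordinates(
            spot_ids=df["spot_id"].astype(str).tolist(),
            x=df["x"].to_numpy(dtype=float),
            y=df["y"].to_numpy(dtype=float),
        )
    if dialect == "visium_positions":
        head = pd.read_csv(path, nrows=1, header=None)
        has_header = str(head.iloc[0, 0]).lower() in ("barcode", "barcodes")
        df = pd.read_csv(path, header=0 if has_header else None)
        df = df.iloc[:, :6]
        df.columns = ["barcode", "in_tissue", "array_row", "array_col",
                      "pxl_row", "pxl_col"]
        df = df[df["in_tissue"].astype(int) == 1]
        return Coordinates(
            spot_ids=df["barcode"].astype(str).tolist(),
            x=df["array_col"].to_numpy(dtype=float),
            y=df["array_row"].to_numpy(dtype=float),
        )
    raise ValueError(f"unknown coordinate dialect {dialect!r}")


def align_coordinates(coords: Coordinates, spot_ids: list[str]) -> Coordinates:
    """Reorder coordinates to the expression matrix's spot order, joining by id."""
    index = {s: i for i, s in enumerate(coords.spot_ids)}
    missing = [s for s in spot_ids if s not in index]
    if missing:
        raise ValueError(
            f"{len(missing)} spot(s) in the matrix are missing from the "
            f"coordinates: {', '.join(missing[:10])}"
        )
    order = np.array([index[s] for s in spot_ids])
    return Coordinates(
        spot_ids=list(spot_ids),
        x=coords.x[order],
        y=coords.y[order],
        torus_extent=coords.torus_extent,
    )


def save_model(model: SpacoModel, L: MoranOperator, path, config: dict | None = None) -> None:
    """Write the model as a directory of delimited files plus a JSON manifest."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "n_spots": model.n_spots,
        "q": model.q,
        "k": model.k,
        "threshold": model.threshold,
        "fwer": model.fwer,
        "seed": model.seed,
        "total_weight": L.total_weight,
        "config": config or {},
    }
    (path / "manifest.json").write_text(json.dumps(manifest, indent=2))
    np.savetxt(path / "eigenvalues.tsv", model.eigenvalues, delimiter="\t")
    np.savetxt(path / "components.tsv", model.components, delimiter="\t")
    np.savetxt(path / "orthonormal_patterns.tsv", model.orthonormal_patterns,
               delimiter="\t")
    np.savetxt(path / "gene_loadings.tsv", model.gene_loadings, delimiter="\t")
    if model.null_sample is not None:
        np.savetxt(path / "null_sample.tsv", model.null_sample, delimiter="\t")
    pd.DataFrame(
        model.patterns, index=model.spot_ids,
        columns=[f"SpaC{i + 1}" for i in range(model.q)],
    ).to_csv(path / "patterns.csv")
    pd.Series(model.gene_ids).to_csv(path / "genes.tsv", sep="\t",
                                     index=False, header=False)
    mmwrite(str(path / "weights.mtx"), sp.coo_matrix(L.W), symmetry="symmetric")


def load_model(path) -> tuple[SpacoModel, MoranOperator]:
    """Reload a model archive written by :func:`save_model`."""
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    patterns = pd.read_csv(path / "patterns.csv", index_col=0)
    null_path = path / "null_sample.tsv"
    model = SpacoModel(
        eigenvalues=np.atleast_1d(np.loadtxt(path / "eigenvalues.tsv")),
        components=np.atleast_2d(np.loadtxt(path / "components.tsv")),
        patterns=patterns.to_numpy(),
        orthonormal_patterns=np.atleast_2d(
            np.loadtxt(path / "orthonormal_patterns.tsv")
        ),
        gene_loadings=np.atleast_2d(np.loadtxt(path / "gene_loadings.tsv")),
        spot_ids=patterns.index.astype(str).tolist(),
        gene_ids=pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0]
        .astype(str).tolist(),
        k=manifest["k"],
        threshold=manifest["threshold"],
        fwer=manifest["fwer"],
        null_sample=np.atleast_1d(np.loadtxt(null_path)) if null_path.exists() else None,
        seed=manifest["seed"],
    )
    W = sp.csr_matrix(mmread(str(path / "weights.mtx")))
    L = MoranOperator(W=W, n=W.shape[0], total_weight=float(W.sum()))
    return model, L
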