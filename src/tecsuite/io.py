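"""Plain-text IO for the pipeline's standard shapes.

Count matrices travel as MatrixMarket + genes.tsv/cells.tsv (or dense CSV);
HTO counts and tissue panels as CSV; germline loci as FASTA (see
:mod:`tecsuite.tcr`); generator ground truth as a JSON sidecar kept apart
from the files pipelines consume.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "write_cell_matrix",
    "read_cell_matrix",
    "write_truth_json",
    "read_hto_csv",
    "read_tissue_panel_csv",
]


def write_cell_matrix(adata: AnnData, outdir) -> None:
    """Write counts as matrix.mtx (genes x cells) + genes.tsv + cells.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), X.T.tocoo())
    adata.var.to_csv(outdir / "genes.tsv", sep="\t")
    adata.obs.to_csv(outdir / "cells.tsv", sep="\t")


def read_cell_matrix(indir) -> AnnData:
    """Read a matrix written by :func:`write_cell_matrix`."""
    indir = Path(indir)
    X = sp.csr_matrix(scipy.io.mmread(str(indir / "matrix.mtx"))).T
    var = pd.read_csv(indir / "genes.tsv", sep="\t", index_col=0)
    obs = pd.read_csv(indir / "cells.tsv", sep="\t", index_col=0)
    obs.index = obs.index.astype(str)
    var.index = var.index.astype(str)
    return AnnData(X=X.tocsr(), obs=obs, var=var)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_truth_json(truth: dict, path) -> None:
    """Ground-truth sidecar, kept separate from pipeline inputs."""
    with open(path, "w") as fh:
        json.dump(_jsonable(truth), fh, indent=1)


def read_hto_csv(path) -> pd.DataFrame:
    """HTO x barcode counts from CSV (rows = HTOs)."""
    return pd.read_csv(path, index_col=0)


def read_tissue_panel_csv(path) -> pd.DataFrame:
    """Gene x tissue expression panel from CSV."""
    return pd.read_csv(path, index_col=0)
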