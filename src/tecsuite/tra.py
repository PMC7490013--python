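"""Tau tissue-specificity index and tissue-restricted-antigen accounting.

The tau index of a gene with expression profile x over n tissues is

    tau = sum_i (1 - x_i / max_j x_j) / (n - 1)

and lies in [0, 1]: 0 for a perfectly uniform profile and 1 for expression
confined to a single tissue.  Genes with tau >= 0.8 are classed as
tissue-restricted antigens (TRA), tau <= 0.4 as constitutively expressed,
and everything between as miscellaneous.  Each TRA gene is assigned to the
tissue in which it is maximally expressed.  Per-cell tissue representation
counts how many TRA genes of each assigned tissue a cell expresses
(log-normalised expression > 0), aggregated per (age, replicate) for
downstream abundance modelling.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = ["tau", "compute_tau_table", "count_tissue_representation"]

logger = logging.getLogger(__name__)

TRA_THRESHOLD = 0.8
CONSTITUTIVE_THRESHOLD = 0.4


def tau(profile) -> float:
    """Tau tissue-specificity index of one non-negative expression profile.

    Returns NaN for an all-zero profile.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a 1-D vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    m = x.max()
    if m == 0:
        return float("nan")
    return float((1.0 - x / m).sum() / (x.size - 1))


def compute_tau_table(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-gene tau, specificity class and assigned tissue.

    ``panel`` is genes x tissues (per-tissue value = maximum normalised
    expression over the tissue's samples, isoforms pre-collapsed by mean).
    All-zero genes are excluded with a warning.  Ties in the maximally
    expressed tissue are broken by column order and logged.
    """
    if panel.shape[1] < 2:
        raise ValueError("panel must cover at least 2 tissues")
    X = panel.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("panel contains negative expression values")
    nonzero = X.max(axis=1) > 0
    if not nonzero.all():
        warnings.warn(f"excluding {(~nonzero).sum()} all-zero genes from the tau table")
    X = X[nonzero]
    genes = panel.index[nonzero]
    n = X.shape[1]
    xhat = X / X.max(axis=1, keepdims=True)
    taus = (1.0 - xhat).sum(axis=1) / (n - 1)
    cls = np.select(
        [taus >= TRA_THRESHOLD, taus <= CONSTITUTIVE_THRESHOLD],
        ["TRA", "constitutive"],
        "miscellaneous",
    )
    argmax = X.argmax(axis=1)
    ties = (X == X.max(axis=1, keepdims=True)).sum(axis=1) > 1
    for g in genes[ties & (cls == "TRA")]:
        logger.info("tau table: %s has tied maximal tissues; using column order", g)
    tissue = np.where(cls == "TRA", panel.columns.to_numpy()[argmax], None)
    return pd.DataFrame(
        {"tau": taus, "class": cls, "assigned_tissue": tissue}, index=genes
    )


def count_tissue_representation(
    adata: AnnData,
    tau_table: pd.DataFrame,
    layer: str = "lognorm",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tissue-representation counts from single-cell expression.

    For every cell and assigned tissue, counts the TRA genes with
    log-normalised expression > 0 (i.e. any non-zero normalised count), and
    aggregates the counts over cells within each (age, replicate) group.

    Returns ``(tissue_counts, per_cell)`` where ``tissue_counts`` is a tidy
    frame (age, replicate, tissue, count) and ``per_cell`` holds the
    per-cell per-tissue counts plus ``pct_tra_of_expressed`` — the
    percentage of a cell's expressed genes classed as TRA.
    """
    for col in ("age", "replicate"):
        if col not in adata.obs:
            raise KeyError(f"obs column {col!r} required")
    tra = tau_table[tau_table["class"] == "TRA"]
    tra = tra[tra.index.isin(adata.var_names)]
    X = adata.layers[layer] if layer in adata.layers else adata.X
    expressed = (X > 0)
    if sp.issparse(expressed):
        expressed = np.asarray(expressed.todense())
    expressed = np.asarray(expressed)
    n_expressed = expressed.sum(axis=1)
    if len(tra) == 0:
        warnings.warn("no TRA genes present in the matrix; returning empty table")
        per_cell = pd.DataFrame(index=adata.obs_names)
        per_cell["pct_tra_of_expressed"] = 0.0
        empty = pd.DataFrame(columns=["age", "replicate", "tissue", "count"])
        return empty, per_cell

    gene_pos = pd.Series(np.arange(adata.n_vars), index=adata.var_names)
    per_tissue = {}
    for tissue, genes in tra.groupby("assigned_tissue").groups.items():
        cols = gene_pos[list(genes)].to_numpy()
        per_tissue[tissue] = expressed[:, cols].sum(axis=1)
    per_cell = pd.DataFrame(per_tissue, index=adata.obs_names)
    tra_cols = gene_pos[tra.index].to_numpy()
    n_tra_expressed = expressed[:, tra_cols].sum(axis=1)
    with np.errstate(invalid="ignore"):
        pct = np.where(n_expressed > 0, 100.0 * n_tra_expressed / np.maximum(n_expressed, 1), 0.0)
    per_cell["pct_tra_of_expressed"] = pct

    melted = per_cell.drop(columns="pct_tra_of_expressed").copy()
    melted["age"] = adata.obs["age"].to_numpy()
    melted["replicate"] = adata.obs["replicate"].to_numpy()
    tissue_counts = (
        melted.melt(id_vars=["age", "replicate"], var_name="tissue", value_name="count")
        .groupby(["age", "replicate", "tissue"], as_index=False)["count"]
        .sum()
    )
    tissue_counts["count"] = tissue_counts["count"].astype(int)
    return tissue_counts, per_cell
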