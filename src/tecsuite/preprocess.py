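"""Quality control, normalisation and highly-variable-gene selection.

Operates on ``AnnData`` objects laid out cells x genes, with per-gene
boolean flags ``is_ercc`` / ``is_mito`` in ``.var`` and per-cell metadata in
``.obs``.  Two QC modes mirror the two assay types: plate-based wells are
filtered on ERCC spike-in fraction, sequencing depth and sparsity; droplet
barcodes on mitochondrial fraction (an upper median + 2*MAD fence, computed
within each sample) and total UMIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

__all__ = [
    "QcThresholds",
    "qc_filter",
    "normalize",
    "select_hvgs",
    "deconvolution_size_factors",
]


@dataclass
class QcThresholds:
    """Cell-filtering thresholds.

    Plate mode: cells fail on ERCC fraction > ``max_ercc_fraction``, depth
    < ``min_depth`` read pairs, or sparsity > ``max_sparsity``.  Droplet
    mode: cells fail on mitochondrial fraction above the per-sample median
    + ``mito_n_mads`` * MAD, or total UMIs < ``min_umis``.  ``mad_scale`` of
    1.0 is the raw median absolute deviation; set 1.4826 for the
    normal-consistent estimator.
    """

    max_ercc_fraction: float = 0.40
    min_depth: float = 1e5
    max_sparsity: float = 0.97
    mito_n_mads: float = 2.0
    mad_scale: float = 1.0
    min_umis: float = 1000.0


def _totals(X) -> np.ndarray:
    return np.asarray(X.sum(axis=1)).ravel()


def _flag_fraction(adata: AnnData, flag: str) -> np.ndarray:
    if flag not in adata.var:
        raise KeyError(f"gene flag {flag!r} missing from .var")
    mask = adata.var[flag].to_numpy(dtype=bool)
    total = _totals(adata.X)
    sub = np.asarray(adata.X[:, mask].sum(axis=1)).ravel()
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, sub / np.maximum(total, 1), 0.0)
    return frac


def qc_filter(
    adata: AnnData,
    mode: str = "plate",
    thresholds: QcThresholds | None = None,
) -> tuple[AnnData, pd.DataFrame]:
    """Filter poor-quality cells; returns the filtered matrix and a report.

    The report covers every input cell with its metrics, a ``pass`` flag and
    a semicolon-joined ``reasons`` string for failures.
    """
    if adata.n_obs == 0 or adata.n_vars == 0:
        raise ValueError("empty matrix")
    th = thresholds or QcThresholds()
    total = _totals(adata.X)
    nnz = adata.X.getnnz(axis=1) if sp.issparse(adata.X) else (adata.X > 0).sum(axis=1)
    sparsity = 1.0 - np.asarray(nnz).ravel() / adata.n_vars
    report = pd.DataFrame(index=adata.obs_names)
    report["total_counts"] = total
    report["sparsity"] = sparsity
    reasons = [[] for _ in range(adata.n_obs)]

    if mode == "plate":
        ercc = _flag_fraction(adata, "is_ercc")
        report["ercc_fraction"] = ercc
        for i in range(adata.n_obs):
            if ercc[i] > th.max_ercc_fraction:
                reasons[i].append("high_ercc")
            if total[i] < th.min_depth:
                reasons[i].append("low_depth")
            if sparsity[i] > th.max_sparsity:
                reasons[i].append("high_sparsity")
    elif mode == "droplet":
        mito = _flag_fraction(adata, "is_mito")
        report["mito_fraction"] = mito
        sample = (
            adata.obs["sample"].to_numpy()
            if "sample" in adata.obs
            else np.zeros(adata.n_obs, dtype=int)
        )
        fence = np.empty(adata.n_obs)
        for s in np.unique(sample):
            m = sample == s
            med = np.median(mito[m])
            mad = th.mad_scale * np.median(np.abs(mito[m] - med))
            fence[m] = med + th.mito_n_mads * mad
        report["mito_fence"] = fence
        for i in range(adata.n_obs):
            if mito[i] > fence[i]:
                reasons[i].append("high_mito")
            if total[i] < th.min_umis:
                reasons[i].append("low_umis")
    else:
        raise ValueError(f"unknown QC mode {mode!r}")

    report["pass"] = [not r for r in reasons]
    report["reasons"] = [";".join(r) for r in reasons]
    kept = adata[report["pass"].to_numpy()].copy()
    return kept, report


def deconvolution_size_factors(counts: np.ndarray, pool_sizes=(21, 41, 61)) -> np.ndarray:
    """Pooled-ratio size factors (ring pooling + least squares).

    Cells are arranged on a ring ordered by library size; for each window
    size the pooled counts are compared to the average cell profile, and the
    per-cell factors are recovered by solving the resulting sparse linear
    system.  Factors are rescaled to unit geometric mean.
    """
    n = counts.shape[0]
    pool_sizes = [p for p in pool_sizes if p <= n] or [max(2, n // 2)]
    totals = counts.sum(axis=1)
    order = np.argsort(totals)
    ref = counts.mean(axis=0)
    keep = ref > 0
    ref = ref[keep]
    rows, cols, vals, b = [], [], [], []
    eq = 0
    for p in pool_sizes:
        for start in range(n):
            idx = order[(start + np.arange(p)) % n]
            pooled = counts[np.ix_(idx, np.where(keep)[0])].sum(axis=0)
            ratio = np.median(pooled / ref)
            for j in idx:
                rows.append(eq); cols.append(j); vals.append(1.0)
            b.append(ratio)
            eq += 1
    A = sp.csr_matrix((vals, (rows, cols)), shape=(eq, n))
    sol = sp.linalg.lsqr(A, np.asarray(b))[0]
    sol = np.clip(sol, 1e-8, None)
    return sol / np.exp(np.mean(np.log(sol)))


def normalize(adata: AnnData, method: str = "library_size") -> AnnData:
    """Compute size factors and log10(normalised + 1) expression.

    ``library_size``: per-cell total over the geometric mean of totals.
    ``deconvolution``: pooled-ratio scheme (see
    :func:`deconvolution_size_factors`).  Stores ``obs['size_factor']`` and
    ``layers['lognorm']``; zeros stay zero.
    """
    total = _totals(adata.X)
    if np.any(total <= 0):
        raise ValueError("cells with zero total counts; run qc_filter first")
    if method == "library_size":
        sf = total / np.exp(np.mean(np.log(total)))
    elif method == "deconvolution":
        dense = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
        sf = deconvolution_size_factors(dense)
    else:
        raise ValueError(f"unknown normalisation method {method!r}")
    adata = adata.copy()
    adata.obs["size_factor"] = sf
    X = adata.X.astype(float)
    if sp.issparse(X):
        X = X.tocsr(copy=True)
        norm = X.multiply(1.0 / sf[:, None]).tocsr()
        norm.data = np.log10(norm.data + 1.0)
        adata.layers["lognorm"] = norm
    else:
        adata.layers["lognorm"] = np.log10(X / sf[:, None] + 1.0)
    return adata


def select_hvgs(
    adata: AnnData,
    fdr: float = 1e-7,
    layer: str = "lognorm",
    trend_degree: int = 2,
    min_genes: int = 10,
    fallback_top_k: int = 2000,
) -> pd.DataFrame:
    """Highly variable genes from a mean-variance trend.

    Fits a polynomial trend of per-gene variance on mean log-normalised
    expression, tests each gene's excess variance with a chi-square test
    ((n-1)*var/trend ~ chi2(n-1), upper tail), and Benjamini-Hochberg
    adjusts across genes.  Returns a per-gene frame with ``mean``, ``var``,
    ``trend``, ``pvalue``, ``fdr`` and ``highly_variable``.  If the trend
    fit is degenerate (e.g. constant variances) the top ``fallback_top_k``
    genes by residual variance are flagged instead.
    """
    if adata.n_vars < min_genes:
        raise ValueError(f"need at least {min_genes} genes")
    X = adata.layers[layer] if layer in adata.layers else adata.X
    if sp.issparse(X):
        X = np.asarray(X.todense())
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    mean = X.mean(axis=0)
    var = X.var(axis=0, ddof=1)
    from statsmodels.stats.multitest import multipletests

    coeffs = np.polyfit(mean, var, deg=trend_degree)
    trend = np.clip(np.polyval(coeffs, mean), 1e-12, None)
    from scipy.stats import chi2

    stat = (n - 1) * var / trend
    pvals = chi2.sf(stat, df=n - 1)
    degenerate = np.all(var <= 1e-12) or not np.isfinite(trend).all()
    out = pd.DataFrame(
        {"mean": mean, "var": var, "trend": trend, "pvalue": pvals},
        index=adata.var_names,
    )
    if degenerate:
        warnings.warn("degenerate variance structure; falling back to top-K residual variance")
        resid = var - trend
        k = min(fallback_top_k, adata.n_vars)
        top = np.argsort(resid)[::-1][:k]
        hv = np.zeros(adata.n_vars, dtype=bool)
        hv[top] = True
        out["fdr"] = np.nan
        out["highly_variable"] = hv
        return out
    out["fdr"] = multipletests(pvals, method="fdr_bh")[1]
    out["highly_variable"] = out["fdr"] <= fdr
    return out
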