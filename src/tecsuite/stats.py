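"""Abundance and trend models for ageing single-cell experiments.

The battery mirrors the count-based workflow of multi-age cell atlases:

* :func:`nb_abundance_test` — negative binomial GLM of per-cluster cell
  counts on age (weeks), weighted by the total cells captured per
  replicate, tested with a quasi-likelihood F-test (dispersion shrunk
  toward the across-group mean) and Benjamini-Hochberg control at FDR 1%.
* :func:`poisson_state_test` — Poisson GLM of per-state cell counts on
  age, Bonferroni-corrected within a lineage at p <= 0.01.
* :func:`offset_selection_test` — negative binomial GLM with
  log(parent population) as offset, for staged selection counts.
* :func:`age_expression_trend` — vectorised per-gene linear model of
  log-normalised expression on log2(age), adjusted for sequencing depth.
* :func:`adjust_pvalues` — BH / Bonferroni multiplicity control.

All fits are deterministic (IRLS with fixed iteration caps).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "adjust_pvalues",
    "estimate_nb_dispersion",
    "nb_abundance_test",
    "poisson_state_test",
    "offset_selection_test",
    "age_expression_trend",
]

_REQUIRED = ["group", "age", "replicate", "count"]


def adjust_pvalues(p, method: str = "BH") -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    key = {"BH": "fdr_bh", "bonferroni": "bonferroni"}.get(method)
    if key is None:
        raise ValueError(f"unknown method {method!r}")
    return multipletests(p, method=key)[1]


def _check_table(table: pd.DataFrame, extra=()) -> pd.DataFrame:
    cols = _REQUIRED + list(extra)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise KeyError(f"table is missing columns {missing}")
    t = table.copy()
    if (t["count"] < 0).any():
        raise ValueError("counts must be non-negative")
    if (t["age"] <= 0).any():
        raise ValueError("ages must be positive")
    return t


def estimate_nb_dispersion(y: np.ndarray, mu: np.ndarray) -> float:
    """Method-of-moments NB dispersion alpha (var = mu + alpha*mu^2)."""
    num = ((y - mu) ** 2 - mu).sum()
    den = (mu**2).sum()
    return float(max(num / den, 0.0)) if den > 0 else 0.0


def _design(age: np.ndarray, terms: str) -> np.ndarray:
    cols = [np.ones_like(age, dtype=float), age.astype(float)]
    if terms == "linear+quadratic":
        cols.append(age.astype(float) ** 2)
    elif terms != "linear":
        raise ValueError(f"unknown terms {terms!r}")
    return np.column_stack(cols)


def _fit_nb_glm(y, X, *, weights=None, offset=None):
    """Poisson pilot fit for dispersion, then NB GLM at that dispersion."""
    pilot = sm.GLM(
        y, X, family=sm.families.Poisson(), var_weights=weights, offset=offset
    ).fit(maxiter=100)
    alpha = estimate_nb_dispersion(np.asarray(y, float), pilot.mu)
    fam = (
        sm.families.NegativeBinomial(alpha=alpha)
        if alpha > 0
        else sm.families.Poisson()
    )
    res = sm.GLM(y, X, family=fam, var_weights=weights, offset=offset).fit(maxiter=100)
    return res, alpha


def _ql_f_test(full, null, phi: float, q: int, df_resid: float):
    """Quasi-likelihood F-test on the deviance drop between nested fits.

    The denominator df is the residual df alone: crediting the shrinkage
    prior's df makes the far tail (where BH at 1% operates) anticonservative
    because the dispersion itself is estimated."""
    num = max(null.deviance - full.deviance, 0.0) / q
    F = num / max(phi, 1e-12)
    return float(sps.f.sf(F, q, df_resid))


def nb_abundance_test(
    table: pd.DataFrame,
    terms: str = "linear",
    fdr: float = 0.01,
    method: str = "qlf",
    prior_df: float = 10.0,
) -> pd.DataFrame:
    """Age-dependent cluster abundance test (NB GLM, log link).

    ``table`` is long-format with columns group, age (weeks), replicate,
    count, and optionally ``total`` (total cells captured per replicate,
    used as a prior weight on the likelihood).  For each group the model
    ``count ~ age`` (optionally + age^2) is fitted with a per-group
    method-of-moments dispersion.  The age terms are tested jointly with a
    quasi-likelihood F-test whose dispersion is shrunk toward the
    across-group mean (``method='qlf'``), or with a likelihood-ratio
    chi-square (``method='lrt'``, labelled in the output).  P-values are
    BH-adjusted across groups.
    """
    t = _check_table(table)
    has_total = "total" in t.columns
    q = 1 if terms == "linear" else 2
    fits = {}
    for g, sub in t.groupby("group"):
        if sub["count"].sum() == 0:
            warnings.warn(f"group {g!r} has all-zero counts; excluded")
            continue
        if sub["age"].nunique() < 3:
            raise ValueError(f"group {g!r}: need >= 3 distinct ages")
        y = sub["count"].to_numpy(dtype=float)
        X = _design(sub["age"].to_numpy(), terms)
        w = None
        if has_total:
            w = sub["total"].to_numpy(dtype=float)
            w = w / w.mean()
        try:
            # dispersion from the full model, shared by both fits so their
            # deviances are on the same scale
            full, alpha = _fit_nb_glm(y, X, weights=w)
            fam = full.family
            null = sm.GLM(y, X[:, :1], family=fam, var_weights=w).fit(maxiter=100)
        except Exception as err:  # non-convergence: Poisson fallback
            warnings.warn(f"group {g!r}: NB fit failed ({err}); Poisson fallback")
            full = sm.GLM(y, X, family=sm.families.Poisson(), var_weights=w).fit()
            null = sm.GLM(y, X[:, :1], family=sm.families.Poisson(), var_weights=w).fit()
            alpha = 0.0
        phi = full.pearson_chi2 / full.df_resid if full.df_resid > 0 else 1.0
        fits[g] = (full, null, alpha, phi)
    if not fits:
        raise ValueError("no testable groups")
    mean_phi = float(np.mean([v[3] for v in fits.values()]))
    rows = []
    for g, (full, null, alpha, phi) in fits.items():
        df_resid = full.df_resid
        if method == "qlf":
            w_shrunk = (df_resid * phi + prior_df * mean_phi) / (df_resid + prior_df)
            p = _ql_f_test(full, null, w_shrunk, q, df_resid)
        elif method == "lrt":
            lr = max(null.deviance - full.deviance, 0.0)
            p = float(sps.chi2.sf(lr, q))
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {
                "group": g,
                "coef_linear": full.params[1],
                "se_linear": full.bse[1],
                "coef_quadratic": full.params[2] if q == 2 else np.nan,
                "dispersion": alpha,
                "pvalue": p,
                "method": method,
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    out["fdr"] = adjust_pvalues(out["pvalue"].to_numpy(), "BH")
    out["significant"] = out["fdr"] <= fdr
    return out


def poisson_state_test(
    state_counts: pd.DataFrame, alpha: float = 0.01
) -> pd.DataFrame:
    """Poisson GLM of per-state replicate counts on age, Bonferroni at 0.01.

    ``state_counts`` is long-format with columns group (or state), age,
    replicate, count; all states in the frame form one lineage for the
    Bonferroni correction.
    """
    t = state_counts.rename(columns={"state": "group"})
    t = _check_table(t)
    rows = []
    for g, sub in t.groupby("group"):
        if sub["count"].sum() == 0:
            warnings.warn(f"state {g!r} has all-zero counts; excluded")
            continue
        y = sub["count"].to_numpy(dtype=float)
        X = _design(sub["age"].to_numpy(), "linear")
        res = sm.GLM(y, X, family=sm.families.Poisson()).fit(maxiter=100)
        rows.append(
            {
                "group": g,
                "coef_linear": res.params[1],
                "se_linear": res.bse[1],
                "pvalue": float(res.pvalues[1]),
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    out["p_adjusted"] = adjust_pvalues(out["pvalue"].to_numpy(), "bonferroni")
    out["significant"] = out["p_adjusted"] <= alpha
    return out


def offset_selection_test(
    wave_counts: pd.DataFrame, fdr: float = 0.01
) -> pd.DataFrame:
    """Parent-offset NB regression of selection-wave counts on age.

    ``wave_counts`` has columns group, age, replicate, count, parent; the
    log of the parent population enters as a model offset, so the tested
    coefficient is the age trend of the selected *fraction*.  Zero-parent
    rows are excluded with a warning.  BH-adjusted across groups.
    """
    t = _check_table(wave_counts, extra=["parent"])
    bad = t["parent"] <= 0
    if bad.any():
        warnings.warn(f"excluding {bad.sum()} rows with non-positive parent counts")
        t = t[~bad]
    rows = []
    for g, sub in t.groupby("group"):
        y = sub["count"].to_numpy(dtype=float)
        X = _design(sub["age"].to_numpy(), "linear")
        off = np.log(sub["parent"].to_numpy(dtype=float))
        res, alpha = _fit_nb_glm(y, X, offset=off)
        rows.append(
            {
                "group": g,
                "coef_linear": res.params[1],
                "se_linear": res.bse[1],
                "dispersion": alpha,
                "pvalue": float(res.pvalues[1]),
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    out["fdr"] = adjust_pvalues(out["pvalue"].to_numpy(), "BH")
    out["significant"] = out["fdr"] <= fdr
    return out


def age_expression_trend(
    log_expr,
    ages,
    size_factors,
    gene_names=None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene linear regression of expression on log2(age).

    ``log_expr`` is cells x genes log-normalised expression; the model per
    gene is ``expr ~ log2(age) + log(size_factor)`` (sequencing-depth
    adjustment).  Fitted for all genes at once by ordinary least squares;
    constant genes get slope 0 and p = 1.  BH-adjusted across genes.
    """
    Y = np.asarray(log_expr, dtype=float)
    ages = np.asarray(ages, dtype=float)
    sf = np.asarray(size_factors, dtype=float)
    if (ages <= 0).any():
        raise ValueError("ages must be positive")
    if (sf <= 0).any():
        raise ValueError("size factors must be positive")
    n, g = Y.shape
    X = np.column_stack([np.ones(n), np.log2(ages), np.log(sf)])
    p = X.shape[1]
    XtX_inv = np.linalg.pinv(X.T @ X)
    beta = XtX_inv @ X.T @ Y  # p x genes
    resid = Y - X @ beta
    dof = n - np.linalg.matrix_rank(X)
    s2 = (resid**2).sum(axis=0) / max(dof, 1)
    se = np.sqrt(np.clip(XtX_inv[1, 1] * s2, 0.0, None))
    slope = beta[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, slope / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * sps.t.sf(np.abs(tval), dof)
    constant = Y.std(axis=0) == 0
    slope = np.where(constant, 0.0, slope)
    pval = np.where(constant | (se == 0), 1.0, pval)
    idx = gene_names if gene_names is not None else pd.RangeIndex(g)
    out = pd.DataFrame(
        {"slope": slope, "se": se, "pvalue": pval}, index=idx
    )
    out["fdr"] = adjust_pvalues(out["pvalue"].to_numpy(), "BH")
    out["significant"] = out["fdr"] <= fdr
    return out
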