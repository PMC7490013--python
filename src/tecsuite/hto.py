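"""Hashtag-oligo (HTO) demultiplexing.

Assigns droplet barcodes to their sample of origin from an HTO x barcode
count matrix.  Per sample: counts are CPM-normalised across the expected
HTOs, barcodes are k-means partitioned with k = number of expected HTOs,
and for each HTO a background null is estimated after excluding (a) the
k-means partition with the highest mean CPM for that HTO and (b) the top
0.5% of barcodes by raw count.  A negative binomial is fitted to the
remaining raw counts and its 99th quantile becomes the assignment threshold
q; every barcode with raw count >= q is assigned the HTO.  Barcodes
assigned exactly one HTO are Singlets, more than one Multiplets, and none
Dropouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from sklearn.utils.validation import check_is_fitted

__all__ = ["fit_background_threshold", "HtoDemultiplexer", "HtoAssignment", "demux"]


def fit_background_threshold(
    counts_for_hto: np.ndarray,
    excluded_idx: np.ndarray | None = None,
    quantile: float = 0.99,
) -> tuple[int, dict]:
    """Background negative-binomial threshold for one HTO.

    Fits a method-of-moments NB (variance = mu + mu^2/size) to the counts
    that remain after exclusion and returns the smallest integer q with
    CDF >= ``quantile``, plus the fitted parameters.  Degenerate cases fall
    back as flagged in the returned params: constant counts give q equal to
    that constant; variance <= mean gives a Poisson quantile.
    """
    counts = np.asarray(counts_for_hto, dtype=float)
    if excluded_idx is not None:
        mask = np.ones(counts.shape[0], dtype=bool)
        mask[np.asarray(excluded_idx)] = False
        counts = counts[mask]
    if counts.size < 20:
        raise ValueError(f"need >= 20 background barcodes, got {counts.size}")
    if quantile <= 0:
        return 0, {"distribution": "none", "mean": float(counts.mean())}
    mean = counts.mean()
    var = counts.var(ddof=1)
    if var == 0:
        return int(counts[0]), {"distribution": "degenerate", "mean": float(mean)}
    if var <= mean:
        q = int(stats.poisson.ppf(quantile, mean))
        return q, {"distribution": "poisson", "mean": float(mean)}
    size_mom = mean**2 / (var - mean)
    size, mu = _nb_mle(counts, size_mom, mean)
    q = int(stats.nbinom.ppf(quantile, size, size / (size + mu)))
    return q, {
        "distribution": "nbinom",
        "mean": float(mu),
        "size": float(size),
        "size_mom": float(size_mom),
    }


def _nb_mle(x: np.ndarray, size0: float, mu0: float) -> tuple[float, float]:
    """Maximum-likelihood NB parameters, initialised from the moment
    estimates.  The likelihood fit is markedly less sensitive than the
    moment estimator to the handful of signal-level counts that survive the
    exclusion steps, which would otherwise inflate the threshold."""
    from scipy.optimize import minimize

    def nll(p):
        s, m = np.exp(p)
        return -stats.nbinom.logpmf(x, s, s / (s + m)).sum()

    res = minimize(nll, np.log([max(size0, 1e-3), max(mu0, 1e-3)]),
                   method="Nelder-Mead")
    if not np.isfinite(res.fun):
        return size0, mu0
    s, m = np.exp(res.x)
    return float(s), float(m)


@dataclass
class HtoAssignment:
    """Per-barcode demultiplexing calls and the per-HTO thresholds."""

    table: pd.DataFrame  # index barcode; columns: call, assigned_htos, n_assigned
    thresholds: pd.Series  # per-HTO q
    background: dict = field(default_factory=dict)  # per-HTO NB params

    @property
    def calls(self) -> pd.Series:
        return self.table["call"]


class HtoDemultiplexer(BaseEstimator):
    """Threshold-based HTO demultiplexer (see module docstring).

    Parameters
    ----------
    quantile : float, default 0.99
        Background NB quantile defining the assignment threshold q.
    top_trim : float, default 0.005
        Fraction of highest-count barcodes excluded per HTO before the
        background fit.
    n_init, random_state : k-means initialisation controls (k-means runs on
        CPM, not log-CPM).

    Attributes
    ----------
    thresholds_ : pandas.Series of per-HTO q
    background_ : dict of per-HTO fitted background parameters
    """

    def __init__(self, quantile: float = 0.99, top_trim: float = 0.005,
                 n_init: int = 10, random_state: int = 0):
        self.quantile = quantile
        self.top_trim = top_trim
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, counts: pd.DataFrame, y=None):
        """Estimate per-HTO thresholds from an HTO x barcode count frame."""
        counts = self._check(counts)
        n_htos, n_bc = counts.shape
        raw = counts.to_numpy(dtype=float)
        totals = raw.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cpm = np.where(totals > 0, raw / np.maximum(totals, 1) * 1e6, 0.0)
        km = KMeans(
            n_clusters=n_htos, n_init=self.n_init, random_state=self.random_state
        ).fit(cpm.T)
        parts = km.labels_
        thresholds, background = {}, {}
        n_trim = int(np.ceil(self.top_trim * n_bc))
        for h, name in enumerate(counts.index):
            part_means = [cpm[h, parts == c].mean() if (parts == c).any() else -np.inf
                          for c in range(n_htos)]
            signal_part = int(np.argmax(part_means))
            excluded = set(np.where(parts == signal_part)[0])
            top = np.argsort(raw[h])[::-1][:n_trim]
            excluded.update(top.tolist())
            q, params = fit_background_threshold(
                raw[h], np.fromiter(excluded, dtype=int), self.quantile
            )
            if params["distribution"] == "poisson":
                warnings.warn(f"{name}: background variance <= mean; Poisson fallback")
            thresholds[name] = q
            background[name] = params
        self.thresholds_ = pd.Series(thresholds, name="q")
        self.background_ = background
        return self

    def predict(self, counts: pd.DataFrame) -> HtoAssignment:
        """Call Singlet/Multiplet/Dropout per barcode against the fitted q."""
        check_is_fitted(self, "thresholds_")
        counts = self._check(counts)
        q = self.thresholds_.reindex(counts.index)
        if q.isna().any():
            raise ValueError("counts contain HTOs unseen during fit")
        assigned = counts.ge(q, axis=0)
        n_assigned = assigned.sum(axis=0)
        call = pd.Series(
            np.select([n_assigned == 1, n_assigned > 1], ["Singlet", "Multiplet"], "Dropout"),
            index=counts.columns,
        )
        names = [
            "+".join(counts.index[assigned[bc].to_numpy()]) for bc in counts.columns
        ]
        table = pd.DataFrame(
            {"call": call, "assigned_htos": names, "n_assigned": n_assigned}
        )
        return HtoAssignment(table=table, thresholds=self.thresholds_, background=self.background_)

    def fit_predict(self, counts: pd.DataFrame) -> HtoAssignment:
        return self.fit(counts).predict(counts)

    @staticmethod
    def _check(counts: pd.DataFrame) -> pd.DataFrame:
        if not isinstance(counts, pd.DataFrame):
            raise TypeError("counts must be an HTO x barcode DataFrame")
        if counts.shape[0] < 2:
            raise ValueError("need >= 2 HTOs")
        if counts.shape[1] < 10 * counts.shape[0]:
            raise ValueError("need >= 10 barcodes per HTO")
        if counts.columns.duplicated().any():
            raise ValueError("barcodes must be unique")
        if (counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        return counts


def demux(
    counts: pd.DataFrame, quantile: float = 0.99, top_trim: float = 0.005,
    random_state: int = 0,
) -> HtoAssignment:
    """One-shot demultiplexing of an HTO x barcode count matrix."""
    return HtoDemultiplexer(
        quantile=quantile, top_trim=top_trim, random_state=random_state
    ).fit_predict(counts)
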