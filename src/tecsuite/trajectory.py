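"""Diffusion maps, diffusion pseudotime, density and meta-stable states.

A diffusion map embeds cells by the leading eigenvectors of a random-walk
transition operator built on a kNN graph (k = 21 and 20 principal
components by default).  Diffusion pseudotime (DPT) measures diffusion
distance from a root cell, taken as the cell at the lowest position on the
first diffusion component (the apex of bifurcating lineages) unless
supplied.  Cells accumulate in meta-stable states along a differentiation
trajectory — regions of high density whose occupancy is inversely related
to differentiation rate — which are identified by fitting a 1-D Gaussian
mixture to DPT and labelling states by ascending mean.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "DiffusionPseudotime",
    "diffusion_pseudotime",
    "dpt_density",
    "PseudotimeStates",
    "assign_states",
    "state_counts",
]


class DiffusionPseudotime(BaseEstimator):
    """Diffusion map + diffusion pseudotime from a DC1-apex root.

    Parameters
    ----------
    k : int, default 21
        Neighbourhood size of the kNN graph.
    n_pcs : int or None, default 20
        Principal components computed before the kNN graph (skipped when the
        input has fewer features).
    n_dcs : int, default 10
        Number of diffusion components retained.
    root : int or None
        Index of the root cell; when None the cell with the lowest DC1 is
        used.

    Attributes
    ----------
    dcs_ : (n_cells, n_dcs) diffusion components (DC1 is column 0)
    dpt_ : (n_cells,) pseudotime distance from the root (root has 0)
    root_ : int
    """

    def __init__(self, k: int = 21, n_pcs: int | None = 20, n_dcs: int = 10,
                 root: int | None = None, random_state: int = 0):
        self.k = k
        self.n_pcs = n_pcs
        self.n_dcs = n_dcs
        self.root = root
        self.random_state = random_state

    def fit(self, X, y=None):
        import scanpy as sc

        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n < self.k + 1:
            raise ValueError(f"need at least k+1={self.k + 1} cells, got {n}")
        adata = AnnData(X=X)
        use_pca = self.n_pcs is not None and self.n_pcs < min(X.shape)
        if use_pca:
            sc.pp.pca(adata, n_comps=self.n_pcs, svd_solver="arpack",
                      random_state=self.random_state)
            rep = "X_pca"
        else:
            rep = "X"
        sc.pp.neighbors(adata, n_neighbors=self.k, use_rep=rep,
                        random_state=self.random_state)
        conn = adata.obsp["connectivities"]
        n_comp, comp_labels = connected_components(conn, directed=False)
        if n_comp > 1:
            sizes = np.bincount(comp_labels)
            raise ValueError(
                f"kNN graph is disconnected into {n_comp} components "
                f"(sizes {sizes.tolist()}); increase k or split the data"
            )
        n_dcs = min(self.n_dcs, n - 2)
        sc.tl.diffmap(adata, n_comps=n_dcs + 1)
        dcs = adata.obsm["X_diffmap"][:, 1:]  # drop the trivial steady-state component
        root = int(np.argmin(dcs[:, 0])) if self.root is None else int(self.root)
        adata.uns["iroot"] = root
        sc.tl.dpt(adata, n_dcs=n_dcs + 1)
        self.dcs_ = dcs
        self.dpt_ = adata.obs["dpt_pseudotime"].to_numpy()
        self.root_ = root
        return self

    def fit_transform(self, X, y=None):
        """Fit and return the diffusion components."""
        return self.fit(X).dcs_


def diffusion_pseudotime(X, k: int = 21, n_pcs: int | None = 20,
                         root: int | None = None) -> pd.DataFrame:
    """Convenience wrapper: per-cell diffusion components and DPT."""
    est = DiffusionPseudotime(k=k, n_pcs=n_pcs, root=root).fit(X)
    out = pd.DataFrame(
        est.dcs_, columns=[f"DC{i + 1}" for i in range(est.dcs_.shape[1])]
    )
    out["dpt"] = est.dpt_
    out.attrs["root"] = est.root_
    return out


def dpt_density(
    dpt_values,
    points_fraction: float = 0.01,
    bw_method: str | float = "silverman",
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of cell density along pseudotime.

    Evaluated at ceil(points_fraction * n) points spanning the DPT range
    (bandwidth by Silverman's rule unless overridden).  Returns
    ``(grid, density)``.
    """
    from scipy.stats import gaussian_kde

    x = np.asarray(dpt_values, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 cells for a density estimate")
    if np.ptp(x) == 0:
        raise ValueError("constant pseudotime: density is degenerate")
    n_points = int(np.ceil(points_fraction * x.size))
    grid = np.linspace(x.min(), x.max(), n_points)
    kde = gaussian_kde(x, bw_method=bw_method)
    return grid, kde(grid)


class PseudotimeStates(BaseEstimator):
    """1-D Gaussian mixture over DPT defining meta-stable states.

    Fitted by EM with ``n_init`` restarts; states are relabelled by
    ascending mean pseudotime (state 1 is the least differentiated).

    Attributes
    ----------
    means_, sds_, weights_ : per-state parameters in state order
    labels_ : per-cell state in {1..K} from the fitting call
    """

    def __init__(self, n_components: int = 3, seed: int = 0, n_init: int = 10,
                 tol: float = 1e-6, max_iter: int = 500):
        self.n_components = n_components
        self.seed = seed
        self.n_init = n_init
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, dpt_values, y=None):
        x = np.asarray(dpt_values, dtype=float).reshape(-1, 1)
        if x.shape[0] < 10 * self.n_components:
            raise ValueError(
                f"need >= {10 * self.n_components} cells for {self.n_components} components"
            )
        if np.ptp(x) == 0:
            raise ValueError("constant pseudotime: mixture is degenerate")
        gmm = GaussianMixture(
            n_components=self.n_components,
            covariance_type="full",
            n_init=self.n_init,
            tol=self.tol,
            max_iter=self.max_iter,
            random_state=self.seed,
        ).fit(x)
        if not gmm.converged_:
            raise RuntimeError(
                f"EM did not converge in {self.max_iter} iterations "
                f"(lower_bound={gmm.lower_bound_:.4g})"
            )
        order = np.argsort(gmm.means_.ravel())
        self._gmm = gmm
        self._order = order
        self.means_ = gmm.means_.ravel()[order]
        self.sds_ = np.sqrt(gmm.covariances_.ravel()[order])
        self.weights_ = gmm.weights_[order]
        self.labels_ = self.predict(x.ravel())
        return self

    def predict(self, dpt_values) -> np.ndarray:
        check_is_fitted(self, "means_")
        x = np.asarray(dpt_values, dtype=float).reshape(-1, 1)
        raw = self._gmm.predict(x)
        relabel = np.empty_like(self._order)
        relabel[self._order] = np.arange(self.n_components)
        return relabel[raw] + 1  # states are 1-based


def assign_states(dpt_values, n_components: int = 3, seed: int = 0) -> pd.DataFrame:
    """Fit meta-stable states; returns a per-cell frame plus state params.

    The frame has columns ``dpt`` and ``state``; per-state mean/sd/weight
    are stored in ``.attrs['states']``.
    """
    est = PseudotimeStates(n_components=n_components, seed=seed).fit(dpt_values)
    out = pd.DataFrame({"dpt": np.asarray(dpt_values, dtype=float), "state": est.labels_})
    out.attrs["states"] = pd.DataFrame(
        {"mean": est.means_, "sd": est.sds_, "weight": est.weights_},
        index=pd.RangeIndex(1, n_components + 1, name="state"),
    )
    return out


def state_counts(states: np.ndarray, obs: pd.DataFrame) -> pd.DataFrame:
    """Cells per (state, age, replicate), for abundance testing."""
    df = obs[["age", "replicate"]].copy()
    df["state"] = np.asarray(states)
    out = (
        df.groupby(["state", "age", "replicate"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
    )
    return out
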