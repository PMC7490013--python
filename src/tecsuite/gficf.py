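"""GF-ICF transform, SNN/Walktrap clustering, consensus robustness and kNN
label transfer.

The gene frequency - inverse cell frequency (GF-ICF) transform is the
TF-IDF analogue for expression matrices: the gene-frequency term is
log2(C + pseudocount) of the normalised counts C, and each gene is scaled
by its inverse cell frequency ICF_x = log10(N / (1 + E_x)), where N is the
number of cells and E_x the number of cells expressing gene x.  The
transform up-weights rarely expressed genes (e.g. promiscuously expressed
tissue antigens) and down-weights ubiquitous ones.  Clustering builds a
shared-nearest-neighbour graph (Jaccard edge weights over kNN sets) and
cuts the Walktrap community dendrogram at maximum modularity.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClassifierMixin, ClusterMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "GfIcfTransformer",
    "SnnWalktrap",
    "snn_graph",
    "consensus_robustness",
    "KnnLabelTransfer",
    "transfer_labels",
]


class GfIcfTransformer(TransformerMixin, BaseEstimator):
    """Gene frequency x inverse cell frequency transform.

    Parameters
    ----------
    pseudocount : float, default 1.0
        Added inside the log2 gene-frequency term so zeros map to zero.

    Attributes
    ----------
    icf_ : ndarray of shape (n_genes,)
        log10(N / (1 + E_x)) per gene, learned on the fitted matrix.  Genes
        expressed in every cell get a small negative ICF, which is retained
        rather than clipped.
    n_cells_ : int
    """

    def __init__(self, pseudocount: float = 1.0):
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        X = self._validate(X)
        n = X.shape[0]
        if n < 2:
            raise ValueError("GF-ICF requires at least 2 cells")
        if sp.issparse(X):
            e_x = X.getnnz(axis=0).astype(float)
        else:
            e_x = (X > 0).sum(axis=0).astype(float)
        self.n_cells_ = n
        self.icf_ = np.log10(n / (1.0 + e_x))
        return self

    def transform(self, X):
        check_is_fitted(self, "icf_")
        X = self._validate(X)
        if sp.issparse(X):
            X = np.asarray(X.todense())
        gf = np.log2(np.asarray(X, dtype=float) + self.pseudocount)
        return gf * self.icf_

    @staticmethod
    def _validate(X):
        if sp.issparse(X):
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D cells x genes matrix")
        if not np.isfinite(X).all():
            raise ValueError("matrix contains non-finite entries")
        return X


def snn_graph(X, k: int = 10, include_self: bool = True):
    """Shared-nearest-neighbour graph with Jaccard edge weights.

    Nodes are cells; an edge joins i and j when either lists the other among
    its k nearest (Euclidean) neighbours, weighted by the Jaccard overlap of
    the two neighbour sets; zero-weight edges are dropped.  Returns a
    symmetric sparse matrix of weights in (0, 1].
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells ({n})")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    idx = nn.kneighbors(return_distance=False)  # excludes self
    sets = np.hstack([np.arange(n)[:, None], idx[:, :k]]) if include_self else idx[:, :k]
    m = sets.shape[1]
    rows = np.repeat(np.arange(n), m)
    A = sp.csr_matrix((np.ones(n * m), (rows, sets.ravel())), shape=(n, n))
    inter = (A @ A.T).tocoo()
    union = 2 * m - inter.data
    jac = inter.data / union
    W = sp.coo_matrix((jac, (inter.row, inter.col)), shape=(n, n)).tocsr()
    # keep only pairs adjacent in the kNN union graph
    mask = ((A + A.T) > 0).astype(float)
    W = W.multiply(mask).tocsr()
    W.setdiag(0)
    W.eliminate_zeros()
    return W


def _walktrap(W: sp.csr_matrix, steps: int = 4) -> np.ndarray:
    import igraph as ig

    coo = sp.triu(W, k=1).tocoo()
    g = ig.Graph(
        n=W.shape[0],
        edges=list(zip(coo.row.tolist(), coo.col.tolist())),
        edge_attrs={"weight": coo.data.tolist()},
    )
    dendro = g.community_walktrap(weights="weight", steps=steps)
    clustering = dendro.as_clustering()  # cut at maximum modularity
    return np.asarray(clustering.membership)


class SnnWalktrap(ClusterMixin, BaseEstimator):
    """SNN-graph Walktrap community detection.

    Optionally reduces to ``n_pcs`` principal components first (droplet-style
    clustering uses 20 PCs, k = 31; plate-style GF-ICF clustering uses the
    transformed matrix directly with k = 10).

    Attributes
    ----------
    labels_ : ndarray of cluster labels per cell
    graph_ : scipy.sparse matrix, the weighted SNN graph
    """

    def __init__(self, k: int = 10, n_pcs: int | None = None, walktrap_steps: int = 4,
                 random_state: int = 0):
        self.k = k
        self.n_pcs = n_pcs
        self.walktrap_steps = walktrap_steps
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if self.n_pcs is not None and self.n_pcs < min(X.shape):
            X = PCA(
                n_components=self.n_pcs, svd_solver="full", random_state=self.random_state
            ).fit_transform(X)
        self.graph_ = snn_graph(X, k=self.k)
        self.labels_ = _walktrap(self.graph_, steps=self.walktrap_steps)
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def consensus_robustness(
    X,
    parameter_grid: list[dict],
    reference_labels=None,
) -> tuple[np.ndarray, float]:
    """Co-clustering consensus across a grid of clustering parameterisations.

    Each grid entry is a dict with optional keys ``use_gficf`` (bool),
    ``k``, ``n_pcs``, ``pseudocount``.  Returns the cell x cell consensus
    matrix (fraction of parameterisations in which two cells co-cluster; a
    symmetric matrix with unit diagonal) and the mean within-cluster
    consensus relative to ``reference_labels`` (default: the partition from
    the first grid entry).
    """
    if len(parameter_grid) < 2:
        raise ValueError("consensus requires at least 2 parameterisations")
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    consensus = np.zeros((n, n))
    partitions = []
    for params in parameter_grid:
        mat = X
        if params.get("use_gficf", False):
            mat = GfIcfTransformer(
                pseudocount=params.get("pseudocount", 1.0)
            ).fit_transform(X)
        labels = SnnWalktrap(
            k=params.get("k", 10), n_pcs=params.get("n_pcs")
        ).fit_predict(mat)
        partitions.append(labels)
        consensus += labels[:, None] == labels[None, :]
    consensus /= len(parameter_grid)
    ref = np.asarray(reference_labels) if reference_labels is not None else partitions[0]
    within = []
    for c in np.unique(ref):
        m = ref == c
        if m.sum() < 2:
            continue
        block = consensus[np.ix_(m, m)]
        iu = np.triu_indices(m.sum(), k=1)
        within.append(block[iu].mean())
    score = float(np.mean(within)) if within else float("nan")
    return consensus, score


def _cosine_rows(X: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(X, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    return X / norms


class KnnLabelTransfer(ClassifierMixin, BaseEstimator):
    """k-nearest-neighbour label transfer between datasets.

    Both reference and query are per-cell cosine-normalised; an optional
    batch ``corrector`` callable ``(reference, query) -> (reference, query)``
    is applied afterwards (identity by default; mean-centering per batch is
    a shipped alternative, full mutual-nearest-neighbour correction can be
    injected).  Each query cell receives the majority label among its k
    nearest reference cells, ties broken by smallest mean distance.
    """

    def __init__(self, k: int = 5, corrector=None):
        self.k = k
        self.corrector = corrector

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of reference cells")
        self.X_ = _cosine_rows(X)
        self.y_ = y
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        check_is_fitted(self, "X_")
        Q = _cosine_rows(np.asarray(X, dtype=float))
        R = self.X_
        if self.corrector is not None:
            R, Q = self.corrector(R, Q)
        k = min(self.k, R.shape[0])
        nn = NearestNeighbors(n_neighbors=k).fit(R)
        dist, idx = nn.kneighbors(Q)
        out = []
        for d_row, i_row in zip(dist, idx):
            labels = self.y_[i_row]
            values, counts = np.unique(labels, return_counts=True)
            best = values[counts == counts.max()]
            if len(best) == 1:
                out.append(best[0])
            else:  # tie: smallest mean distance to the tied label's neighbours
                means = [d_row[labels == v].mean() for v in best]
                out.append(best[int(np.argmin(means))])
        return np.asarray(out)


def mean_center_corrector(reference: np.ndarray, query: np.ndarray):
    """Per-batch mean-centering batch corrector."""
    return reference - reference.mean(axis=0), query - query.mean(axis=0)


def transfer_labels(
    reference: pd.DataFrame,
    reference_labels,
    query: pd.DataFrame,
    k: int = 5,
    corrector=None,
) -> pd.Series:
    """Label transfer between gene-named frames (cells x genes).

    Takes the gene intersection of the two frames before fitting.
    """
    shared = reference.columns.intersection(query.columns)
    if len(shared) == 0:
        raise ValueError("reference and query share no genes")
    clf = KnnLabelTransfer(k=k, corrector=corrector)
    clf.fit(reference[shared].to_numpy(), reference_labels)
    return pd.Series(clf.predict(query[shared].to_numpy()), index=query.index)
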