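"""Synthetic input generators for every pipeline stage.

Each generator emulates the statistical structure a downstream stage
assumes — a two-cassette beta germline locus, count matrices with discrete
subtype structure and age-varying composition, hashtag-oligo mixtures with
known singlet/doublet/empty labels, tissue expression panels with genes of
known specificity, and 1-D latent trajectories sampled from Gaussian
mixtures whose weights shift with age.  Ground-truth labels are returned
alongside, never inside, the objects the pipeline stages consume.

All generators are deterministic for a fixed spec seed (one
``numpy.random.default_rng`` stream per generator call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .tcr import GermlineLocus, Segment

__all__ = [
    "LocusSpec",
    "ScCountSpec",
    "HtoMixSpec",
    "TissuePanelSpec",
    "TrajectorySpec",
    "gen_germline_locus",
    "gen_sc_counts",
    "gen_hto_counts",
    "gen_tissue_panel",
    "gen_trajectory",
]

_BASES = np.array(list("ACGT"))


class SpecificationError(ValueError):
    """A generator spec violates its invariants."""


# ---------------------------------------------------------------------------
# germline locus
# ---------------------------------------------------------------------------


@dataclass
class LocusSpec:
    """Parametric emulation of a two-cassette TCR germline locus.

    Segments are random sequences over {A,C,G,T} with configurable base
    composition.  Spurious ATG triplets are scrubbed from V segments and a
    single ATG is planted at ``atg_offset`` in a configurable fraction of V
    segments, which makes per-attempt productivity steerable: productivity
    then requires the planted frame to reach the final base (probability
    ~1/3 over junction-insertion lengths) without hitting a stop codon.
    Short segments and a T-poor composition keep that probability
    appreciable, as in a real locus whose segments are ORF-biased.
    """

    n_v_alpha: int = 20
    n_j_alpha: int = 10
    n_c_alpha: int = 1
    n_v_beta: int = 15
    n_d_beta: int = 2
    n_j_beta_per_cassette: int = 6
    n_c_beta_per_cassette: int = 1
    v_len_range: tuple[int, int] = (36, 48)
    d_len_range: tuple[int, int] = (10, 14)
    j_len_range: tuple[int, int] = (15, 21)
    c_len_range: tuple[int, int] = (21, 30)
    base_probs: tuple[float, float, float, float] = (0.30, 0.25, 0.30, 0.15)  # A,C,G,T
    atg_fraction: float = 1.0
    atg_offset: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_d_beta < 1:
            raise SpecificationError("beta chain requires at least one D segment")
        if self.n_j_beta_per_cassette < 1 or self.n_c_beta_per_cassette < 1:
            raise SpecificationError("both beta J/C cassettes must be non-empty")
        if not np.isclose(sum(self.base_probs), 1.0):
            raise SpecificationError("base_probs must sum to 1")
        if not 0.0 <= self.atg_fraction <= 1.0:
            raise SpecificationError("atg_fraction must lie in [0, 1]")


def _scrub_atg(seq: np.ndarray) -> None:
    """Remove every ATG triplet in-place (replace the G with C)."""
    s = "".join(seq)
    i = s.find("ATG")
    while i != -1:
        seq[i + 2] = "C"
        s = "".join(seq)
        i = s.find("ATG", i + 1)


def _random_segment(rng, length: int, probs, *, scrub: bool, plant_atg: bool, offset: int) -> str:
    seq = rng.choice(_BASES, size=length, p=list(probs))
    if scrub:
        _scrub_atg(seq)
    if plant_atg:
        if offset + 3 > length:
            raise SpecificationError("atg_offset does not fit in the V segment")
        seq[offset : offset + 3] = list("ATG")
    return "".join(seq)


def gen_germline_locus(spec: LocusSpec) -> GermlineLocus:
    """Generate a synthetic germline locus.

    Alpha segments carry no cassette; beta J and C segments are partitioned
    into cassettes 1 and 2.  Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    segments: list[Segment] = []

    def lengths(rng, rng_range, n):
        lo, hi = rng_range
        return rng.integers(lo, hi + 1, size=n)

    def add(names_prefix, chain, segtype, cassette, n, len_range, is_v=False):
        for i, L in enumerate(lengths(rng, len_range, n), start=1):
            plant = is_v and (rng.random() < spec.atg_fraction)
            seq = _random_segment(
                rng, int(L), spec.base_probs,
                scrub=is_v, plant_atg=plant, offset=spec.atg_offset,
            )
            segments.append(
                Segment(f"{names_prefix}{i}", chain, segtype, cassette, seq)
            )

    add("TRAV", "alpha", "V", None, spec.n_v_alpha, spec.v_len_range, is_v=True)
    add("TRAJ", "alpha", "J", None, spec.n_j_alpha, spec.j_len_range)
    add("TRAC", "alpha", "C", None, spec.n_c_alpha, spec.c_len_range)
    add("TRBV", "beta", "V", None, spec.n_v_beta, spec.v_len_range, is_v=True)
    add("TRBD", "beta", "D", None, spec.n_d_beta, spec.d_len_range)
    for cas in (1, 2):
        add(f"TRBJ{cas}-", "beta", "J", cas, spec.n_j_beta_per_cassette, spec.j_len_range)
        add(f"TRBC{cas}-", "beta", "C", cas, spec.n_c_beta_per_cassette, spec.c_len_range)
    return GermlineLocus(segments)


# ---------------------------------------------------------------------------
# single-cell counts
# ---------------------------------------------------------------------------


@dataclass
class ScCountSpec:
    """Gene-by-cell counts with discrete subtype structure, age-varying
    composition and a TRA-expressing subtype.

    Defaults emulate a small multi-age sort: five ages, two replicate mice
    per age, five subtypes whose proportions shift with age, a block of
    tissue-restricted-antigen genes expressed only in one (mTEC-like)
    subtype, and modest dropout.
    """

    n_genes: int = 2000
    ages: tuple[int, ...] = (1, 4, 16, 32, 52)
    n_replicates: int = 2
    n_cells_per_sample: int = 50
    n_clusters: int = 5
    markers_per_cluster: int = 50
    marker_fold: float = 8.0
    cluster_proportions: Mapping[int, Sequence[float]] | None = None  # age -> props
    tra_tissues: int = 6
    tra_genes_per_tissue: int = 8
    tra_cluster: int = 0  # cluster index expressing the TRA block
    tra_mean: float = 2.0
    cell_depth: float = 3000.0
    depth_sd: float = 0.2  # lognormal sd of per-cell depth factor
    dropout: float = 0.1
    ercc_fraction: float = 0.02
    mito_fraction: float = 0.02
    seed: int = 0

    def proportions(self, age: int) -> np.ndarray:
        if self.cluster_proportions is not None:
            p = np.asarray(self.cluster_proportions[age], dtype=float)
        else:
            p = np.full(self.n_clusters, 1.0 / self.n_clusters)
        if not np.isclose(p.sum(), 1.0):
            raise SpecificationError(f"cluster proportions for age {age} must sum to 1")
        return p

    def validate(self) -> None:
        if self.n_cells_per_sample < 1:
            raise SpecificationError("need at least one cell per (age, replicate)")
        if not 0.0 <= self.dropout <= 1.0:
            raise SpecificationError("dropout must lie in [0, 1]")
        for age in self.ages:
            self.proportions(age)


def gen_sc_counts(spec: ScCountSpec) -> tuple[AnnData, dict]:
    """Generate a count matrix plus separated ground truth.

    Returns ``(adata, truth)`` where ``adata`` (cells x genes) carries only
    what a pipeline would see — integer counts, per-cell age/replicate, and
    per-gene ERCC/mitochondrial flags — and ``truth`` holds the generating
    cluster label per cell and the TRA tissue per planted gene.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_genes = spec.n_genes
    n_ercc = int(round(spec.ercc_fraction * n_genes))
    n_mito = int(round(spec.mito_fraction * n_genes))
    n_tra = spec.tra_tissues * spec.tra_genes_per_tissue
    n_body = n_genes - n_ercc - n_mito
    if n_body < spec.n_clusters * spec.markers_per_cluster + n_tra:
        raise SpecificationError("n_genes too small for the requested marker/TRA blocks")

    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    # baseline relative expression, normalised to the nominal cell depth
    profiles = np.tile(base, (spec.n_clusters, 1))
    marker_truth = {}
    g = 0
    for c in range(spec.n_clusters):
        idx = np.arange(g, g + spec.markers_per_cluster)
        profiles[c, idx] *= spec.marker_fold
        marker_truth[c] = idx
        g += spec.markers_per_cluster
    tra_tissue = np.full(n_genes, "", dtype=object)
    for t in range(spec.tra_tissues):
        idx = np.arange(g, g + spec.tra_genes_per_tissue)
        profiles[:, idx] = 0.0
        profiles[spec.tra_cluster, idx] = spec.tra_mean
        tra_tissue[idx] = f"tissue_{t + 1}"
        g += spec.tra_genes_per_tissue
    ercc_idx = np.arange(n_genes - n_ercc - n_mito, n_genes - n_mito)
    mito_idx = np.arange(n_genes - n_mito, n_genes)
    profiles[:, ercc_idx] = base[ercc_idx]  # spike-ins: identical in every cell
    profiles /= profiles.sum(axis=1, keepdims=True)
    profiles *= spec.cell_depth

    cells, metas, labels = [], [], []
    for age in spec.ages:
        props = spec.proportions(age)
        for rep in range(1, spec.n_replicates + 1):
            k = rng.multinomial(spec.n_cells_per_sample, props)
            for cluster, n_c in enumerate(k):
                for _ in range(n_c):
                    depth = rng.lognormal(0.0, spec.depth_sd)
                    lam = profiles[cluster] * depth
                    counts = rng.poisson(lam)
                    if spec.dropout > 0:
                        counts = counts * (rng.random(n_genes) >= spec.dropout)
                    cells.append(counts)
                    metas.append((age, rep))
                    labels.append(cluster)

    X = sp.csr_matrix(np.vstack(cells).astype(np.int64))
    if X.nnz == 0:
        warnings.warn("generated matrix is all zero (degenerate; dropout too high?)")
    obs = pd.DataFrame(metas, columns=["age", "replicate"])
    obs.index = [f"cell_{i}" for i in range(len(obs))]
    obs["age"] = obs["age"].astype(int)
    var = pd.DataFrame(index=[f"gene_{i}" for i in range(n_genes)])
    var["is_ercc"] = False
    var["is_mito"] = False
    var.iloc[ercc_idx, var.columns.get_loc("is_ercc")] = True
    var.iloc[mito_idx, var.columns.get_loc("is_mito")] = True
    adata = AnnData(X=X, obs=obs, var=var)
    truth = {
        "cluster": np.asarray(labels),
        "tra_tissue": pd.Series(tra_tissue, index=var.index),
        "marker_genes": {c: var.index[idx].to_numpy() for c, idx in marker_truth.items()},
    }
    return adata, truth


# ---------------------------------------------------------------------------
# hashtag-oligo mixtures
# ---------------------------------------------------------------------------


@dataclass
class HtoMixSpec:
    """Hashtag count mixtures with known singlet/doublet/empty labels."""

    n_htos: int = 6
    n_singlets_per_hto: int = 300
    n_doublets: int = 200
    n_empty: int = 0
    signal_mean: float = 500.0
    signal_size: float = 10.0  # NB size (inverse dispersion)
    background_mean: float = 5.0
    background_size: float = 10.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_htos < 1:
            raise SpecificationError("need at least one HTO")
        for v in (self.signal_mean, self.background_mean):
            if v <= 0:
                raise SpecificationError("NB means must be > 0")
        for v in (self.signal_size, self.background_size):
            if v <= 0:
                raise SpecificationError("NB dispersions (sizes) must be > 0")


def _nb(rng, mean: float, size: float, n: int) -> np.ndarray:
    p = size / (size + mean)
    return rng.negative_binomial(size, p, size=n)


def gen_hto_counts(spec: HtoMixSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate an HTO x barcode count matrix and its true labels.

    Singlets get signal-level counts on one HTO and background on the rest;
    doublets get signal on two distinct HTOs; empty barcodes background
    everywhere.  Returns ``(counts, truth)`` with truth columns ``label``
    (Singlet/Multiplet/Dropout) and ``htos`` (true source HTOs, '+'-joined).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    hto_names = [f"HTO{i + 1}" for i in range(spec.n_htos)]
    n_bc = spec.n_htos * spec.n_singlets_per_hto + spec.n_doublets + spec.n_empty
    counts = np.vstack(
        [_nb(rng, spec.background_mean, spec.background_size, n_bc) for _ in hto_names]
    )
    labels, sources = [], []
    col = 0
    for h in range(spec.n_htos):
        for _ in range(spec.n_singlets_per_hto):
            counts[h, col] = _nb(rng, spec.signal_mean, spec.signal_size, 1)[0]
            labels.append("Singlet")
            sources.append(hto_names[h])
            col += 1
    for _ in range(spec.n_doublets):
        if spec.n_htos < 2:
            raise SpecificationError("doublets require >= 2 HTOs")
        a, b = rng.choice(spec.n_htos, size=2, replace=False)
        counts[a, col] = _nb(rng, spec.signal_mean, spec.signal_size, 1)[0]
        counts[b, col] = _nb(rng, spec.signal_mean, spec.signal_size, 1)[0]
        labels.append("Multiplet")
        sources.append(f"{hto_names[a]}+{hto_names[b]}")
        col += 1
    for _ in range(spec.n_empty):
        labels.append("Dropout")
        sources.append("")
        col += 1
    barcodes = [f"BC{i + 1}" for i in range(n_bc)]
    counts_df = pd.DataFrame(counts, index=hto_names, columns=barcodes)
    truth = pd.DataFrame({"label": labels, "htos": sources}, index=barcodes)
    return counts_df, truth


# ---------------------------------------------------------------------------
# tissue expression panel
# ---------------------------------------------------------------------------


@dataclass
class TissuePanelSpec:
    """Gene x tissue expression panel with genes of known specificity."""

    n_single: int = 20  # one tissue only  -> tau = 1
    n_uniform: int = 20  # flat profile     -> tau = 0
    n_graded: int = 20  # geometric decay  -> intermediate tau
    n_random: int = 40  # lognormal noise genes
    graded_ratio: float = 0.5
    level: float = 10.0
    seed: int = 0


def gen_tissue_panel(
    n_genes: int | None = None,
    n_tissues: int = 27,
    spec: TissuePanelSpec | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a tissue panel and per-gene construction truth.

    Returns ``(panel, truth)``; ``truth`` records each gene's archetype
    (single/uniform/graded/random) and, for single-tissue genes, the tissue.
    If ``n_genes`` is given the archetype counts are scaled to match it.
    """
    spec = spec or TissuePanelSpec()
    if n_tissues < 2:
        raise SpecificationError("need at least two tissues")
    counts = np.array([spec.n_single, spec.n_uniform, spec.n_graded, spec.n_random])
    if n_genes is not None:
        counts = np.maximum(1, (counts * n_genes / counts.sum()).astype(int))
    rng = np.random.default_rng(spec.seed)
    tissues = [f"tissue_{i + 1}" for i in range(n_tissues)]
    rows, names, kinds, true_tissue = [], [], [], []
    g = 0
    for _ in range(counts[0]):
        t = int(rng.integers(n_tissues))
        x = np.zeros(n_tissues)
        x[t] = spec.level
        rows.append(x); names.append(f"gene_{g}"); kinds.append("single")
        true_tissue.append(tissues[t]); g += 1
    for _ in range(counts[1]):
        rows.append(np.full(n_tissues, spec.level))
        names.append(f"gene_{g}"); kinds.append("uniform"); true_tissue.append(""); g += 1
    for _ in range(counts[2]):
        order = rng.permutation(n_tissues)
        x = spec.level * spec.graded_ratio ** np.argsort(order)
        rows.append(x); names.append(f"gene_{g}"); kinds.append("graded")
        true_tissue.append(tissues[int(np.argmax(x))]); g += 1
    for _ in range(counts[3]):
        rows.append(rng.lognormal(0, 1, size=n_tissues))
        names.append(f"gene_{g}"); kinds.append("random"); true_tissue.append(""); g += 1
    panel = pd.DataFrame(rows, index=names, columns=tissues)
    truth = pd.DataFrame({"archetype": kinds, "tissue": true_tissue}, index=names)
    return panel, truth


# ---------------------------------------------------------------------------
# latent trajectory
# ---------------------------------------------------------------------------


@dataclass
class TrajectorySpec:
    """1-D latent differentiation axis sampled from a Gaussian mixture whose
    state weights shift with age, embedded on a noisy curve."""

    ages: tuple[int, ...] = (1, 4, 16)
    n_replicates: int = 3
    n_cells_per_sample: int = 150
    state_means: tuple[float, ...] = (2.0, 5.0, 8.0)
    state_sds: tuple[float, ...] = (0.5, 0.5, 0.5)
    state_weights: Mapping[int, Sequence[float]] | None = None  # age -> weights
    embed_dim: int = 10
    noise_sd: float = 0.2
    seed: int = 0

    def weights(self, age: int) -> np.ndarray:
        if self.state_weights is not None:
            w = np.asarray(self.state_weights[age], dtype=float)
        else:
            w = np.full(len(self.state_means), 1.0 / len(self.state_means))
        if not np.isclose(w.sum(), 1.0):
            raise SpecificationError(f"state weights for age {age} must sum to 1")
        return w

    def validate(self) -> None:
        means = np.asarray(self.state_means)
        if not np.all(np.diff(means) > 0):
            raise SpecificationError("state means must be strictly increasing")
        for age in self.ages:
            self.weights(age)


def _curve(t: np.ndarray, dim: int) -> np.ndarray:
    """Smooth injective curve embedding of a 1-D axis.

    Only gentle (low-frequency) components so the curve never folds back on
    itself at the scale of the embedding noise."""
    cols = [t, np.sin(0.4 * t), np.cos(0.4 * t)]
    for i in range(3, dim):
        cols.append(0.3 * np.sin(0.1 * t + 0.7 * i))
    return np.column_stack(cols[:dim])


def gen_trajectory(spec: TrajectorySpec) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Generate an embedded trajectory sample.

    Returns ``(X, obs, truth)``: the cells x dims embedding, per-cell
    ``age``/``replicate`` metadata, and truth holding the generating state
    and latent position of every cell.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ts, states, metas = [], [], []
    for age in spec.ages:
        w = spec.weights(age)
        for rep in range(1, spec.n_replicates + 1):
            comp = rng.choice(len(w), size=spec.n_cells_per_sample, p=w)
            t = rng.normal(np.asarray(spec.state_means)[comp], np.asarray(spec.state_sds)[comp])
            ts.append(t)
            states.append(comp)
            metas.extend([(age, rep)] * spec.n_cells_per_sample)
    t = np.concatenate(ts)
    states = np.concatenate(states) + 1  # states are 1-based
    X = _curve(t, spec.embed_dim)
    if spec.noise_sd > 0:
        X = X + rng.normal(0.0, spec.noise_sd, size=X.shape)
    obs = pd.DataFrame(metas, columns=["age", "replicate"])
    obs.index = [f"cell_{i}" for i in range(len(obs))]
    truth = {"state": states, "latent": t}
    return X, obs, truth
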