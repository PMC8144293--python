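"""Alpha and beta diversity measures over one shared tree kernel.

All four phylogenetic quantities (Faith's PD, balance-weighted PD, and both
UniFracs) are functions of the same object: the *edge mass* p_e, the total
relative abundance of the taxa descending from each edge e of a rooted tree.

* Faith's PD      = Σ l_e · [p_e > 0]                 (presence of the edge)
* BWPD_θ          = Σ l_e · (2 · min(p_e, 1 − p_e))^θ (balance weighting)
* unweighted UniFrac = Σ_{XOR} l_e / Σ_{OR} l_e       (edge presence sets)
* weighted UniFrac   = Σ l_e |p_e^x − p_e^y|  [/ Σ l_e (p_e^x + p_e^y)]

Edge masses are computed in a single post-order pass; for whole tables the
pass is vectorized across samples, which is what makes the threshold sweep
cheap.  The non-phylogenetic measures (richness, Shannon, Jaccard, Morisita,
Bray–Curtis) are classical and implemented directly from their formulas.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import CongruenceError, ParameterError, UndefinedValueError
from .io import FeatureTable
from .tree import Phylogeny

logger = logging.getLogger(__name__)

ALPHA_METRICS = ("richness", "faith_pd", "shannon", "bwpd")
BETA_METRICS = ("jaccard", "unweighted-unifrac", "morisita", "weighted-unifrac", "bray-curtis")

__all__ = [
    "ALPHA_METRICS",
    "BETA_METRICS",
    "DissimilarityMatrix",
    "edge_masses",
    "edge_mass_matrix",
    "observed_richness",
    "shannon",
    "faith_pd",
    "bwpd",
    "jaccard",
    "morisita",
    "bray_curtis",
    "unweighted_unifrac",
    "weighted_unifrac",
    "pairwise_matrix",
    "mean_dissimilarity_per_sample",
    "alpha_diversity_table",
]


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise beta-diversity matrix with zero diagonal."""

    sample_ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValueError("matrix shape does not match sample ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        np.fill_diagonal(self.data, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids, columns=self.sample_ids)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy's condensed order."""
        return squareform(self.data, checks=False)


# --------------------------------------------------------------------- #
# edge-mass kernel
# --------------------------------------------------------------------- #
def edge_mass_matrix(
    rel_abund: np.ndarray, taxon_ids: list[str], tree: Phylogeny
) -> np.ndarray:
    """Descendant mass on every tree edge, for many samples at once.

    Parameters
    ----------
    rel_abund : (n_samples, n_taxa) relative abundances, rows sum to 1
        (or to 0 for empty samples).
    taxon_ids : column labels of ``rel_abund``; must all be tree leaves.

    Returns
    -------
    (n_nodes, n_samples) array M with ``M[v, i]`` the abundance mass of
    sample i below the edge above node v.  The root row is the row sum
    (1 for non-empty samples).
    """
    rel_abund = np.atleast_2d(np.asarray(rel_abund, dtype=float))
    missing = [t for t in taxon_ids if t not in tree.leaf_index]
    if missing:
        raise CongruenceError(f"taxa not in tree: {missing[:5]}")
    n_nodes = tree.n_nodes
    mass = np.zeros((n_nodes, rel_abund.shape[0]))
    rows = np.array([tree.leaf_index[t] for t in taxon_ids], dtype=np.int64)
    np.add.at(mass, rows, rel_abund.T)
    parent = tree.parent
    for v in tree.postorder:
        p = parent[v]
        if p >= 0:
            mass[p] += mass[v]
    return mass


def edge_masses(abundances: Mapping[str, float], tree: Phylogeny) -> np.ndarray:
    """Edge masses for a single sample given a taxon → abundance mapping."""
    taxa = list(abundances)
    vec = np.array([[abundances[t] for t in taxa]], dtype=float)
    return edge_mass_matrix(vec, taxa, tree)[:, 0]


def _rel(counts: np.ndarray) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise UndefinedValueError("sample has no reads")
    return counts / total


def _single_edge_masses(
    counts: np.ndarray, taxon_ids: list[str], tree: Phylogeny
) -> np.ndarray:
    return edge_mass_matrix(_rel(counts)[None, :], taxon_ids, tree)[:, 0]


# --------------------------------------------------------------------- #
# alpha diversity
# --------------------------------------------------------------------- #
def observed_richness(counts: np.ndarray) -> int:
    """Number of taxa with a positive count."""
    return int(np.count_nonzero(np.asarray(counts) > 0))


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy H = −Σ p_j ln p_j (natural log; 0·ln 0 ≡ 0)."""
    p = _rel(counts)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def faith_pd(counts: np.ndarray, taxon_ids: list[str], tree: Phylogeny) -> float:
    """Faith's phylogenetic diversity, rooted convention.

    Sum of branch lengths over every edge with positive descendant mass,
    i.e. the subtree connecting all present taxa up to and including the
    root (so a single-taxon sample scores its full root-to-leaf path).
    """
    mass = _single_edge_masses(counts, taxon_ids, tree)
    return float(tree.length[mass > 0].sum())


def bwpd(
    counts: np.ndarray, taxon_ids: list[str], tree: Phylogeny, theta: float = 0.5
) -> float:
    """Balance-weighted phylogenetic diversity BWPD_θ.

    Each branch contributes l_e · (2 · min(p_e, 1 − p_e))^θ, interpolating
    between plain PD restricted to "balanced" edges (θ=0, with 0^0 ≡ 0 so
    edges carrying all or none of the sample never contribute) and twice the
    abundance-balance mass (θ=1).  Default θ = 0.5.
    """
    if not 0.0 <= theta <= 1.0:
        raise ParameterError(f"theta must be in [0, 1], got {theta}")
    mass = _single_edge_masses(counts, taxon_ids, tree)
    return float(_bwpd_from_mass(mass[:, None], tree.length, theta)[0])


def _bwpd_from_mass(mass: np.ndarray, lengths: np.ndarray, theta: float) -> np.ndarray:
    bal = 2.0 * np.minimum(mass, 1.0 - mass)
    bal = np.clip(bal, 0.0, 1.0)
    # edges carrying (numerically) all or none of the sample never contribute:
    # for theta < 1 a rounding-level balance would otherwise be amplified by
    # the fractional power (eps^theta >> eps)
    bal[bal < 1e-12] = 0.0
    if theta == 0.0:
        w = (bal > 0).astype(float)  # 0^0 := 0 on degenerate edges
    else:
        w = bal**theta
    return lengths @ w


def alpha_diversity_table(
    table: FeatureTable,
    tree: Phylogeny | None = None,
    metrics: tuple[str, ...] = ALPHA_METRICS,
    theta: float = 0.5,
) -> pd.DataFrame:
    """All requested alpha metrics for every sample (vectorized).

    Samples with zero reads get NaN for every metric except richness (0).
    """
    unknown = set(metrics) - set(ALPHA_METRICS)
    if unknown:
        raise ParameterError(f"unknown alpha metrics: {sorted(unknown)}")
    totals = table.library_sizes().astype(float)
    rel = table.relative_abundances()
    out = pd.DataFrame(index=table.sample_ids)
    empty = totals == 0
    if "richness" in metrics:
        out["richness"] = (table.counts > 0).sum(axis=1).astype(float)
    if "shannon" in metrics:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(rel > 0, rel * np.log(np.where(rel > 0, rel, 1.0)), 0.0)
        h = -plogp.sum(axis=1)
        h[empty] = np.nan
        out["shannon"] = h
    if "faith_pd" in metrics or "bwpd" in metrics:
        if tree is None:
            raise ParameterError("phylogenetic alpha metrics require a tree")
        mass = edge_mass_matrix(rel, table.taxon_ids, tree)
        if "faith_pd" in metrics:
            pd_vals = tree.length @ (mass > 0)
            pd_vals[empty] = np.nan
            out["faith_pd"] = pd_vals
        if "bwpd" in metrics:
            bw = _bwpd_from_mass(mass, tree.length, theta)
            bw[empty] = np.nan
            out["bwpd"] = bw
    return out[list(metrics)]


# --------------------------------------------------------------------- #
# beta diversity (scalar forms)
# --------------------------------------------------------------------- #
def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("samples must have equal length")
    if x.sum() <= 0 or y.sum() <= 0:
        raise UndefinedValueError("beta dissimilarity is undefined for empty samples")
    return x, y


def jaccard(x: np.ndarray, y: np.ndarray) -> float:
    """Presence/absence Jaccard dissimilarity 1 − |A∩B|/|A∪B|."""
    x, y = _check_pair(x, y)
    a, b = x > 0, y > 0
    union = np.count_nonzero(a | b)
    inter = np.count_nonzero(a & b)
    return 1.0 - inter / union


def morisita(x: np.ndarray, y: np.ndarray, clamp: bool = True) -> float:
    """Morisita dissimilarity on integer counts.

    Similarity C = 2 Σ x_j y_j / ((λ_x + λ_y) X Y) with
    λ_x = Σ x_j (x_j − 1) / (X (X − 1)); the returned dissimilarity 1 − C is
    clamped at 0 by default because C can exceed 1 for near-identical
    low-count samples (set ``clamp=False`` for the raw value).
    """
    x, y = _check_pair(x, y)
    for v in (x, y):
        if np.any(np.abs(v - np.round(v)) > 0):
            raise ParameterError("Morisita requires integer counts")
    X, Y = x.sum(), y.sum()
    if X < 2 or Y < 2:
        raise UndefinedValueError("Morisita requires sample totals >= 2")
    lam_x = (x * (x - 1)).sum() / (X * (X - 1))
    lam_y = (y * (y - 1)).sum() / (Y * (Y - 1))
    if lam_x + lam_y == 0:
        raise UndefinedValueError("Morisita undefined: both samples are all singletons")
    c = 2.0 * (x * y).sum() / ((lam_x + lam_y) * X * Y)
    d = 1.0 - c
    return float(max(0.0, d)) if clamp else float(d)


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Bray–Curtis dissimilarity Σ|x_j − y_j| / Σ(x_j + y_j)."""
    x, y = _check_pair(x, y)
    return float(np.abs(x - y).sum() / (x + y).sum())


def unweighted_unifrac(
    x: np.ndarray, y: np.ndarray, taxon_ids: list[str], tree: Phylogeny
) -> float:
    """Fraction of branch length unique to either community.

    An edge is "present" for a sample when its descendant mass is positive;
    the score is (length in exactly one edge set) / (length in at least one).
    """
    x, y = _check_pair(x, y)
    mx = _single_edge_masses(x, taxon_ids, tree) > 0
    my = _single_edge_masses(y, taxon_ids, tree) > 0
    unique = tree.length[mx ^ my].sum()
    union = tree.length[mx | my].sum()
    return float(unique / union)


def weighted_unifrac(
    x: np.ndarray,
    y: np.ndarray,
    taxon_ids: list[str],
    tree: Phylogeny,
    normalized: bool = True,
) -> float:
    """Weighted UniFrac: branch-length-weighted edge-mass differences.

    Raw form Σ l_e |p_e^x − p_e^y|; the normalized form (default) divides by
    Σ l_e (p_e^x + p_e^y) so the score lies in [0, 1].
    """
    x, y = _check_pair(x, y)
    mx = _single_edge_masses(x, taxon_ids, tree)
    my = _single_edge_masses(y, taxon_ids, tree)
    raw = float((tree.length * np.abs(mx - my)).sum())
    if not normalized:
        return raw
    denom = float((tree.length * (mx + my)).sum())
    return raw / denom


# --------------------------------------------------------------------- #
# pairwise matrices (vectorized)
# --------------------------------------------------------------------- #
def pairwise_matrix(
    table: FeatureTable,
    tree: Phylogeny | None = None,
    metric: str = "jaccard",
    normalized: bool = True,
) -> DissimilarityMatrix:
    """Pairwise beta-diversity matrix over all usable samples.

    Samples with zero total count (or, for Morisita, total < 2) cannot be
    scored and are excluded with a warning; the returned matrix covers the
    remaining samples.
    """
    if metric not in BETA_METRICS:
        raise ParameterError(f"unknown metric {metric!r}; choose from {BETA_METRICS}")
    totals = table.library_sizes()
    min_total = 2 if metric == "morisita" else 1
    usable = np.flatnonzero(totals >= min_total)
    dropped = [table.sample_ids[i] for i in np.flatnonzero(totals < min_total)]
    if dropped:
        logger.warning(
            "pairwise_matrix(%s): excluding %d sample(s) with insufficient reads: %s",
            metric, len(dropped), dropped[:10],
        )
    if usable.size < 2:
        raise UndefinedValueError("need at least two non-empty samples")
    sub = table.select_samples(usable)
    ids = sub.sample_ids
    counts = sub.counts.astype(float)

    if metric == "jaccard":
        mat = squareform(pdist(counts > 0, metric="jaccard"))
    elif metric == "bray-curtis":
        num = squareform(pdist(counts, metric="cityblock"))
        tot = counts.sum(axis=1)
        mat = num / (tot[:, None] + tot[None, :])
    elif metric == "morisita":
        X = counts.sum(axis=1)
        lam = (counts * (counts - 1)).sum(axis=1) / (X * (X - 1))
        cross = counts @ counts.T
        c = 2.0 * cross / ((lam[:, None] + lam[None, :]) * X[:, None] * X[None, :])
        mat = np.maximum(0.0, 1.0 - c)
    else:
        if tree is None:
            raise ParameterError(f"{metric} requires a tree")
        mass = edge_mass_matrix(sub.relative_abundances(), sub.taxon_ids, tree)
        lengths = tree.length
        if metric == "unweighted-unifrac":
            pres = (mass > 0).astype(float) * lengths[:, None]
            uniq = squareform(pdist(pres.T, metric="cityblock"))
            s = pres.sum(axis=0)
            union = (s[:, None] + s[None, :] + uniq) / 2.0
            with np.errstate(invalid="ignore", divide="ignore"):
                mat = np.where(union > 0, uniq / union, 0.0)
        else:  # weighted-unifrac
            weighted = mass * lengths[:, None]
            raw = squareform(pdist(weighted.T, metric="cityblock"))
            if normalized:
                s = weighted.sum(axis=0)
                mat = raw / (s[:, None] + s[None, :])
            else:
                mat = raw
    np.fill_diagonal(mat, 0.0)
    return DissimilarityMatrix(ids, mat)


def mean_dissimilarity_per_sample(matrix: DissimilarityMatrix) -> pd.Series:
    """Mean of d(i, j) over all j ≠ i, per sample i."""
    n = len(matrix.sample_ids)
    if n < 2:
        raise UndefinedValueError("mean dissimilarity needs at least two samples")
    sums = matrix.data.sum(axis=1)
    return pd.Series(sums / (n - 1), index=matrix.sample_ids)


def matrix_to_long(matrix: DissimilarityMatrix, metric: str) -> pd.DataFrame:
    """Long-format (i, j, metric, value) records of the upper triangle."""
    ids = matrix.sample_ids
    rows = [
        (ids[a], ids[b], metric, matrix.data[a, b])
        for a in range(len(ids))
        for b in range(a + 1, len(ids))
    ]
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "metric", "value"])
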