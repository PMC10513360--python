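"""Spatial statistics for compositional annotations.

Pair statistics treat compositional annotations bilinearly: the weight of an
ordered observation pair (i, j) for (center c, annotation a) is
center_i[c] * anno_j[a].  Self-pairs are excluded throughout.  Distances are
Euclidean in the stored coordinate units (micrometres) with half-open bins
[e_k, e_{k+1}).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree
from scipy.stats import ttest_ind

import igraph
import leidenalg
from sklearn.neighbors import NearestNeighbors

from .data import CompositionMatrix

__all__ = [
    "CoOccurrence",
    "co_occurrence",
    "neighborhood_zscores",
    "define_regions",
    "annotation_coordinate",
    "enrichment_test",
]


@dataclass
class CoOccurrence:
    """p(anno|center; bin) / p(anno), indexed [anno, center, bin]."""

    anno_ids: list
    center_ids: list
    bin_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray


def _check_bins(bins) -> np.ndarray:
    edges = np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or (np.diff(edges) <= 0).any() or edges[0] < 0:
        raise ValueError("bins must be increasing non-negative distance edges")
    return edges


def _coords(positions) -> np.ndarray:
    if hasattr(positions, "coords"):
        return positions.coords
    return np.asarray(positions, dtype=float)


def _bin_adjacency(coords: np.ndarray, edges: np.ndarray) -> list:
    """Sparse 0/1 adjacency of ordered pairs per distance bin (no self-pairs)."""
    n = len(coords)
    tree = cKDTree(coords)
    dist = tree.sparse_distance_matrix(
        tree, float(edges[-1]), output_type="coo_matrix"
    )
    mask = dist.row != dist.col
    row, col, d = dist.row[mask], dist.col[mask], dist.data[mask]
    if edges[0] > 0:
        inside = d >= edges[0]
        row, col, d = row[inside], col[inside], d[inside]
    which = np.digitize(d, edges) - 1
    # half-open bins: drop d == last edge
    ok = (which >= 0) & (which < len(edges) - 1)
    out = []
    for k in range(len(edges) - 1):
        sel = ok & (which == k)
        out.append(
            sp.csr_matrix(
                (np.ones(int(sel.sum())), (row[sel], col[sel])), shape=(n, n)
            )
        )
    return out


def _pair_sums(adj: list, center_w: np.ndarray, anno_w: np.ndarray) -> np.ndarray:
    """S[a, c, k] = sum over ordered pairs in bin k of center_i[c] anno_j[a]."""
    n_anno, n_center = anno_w.shape[1], center_w.shape[1]
    S = np.empty((n_anno, n_center, len(adj)))
    for k, A in enumerate(adj):
        S[:, :, k] = (anno_w.T @ A.T @ center_w)
    return S


def co_occurrence(
    positions,
    anno: CompositionMatrix,
    center: CompositionMatrix | None = None,
    bins=(0.0, 20.0),
) -> CoOccurrence:
    """Distance-resolved co-occurrence ratio p(anno|center; x) / p(anno).

    For each distance bin, pair weights of ordered (center, anno) pairs are
    summed and normalized over the anno axis, then divided by the global
    annotation frequency.  Bins without pairs yield NaN.
    """
    center = center if center is not None else anno
    edges = _check_bins(bins)
    coords = _coords(positions)
    anno_w = anno.to_probability().weights
    center_w = center.to_probability().weights
    adj = _bin_adjacency(coords, edges)
    S = _pair_sums(adj, center_w, anno_w)
    counts = S.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_cond = S / counts
        p_anno = anno_w.mean(axis=0)
        values = p_cond / p_anno[:, None, None]
    values[:, (counts[0] == 0)] = np.nan
    return CoOccurrence(
        list(anno.category_ids),
        list(center.category_ids),
        edges,
        values,
        np.broadcast_to(counts[0], values.shape).copy(),
    )


def neighborhood_zscores(
    positions,
    anno: CompositionMatrix,
    center: CompositionMatrix | None = None,
    bins=(0.0, 20.0),
    n_perm: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Permutation z-scores of pair-weight sums per (anno, center, bin).

    The observed bilinear pair-weight sum is compared with its distribution
    over ``n_perm`` random permutations of the annotation rows across
    observations; z = (obs - mean) / sd, with z = 0 where sd = 0.  When
    ``center`` is the same annotation as ``anno`` (or omitted), the same
    permutation is applied to both, i.e. whole annotation assignments are
    permuted; unrelated center annotations stay fixed.
    """
    if n_perm < 30:
        raise ValueError("n_perm must be >= 30")
    joint = center is None or center is anno
    center = center if center is not None else anno
    edges = _check_bins(bins)
    coords = _coords(positions)
    anno_w = anno.to_probability().weights
    center_w = center.to_probability().weights
    adj = _bin_adjacency(coords, edges)
    observed = _pair_sums(adj, center_w, anno_w)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm,) + observed.shape)
    for p in range(n_perm):
        perm = rng.permutation(anno_w.shape[0])
        cw = center_w[perm] if joint else center_w
        perms[p] = _pair_sums(adj, cw, anno_w[perm])
    mean = perms.mean(axis=0)
    sd = perms.std(axis=0, ddof=1)
    z = np.zeros_like(observed)
    np.divide(observed - mean, sd, out=z, where=sd > 0)
    return z


def define_regions(
    features: np.ndarray,
    positions,
    sample_labels=None,
    position_weight: float = 0.5,
    k_neighbors: int = 10,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Region labels from combined expression/annotation and position graphs.

    A k-nearest-neighbor graph in feature space spans all samples; a second
    kNN graph in position space is built within each sample.  The combined
    adjacency is (1 - position_weight) * A_feat + position_weight * A_pos,
    where cross-sample feature edges are up-weighted by the ratio of total
    within-sample to cross-sample feature edge weight, compensating for the
    position graph having no cross-sample links.  Leiden clustering of the
    combined graph yields labels consistent across samples.
    """
    features = np.asarray(features, dtype=float)
    coords = _coords(positions)
    n = len(features)
    if sample_labels is None:
        sample_labels = np.zeros(n, dtype=int)
    sample_labels = np.asarray(sample_labels)
    if not 0 <= position_weight <= 1:
        raise ValueError("position_weight must be in [0, 1]")

    def _knn_graph(X, subset=None):
        idx = np.arange(n) if subset is None else subset
        if len(idx) == 1:
            return sp.csr_matrix((n, n))
        k = min(k_neighbors, len(idx) - 1)
        nn = NearestNeighbors(n_neighbors=k).fit(X[idx])
        A = nn.kneighbors_graph(X[idx], mode="connectivity")
        A = sp.coo_matrix(A)
        return sp.csr_matrix(
            (A.data, (idx[A.row], idx[A.col])), shape=(n, n)
        )

    A_feat = _knn_graph(features)
    A_feat = ((A_feat + A_feat.T) > 0).astype(float)
    A_pos = sp.csr_matrix((n, n))
    for s in np.unique(sample_labels):
        members = np.flatnonzero(sample_labels == s)
        A_pos = A_pos + _knn_graph(coords, members)
    A_pos = ((A_pos + A_pos.T) > 0).astype(float)

    coo = A_feat.tocoo()  # rescale cross-sample feature edges
    cross = sample_labels[coo.row] != sample_labels[coo.col]
    within_weight = coo.data[~cross].sum()
    cross_weight = coo.data[cross].sum()
    if cross_weight > 0 and within_weight > 0:
        data = coo.data.copy()
        data[cross] *= within_weight / cross_weight
        A_feat = sp.csr_matrix((data, (coo.row, coo.col)), shape=(n, n))

    A = (1.0 - position_weight) * A_feat + position_weight * A_pos
    A = sp.coo_matrix(A)
    upper = A.row < A.col
    g = igraph.Graph(
        n=n,
        edges=list(zip(A.row[upper].tolist(), A.col[upper].tolist())),
        edge_attrs={"weight": A.data[upper].tolist()},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    return np.asarray(part.membership)


def annotation_coordinate(
    positions,
    anno: CompositionMatrix,
    category: str,
    threshold: float = 2.0,
    bin_width: float = 1.0,
) -> np.ndarray:
    """Stable per-observation distance to an annotation category.

    For each observation x, occurrence histograms of the category weight
    versus distance are cumulated; the regularized radius d^l is the first
    bin where the cumulative weight reaches ``threshold`` (N_l).  The
    regularization bias is removed with a fictitious homogeneous category H
    (weight 1 per observation): d0 solves N_H(d0) = N_H(d^l) - N_l by linear
    interpolation of the cumulative H histogram.  Observations whose total
    category weight never reaches N_l get d0 = +inf.
    """
    if threshold <= 0 or bin_width <= 0:
        raise ValueError("threshold and bin_width must be positive")
    coords = _coords(positions)
    comp = anno.to_probability()
    if category not in comp.category_ids:
        raise KeyError(f"unknown category {category!r}")
    w = comp.weights[:, comp.category_ids.index(category)]
    n = len(coords)
    diffs = coords[:, None, :] - coords[None, :, :]
    D = np.sqrt((diffs**2).sum(axis=-1))
    d_max = D.max()
    edges = np.arange(0.0, d_max + 2 * bin_width, bin_width)
    d0 = np.full(n, np.inf)
    for i in range(n):
        # the observation itself participates (distance 0): required so that
        # a homogeneous annotation yields a coordinate of exactly 0
        d = D[i]
        which = np.minimum(np.digitize(d, edges) - 1, len(edges) - 2)
        n_A = np.bincount(which, weights=w, minlength=len(edges) - 1)
        N_A = np.concatenate([[0.0], np.cumsum(n_A)])  # at bin edges
        if N_A[-1] < threshold:
            continue
        n_H = np.bincount(which, minlength=len(edges) - 1).astype(float)
        N_H = np.concatenate([[0.0], np.cumsum(n_H)])
        d_l = _rising_crossing(N_A, edges, threshold)
        target = max(_eval_piecewise(N_H, edges, d_l) - threshold, 0.0)
        d0[i] = max(_falling_crossing(N_H, edges, target), 0.0)
    return d0


def _rising_crossing(N: np.ndarray, edges: np.ndarray, level: float) -> float:
    """Smallest d with piecewise-linear cumulative N(d) >= level."""
    k = int(np.searchsorted(N, level, side="left"))
    if k == 0:
        return float(edges[0])
    rise = N[k] - N[k - 1]
    frac = (level - N[k - 1]) / rise if rise > 0 else 1.0
    return float(edges[k - 1] + frac * (edges[k] - edges[k - 1]))


def _falling_crossing(N: np.ndarray, edges: np.ndarray, level: float) -> float:
    """Largest d with piecewise-linear cumulative N(d) <= level."""
    j = int(np.searchsorted(N, level, side="right"))
    if j >= len(N):
        return float(edges[-1])
    if j == 0:
        return float(edges[0])
    rise = N[j] - N[j - 1]
    frac = (level - N[j - 1]) / rise if rise > 0 else 1.0
    return float(edges[j - 1] + frac * (edges[j] - edges[j - 1]))


def _eval_piecewise(N: np.ndarray, edges: np.ndarray, d: float) -> float:
    return float(np.interp(d, edges, N))


def enrichment_test(
    compositions: CompositionMatrix,
    group_labels,
    sample_labels,
    n_splits_per_axis: int | None = None,
    positions=None,
) -> pd.DataFrame:
    """Per-category enrichment between two groups across ensemble units.

    Ensemble units are samples, or spatial sub-blocks of samples when
    ``n_splits_per_axis`` is given (requires positions).  Within each unit
    the mean composition is taken; per category a two-sided Welch t-test
    compares the two groups across units, with Benjamini-Hochberg
    correction.  Effect sizes are log2 ratios of group means.
    """
    comp = compositions.to_probability()
    group_labels = np.asarray(group_labels)
    sample_labels = np.asarray(sample_labels)
    units = sample_labels.astype(str)
    if n_splits_per_axis:
        if positions is None:
            raise ValueError("spatial splitting requires positions")
        coords = _coords(positions)
        block = np.empty(len(coords), dtype=object)
        for s in np.unique(units):
            members = units == s
            sub = coords[members]
            codes = np.zeros(members.sum(), dtype=int)
            for ax in range(sub.shape[1]):
                lo, hi = sub[:, ax].min(), sub[:, ax].max()
                cuts = np.linspace(lo, hi, n_splits_per_axis + 1)[1:-1]
                codes = codes * n_splits_per_axis + np.digitize(sub[:, ax], cuts)
            block[members] = [f"{s}:{c}" for c in codes]
        units = block.astype(str)

    groups = np.unique(group_labels)
    if len(groups) != 2:
        raise ValueError("enrichment test expects exactly two groups")
    df = pd.DataFrame(comp.weights, columns=comp.category_ids)
    df["unit"] = units
    df["group"] = group_labels
    unit_means = df.groupby(["group", "unit"], observed=True).mean()
    rows = []
    for cat in comp.category_ids:
        a = unit_means.loc[groups[0]][cat].to_numpy()
        b = unit_means.loc[groups[1]][cat].to_numpy()
        if len(a) < 2 or len(b) < 2:
            warnings.warn("a group has fewer than 2 ensemble units")
            p = np.nan
        elif np.allclose(a, a[0]) and np.allclose(b, b[0]) and np.isclose(a[0], b[0]):
            p = 1.0
        else:
            p = float(ttest_ind(a, b, equal_var=False).pvalue)
            if np.isnan(p):
                p = 1.0
        mean_a, mean_b = a.mean(), b.mean()
        effect = np.log2(max(mean_a, 1e-300) / max(mean_b, 1e-300))
        rows.append({"category": cat, "effect_log2": effect, "pvalue": p})
    out = pd.DataFrame(rows)
    out["qvalue"] = _benjamini_hochberg(out["pvalue"].to_numpy())
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    from scipy.stats import false_discovery_control

    q = np.full_like(p, np.nan, dtype=float)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = false_discovery_control(p[ok], method="bh")
    return q
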