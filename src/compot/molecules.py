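"""Segmentation-free single-molecule annotation and image-free segmentation.

Molecules (x, y, gene) are binned on a Cartesian grid, each bin is
compositionally annotated against reference category profiles, the bin
annotation is distributed to individual molecules through per-bin count
splitting, and the whole procedure is repeated on shifted grids so each
molecule collects several votes; the modal vote is its category.

Segmentation into cell-like objects combines spatial distances and a
category-derived distance in quadrature, converts them to Gaussian
affinities and cuts the resulting sparse graph recursively with normalized
cuts, starting from spatially defined supernodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .boosters import AnnotateConfig, annotate_with_profiles
from .data import CountMatrix, MoleculeTable, ReferenceProfiles
from .ot import bhattacharyya
from .splitting import split_observation

__all__ = [
    "MoleculeAnnotationConfig",
    "SegmentationConfig",
    "bin_molecules",
    "annotate_molecules",
    "sparse_spatial_distances",
    "segment_molecules",
    "pool_segments",
]


def _default_annotate_config() -> AnnotateConfig:
    # molecule data and reference share platform effects: normalization off
    return AnnotateConfig(platform_normalize=False, multi_center=0)


@dataclass
class MoleculeAnnotationConfig:
    bin_size: float = 10.0  # um, the expected feature (cell) size
    n_shifts: int = 3
    annotate_config: AnnotateConfig = field(default_factory=_default_annotate_config)
    seed: int = 0

    def __post_init__(self):
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if self.n_shifts < 1:
            raise ValueError("n_shifts must be >= 1")


@dataclass
class SegmentationConfig:
    distance_scale: float = 3.0  # um, subcellular Gaussian kernel width
    max_distance: float | None = None  # neighbor cutoff; default 4x scale
    annotation_distance: str | np.ndarray = "infinite"  # or 'auto', or matrix
    min_molecules: int = 20
    supernode_size: float = 20.0  # um, grid for initial supernodes
    seed: int = 0

    def __post_init__(self):
        if self.distance_scale <= 0:
            raise ValueError("distance_scale must be positive")
        if self.min_molecules < 1:
            raise ValueError("min_molecules must be >= 1")
        if self.max_distance is None:
            self.max_distance = 4.0 * self.distance_scale


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def bin_molecules(
    mol: MoleculeTable,
    bin_size: float,
    shift: np.ndarray | tuple = (0.0, 0.0),
    gene_ids: list | None = None,
) -> tuple[CountMatrix, np.ndarray, np.ndarray]:
    """Bin molecules on a Cartesian grid.

    A molecule at position x goes to bin floor(x / bin_size - shift) per
    dimension (boundary molecules go to the lower-index bin).  Empty bins
    are omitted.  Returns (bin x gene counts, bin center coordinates,
    per-molecule bin index into the returned bins).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    shift = np.asarray(shift, dtype=float)
    coords = mol.coords
    idx = np.floor(coords / bin_size - shift[None, :]).astype(np.int64)
    bins, inverse = np.unique(idx, axis=0, return_inverse=True)
    genes = gene_ids if gene_ids is not None else sorted(set(mol.genes))
    gene_pos = pd.Index(genes).get_indexer(mol.genes)
    if (gene_pos < 0).any():
        raise KeyError("molecule gene outside the declared gene universe")
    counts = sp.csr_matrix(
        (np.ones(len(mol)), (inverse, gene_pos)),
        shape=(len(bins), len(genes)),
    )
    centers = (bins + shift[None, :] + 0.5) * bin_size
    bin_ids = [f"bin{i}" for i in range(len(bins))]
    return CountMatrix(bin_ids, list(genes), counts), centers, inverse


# ---------------------------------------------------------------------------
# single-molecule annotation
# ---------------------------------------------------------------------------

def annotate_molecules(
    mol: MoleculeTable,
    ref_profiles: ReferenceProfiles,
    config: MoleculeAnnotationConfig | None = None,
) -> MoleculeTable:
    """Assign a category to every molecule with a known gene.

    For each of n_shifts^2 shifted grids, bins are compositionally annotated
    and the bin annotation is split over molecule species; within a (bin,
    gene) cell the integer category counts are dealt out randomly among the
    individual molecules so the population reproduces the annotation
    probabilities.  Each molecule's final label is the modal vote over
    grids; ties break toward the category with the highest mean
    compositional weight over the molecule's bins, then lexicographically.
    """
    config = config or MoleculeAnnotationConfig()
    genes = list(ref_profiles.gene_ids)
    known = np.isin(mol.genes, genes)
    if not known.all():
        warnings.warn(
            f"dropping {int((~known).sum())} molecules with genes absent "
            "from the reference profiles"
        )
    sub = MoleculeTable(mol.frame.loc[known].reset_index(drop=True))
    n_mol = len(sub)
    cats = list(ref_profiles.category_ids)
    parent_ids = sorted(set(ref_profiles.parents()))
    n_shifts = config.n_shifts
    votes = np.zeros((n_mol, len(parent_ids)), dtype=np.int64)
    weight_sums = np.zeros((n_mol, len(parent_ids)))
    rng = np.random.default_rng(config.seed)
    gene_pos = pd.Index(genes).get_indexer(sub.genes)
    for si in range(n_shifts):
        for sj in range(n_shifts):
            shift = np.array([si / n_shifts, sj / n_shifts])
            bins, _, inverse = bin_molecules(sub, config.bin_size, shift, genes)
            comp = annotate_with_profiles(bins, ref_profiles, config.annotate_config)
            comp = comp.as_frame()[parent_ids].to_numpy()
            weight_sums += comp[inverse]
            labels = _assign_bin_labels(
                bins, comp, parent_ids, ref_profiles, gene_pos, inverse, rng
            )
            votes[np.arange(n_mol), labels] += 1
    best = _break_ties(votes, weight_sums, parent_ids)
    out = mol.frame.copy()
    out.loc[:, "category"] = None
    out.loc[known, "category"] = np.asarray(parent_ids, dtype=object)[best]
    return MoleculeTable(out.loc[known].reset_index(drop=True))


def _assign_bin_labels(
    bins: CountMatrix,
    comp: np.ndarray,
    parent_ids: list,
    profiles: ReferenceProfiles,
    gene_pos: np.ndarray,
    inverse: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Distribute per-bin compositions to individual molecules.

    Splits each bin's species counts over categories (RAS + multinomial
    rounding of remainders) and deals the integer category counts randomly
    among that bin's molecules of each species.
    """
    # aggregate (possibly sub-categorized) profiles to parent categories
    parents = profiles.parents()
    agg = np.zeros((len(profiles.gene_ids), len(parent_ids)))
    col = {p: j for j, p in enumerate(parent_ids)}
    weights = (
        profiles.category_weights
        if profiles.category_weights is not None
        else np.ones(len(profiles.category_ids))
    )
    for i, p in enumerate(parents):
        agg[:, col[p]] += profiles.profiles[:, i] * weights[i]
    agg /= np.maximum(agg.sum(axis=0, keepdims=True), 1e-300)

    labels = np.zeros(len(inverse), dtype=np.int64)
    X = bins.values.tocsr()
    for b in range(X.shape[0]):
        mol_here = np.flatnonzero(inverse == b)
        row = np.zeros(X.shape[1])
        r = X.getrow(b)
        row[r.indices] = r.data
        joint = split_observation(row, comp[b], agg)
        # integer counts per (gene, category), conserving gene totals
        floored = np.floor(joint)
        remainder = joint - floored
        leftover = np.rint(row - floored.sum(axis=1)).astype(int)
        for g in np.flatnonzero(leftover > 0):
            p = remainder[g]
            tot = p.sum()
            p = p / tot if tot > 0 else np.full(len(parent_ids), 1 / len(parent_ids))
            floored[g] += rng.multinomial(leftover[g], p)
        for g in r.indices:
            members = mol_here[gene_pos[mol_here] == g]
            alloc = np.repeat(np.arange(len(parent_ids)), floored[g].astype(int))
            if len(alloc) < len(members):  # numerical shortfall: pad with argmax
                alloc = np.append(
                    alloc, np.full(len(members) - len(alloc), np.argmax(comp[b]))
                )
            rng.shuffle(alloc)
            labels[members] = alloc[: len(members)]
    return labels


def _break_ties(votes, weight_sums, parent_ids):
    n_cat = len(parent_ids)
    order = np.argsort(parent_ids)  # lexicographic as last resort
    rank = np.empty(n_cat)
    rank[order] = np.arange(n_cat)
    key = (
        votes.astype(np.float64) * 1e12
        + weight_sums / np.maximum(weight_sums.max(), 1e-300) * 1e3
        - rank[None, :] * 1e-6
    )
    return np.argmax(key, axis=1)


# ---------------------------------------------------------------------------
# distances and segmentation
# ---------------------------------------------------------------------------

def sparse_spatial_distances(points: np.ndarray, max_distance: float) -> sp.csr_matrix:
    """Sparse symmetric Euclidean distance matrix up to ``max_distance``.

    Contains all and only the pairs within the cutoff (diagonal excluded).
    """
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    points = np.asarray(points, dtype=float)
    tree = cKDTree(points)
    dist = tree.sparse_distance_matrix(tree, max_distance, output_type="coo_matrix")
    mask = dist.row != dist.col
    out = sp.csr_matrix(
        (dist.data[mask], (dist.row[mask], dist.col[mask])), shape=dist.shape
    )
    return out


def _affinity_graph(
    mol: MoleculeTable, config: SegmentationConfig, categories: list
) -> sp.csr_matrix:
    coords = mol.coords
    dists = sparse_spatial_distances(coords, config.max_distance).tocoo()
    cat_idx = pd.Index(categories).get_indexer(mol.frame["category"].astype(str))
    d2 = dists.data**2
    if isinstance(config.annotation_distance, str):
        if config.annotation_distance == "infinite":
            same = cat_idx[dists.row] == cat_idx[dists.col]
            keep = same
            d_tot2 = d2
        elif config.annotation_distance == "auto":
            d_anno = _auto_annotation_distance(config, categories)
            add = d_anno[cat_idx[dists.row], cat_idx[dists.col]] ** 2
            d_tot2 = d2 + add
            keep = np.isfinite(d_tot2)
        else:
            raise ValueError(
                f"unknown annotation_distance {config.annotation_distance!r}"
            )
    else:
        mat = np.asarray(config.annotation_distance, dtype=float)
        add = mat[cat_idx[dists.row], cat_idx[dists.col]] ** 2
        d_tot2 = d2 + add
        keep = np.isfinite(d_tot2)
    aff = np.exp(-0.5 * d_tot2[keep] / config.distance_scale**2)
    n = len(mol)
    return sp.csr_matrix((aff, (dists.row[keep], dists.col[keep])), shape=(n, n))


_AUTO_PROFILES: dict = {}


def _auto_annotation_distance(config: SegmentationConfig, categories: list):
    profiles = _AUTO_PROFILES.get(id(config))
    if profiles is None:
        raise ValueError(
            "annotation_distance='auto' requires profiles passed to "
            "segment_molecules"
        )
    idx = [profiles.category_ids.index(c) for c in categories]
    P = profiles.profiles[:, idx]
    n = len(categories)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            d[i, j] = 1.0 - bhattacharyya(P[:, i], P[:, j])
    return d * config.distance_scale


def segment_molecules(
    mol: MoleculeTable,
    config: SegmentationConfig | None = None,
    profiles: ReferenceProfiles | None = None,
) -> MoleculeTable:
    """Partition annotated molecules into cell-like objects.

    Affinities are Gaussian in the quadrature-combined spatial/annotation
    distance.  Connected components are processed independently; inside a
    component, supernodes (occupied coarse-grid cells per category) are cut
    recursively with 2-way normalized cuts, accepting a cut only if both
    parts hold at least ``min_molecules`` molecules and its normalized-cut
    cost is below the cost expected for a homogeneous bulk point set of the
    same size and density.  Adds a ``segment_id`` column; segments below
    ``min_molecules`` keep their id but are flagged in
    ``segment_molecules.small_segments``.
    """
    config = config or SegmentationConfig()
    if "category" not in mol.frame.columns:
        raise ValueError("molecules must carry a category column")
    if profiles is not None:
        _AUTO_PROFILES[id(config)] = profiles
    categories = sorted(set(mol.frame["category"].astype(str)))
    aff = _affinity_graph(mol, config, categories)
    n_comp, comp_labels = connected_components(aff, directed=False)
    rng = np.random.default_rng(config.seed)
    segment_ids = np.full(len(mol), -1, dtype=np.int64)
    next_id = 0
    for comp in range(n_comp):
        members = np.flatnonzero(comp_labels == comp)
        sub_aff = aff[members][:, members]
        pieces = _recursive_ncut(
            mol.coords[members], sub_aff, config, rng
        )
        for piece in pieces:
            segment_ids[members[piece]] = next_id
            next_id += 1
    out = mol.frame.copy()
    out["segment_id"] = segment_ids
    sizes = pd.Series(segment_ids).value_counts()
    segment_molecules.small_segments = set(
        sizes[sizes < config.min_molecules].index.tolist()
    )
    return MoleculeTable(out)


def _ncut_cost(aff: sp.csr_matrix, mask: np.ndarray) -> float:
    """Normalized-cut cost of a binary partition of a weighted graph."""
    degrees = np.asarray(aff.sum(axis=1)).ravel()
    cut = float(aff[mask][:, ~mask].sum())
    assoc_a = degrees[mask].sum()
    assoc_b = degrees[~mask].sum()
    if assoc_a == 0 or assoc_b == 0:
        return np.inf
    return cut / assoc_a + cut / assoc_b


def _best_spectral_cut(aff: sp.csr_matrix) -> np.ndarray | None:
    """2-way partition from the Fiedler vector of the normalized Laplacian."""
    n = aff.shape[0]
    degrees = np.asarray(aff.sum(axis=1)).ravel()
    if (degrees == 0).any() or n < 4:
        return None
    d_inv_sqrt = 1.0 / np.sqrt(degrees)
    D = sp.diags(d_inv_sqrt)
    L = sp.identity(n) - D @ aff @ D
    try:
        if n <= 64:
            vals, vecs = np.linalg.eigh(L.toarray())
            fiedler = vecs[:, 1]
        else:
            vals, vecs = sp.linalg.eigsh(L, k=2, sigma=0, which="LM")
            fiedler = vecs[:, np.argsort(vals)[1]]
    except Exception:
        return None
    score = fiedler * d_inv_sqrt
    order = np.argsort(score)
    best_mask, best_cost = None, np.inf
    # evaluate sweep cuts along the sorted Fiedler values
    checkpoints = np.unique(np.linspace(1, n - 1, min(n - 1, 32)).astype(int))
    for k in checkpoints:
        mask = np.zeros(n, dtype=bool)
        mask[order[:k]] = True
        cost = _ncut_cost(aff, mask)
        if cost < best_cost:
            best_cost, best_mask = cost, mask
    return best_mask


def _recursive_ncut(coords, aff, config: SegmentationConfig, rng) -> list:
    """Recursively split one connected component; returns index groups."""
    n = aff.shape[0]
    if n < 2 * config.min_molecules:
        return [np.arange(n)]
    mask = _best_spectral_cut(aff)
    if mask is None:
        return [np.arange(n)]
    size_a, size_b = int(mask.sum()), int((~mask).sum())
    if min(size_a, size_b) < config.min_molecules:
        return [np.arange(n)]
    cost = _ncut_cost(aff, mask)
    if cost >= _bulk_reference_cost(coords, config, rng):
        return [np.arange(n)]
    idx = np.arange(n)
    out = []
    for part in (idx[mask], idx[~mask]):
        sub = aff[part][:, part]
        for piece in _recursive_ncut(coords[part], sub, config, rng):
            out.append(part[piece])
    return out


_BULK_CACHE: dict = {}


def _bulk_reference_cost(coords, config: SegmentationConfig, rng) -> float:
    """Expected normalized-cut cost of a homogeneous uniform point set.

    Monte-Carlo calibration: uniform points at the same count and density as
    the cluster under consideration, same kernel and cutoff; the mean best
    sweep-cut cost over a few draws is the acceptance threshold.
    """
    n = coords.shape[0]
    span = coords.max(axis=0) - coords.min(axis=0)
    area = max(float(np.prod(np.maximum(span, config.distance_scale))), 1e-12)
    density = n / area
    key = (
        int(np.round(np.log2(max(n, 2)))),
        int(np.round(np.log2(max(density, 1e-12)))),
        round(config.distance_scale, 6),
    )
    if key in _BULK_CACHE:
        return _BULK_CACHE[key]
    side = np.sqrt(n / density)
    costs = []
    for _ in range(3):
        pts = rng.random((n, 2)) * side
        d = sparse_spatial_distances(pts, config.max_distance)
        a = d.copy()
        a.data = np.exp(-0.5 * (a.data / config.distance_scale) ** 2)
        n_comp, labels = connected_components(a, directed=False)
        if n_comp > 1:  # bulk graph should be connected; keep largest
            main = np.flatnonzero(labels == np.bincount(labels).argmax())
            a = a[main][:, main]
        mask = _best_spectral_cut(a)
        if mask is not None:
            costs.append(_ncut_cost(a, mask))
    threshold = float(np.mean(costs)) if costs else np.inf
    _BULK_CACHE[key] = threshold
    return threshold


def pool_segments(
    mol: MoleculeTable, min_molecules: int = 20
) -> tuple[CountMatrix, pd.Series]:
    """Pool gene counts and modal category per segment.

    Segments with fewer than ``min_molecules`` molecules are excluded.
    Pooling is independent of molecule order.
    """
    if "segment_id" not in mol.frame.columns:
        raise ValueError("molecules must carry a segment_id column")
    df = mol.frame
    sizes = df.groupby("segment_id").size()
    keep = sizes[sizes >= min_molecules].index
    genes = sorted(set(df["gene"]))
    seg_ids = sorted(keep.tolist())
    seg_pos = pd.Index(seg_ids).get_indexer(df["segment_id"])
    gene_pos = pd.Index(genes).get_indexer(df["gene"])
    ok = seg_pos >= 0
    counts = sp.csr_matrix(
        (np.ones(int(ok.sum())), (seg_pos[ok], gene_pos[ok])),
        shape=(len(seg_ids), len(genes)),
    )
    modal = (
        df.loc[ok.nonzero()[0] if isinstance(ok, np.ndarray) else ok]
        .groupby("segment_id")["category"]
        .agg(lambda s: s.value_counts().idxmax())
        .reindex(seg_ids)
        if "category" in df.columns
        else pd.Series(index=seg_ids, dtype=object)
    )
    pooled = CountMatrix([f"seg{s}" for s in seg_ids], genes, counts)
    return pooled, modal
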