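"""Shared domain containers, file I/O and count preprocessing.

All count data are kept observation-major: rows are observations (cells,
beads, bins), columns are genes.  Category-by-observation orientations used
by the transport solver are views derived from these containers.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

__all__ = [
    "CountMatrix",
    "CategoricalAnnotation",
    "ReferenceProfiles",
    "CompositionMatrix",
    "SpatialPositions",
    "MoleculeTable",
    "read_count_matrix",
    "write_count_matrix",
    "mean_profiles",
    "log1p_normalize",
    "intersect_genes",
]


def _check_unique(ids, what: str) -> list:
    ids = list(map(str, ids))
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")
    return ids


@dataclass
class CountMatrix:
    """Sparse non-negative observation x gene count matrix."""

    obs_ids: list
    gene_ids: list
    values: sp.csr_matrix

    def __post_init__(self):
        self.obs_ids = _check_unique(self.obs_ids, "observation")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        values = sp.csr_matrix(self.values, dtype=np.float64)
        if values.shape != (len(self.obs_ids), len(self.gene_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match id lists "
                f"({len(self.obs_ids)}, {len(self.gene_ids)})"
            )
        if values.nnz and values.data.min() < 0:
            raise ValueError("negative entries in count matrix")
        self.values = values

    @property
    def shape(self):
        return self.values.shape

    def obs_totals(self) -> np.ndarray:
        """Total counts per observation (rho_b)."""
        return np.asarray(self.values.sum(axis=1)).ravel()

    def gene_totals(self) -> np.ndarray:
        """Pseudobulk counts per gene (rho_g)."""
        return np.asarray(self.values.sum(axis=0)).ravel()

    def subset_genes(self, genes) -> "CountMatrix":
        idx = pd.Index(self.gene_ids).get_indexer(genes)
        if (idx < 0).any():
            raise KeyError("unknown gene ids")
        return CountMatrix(self.obs_ids, list(genes), self.values[:, idx])

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


@dataclass
class CategoricalAnnotation:
    """One category label per observation."""

    obs_ids: list
    labels: list

    def __post_init__(self):
        self.obs_ids = _check_unique(self.obs_ids, "observation")
        self.labels = list(map(str, self.labels))
        if len(self.labels) != len(self.obs_ids):
            raise ValueError("labels and obs_ids differ in length")

    @property
    def categories(self) -> list:
        return sorted(set(self.labels))

    def as_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.obs_ids)

    def reindex(self, obs_ids) -> "CategoricalAnnotation":
        s = self.as_series().reindex(list(map(str, obs_ids)))
        if s.isna().any():
            raise KeyError("annotation missing for some observations")
        return CategoricalAnnotation(list(s.index), list(s.values))


@dataclass
class ReferenceProfiles:
    """Per-category expression profiles pi_gt with unit column sums.

    ``profiles`` is stored genes x categories.  ``parent_map`` maps
    sub-category ids to parent categories when profiles come from
    within-category subclustering.
    """

    category_ids: list
    gene_ids: list
    profiles: np.ndarray
    parent_map: dict | None = None
    category_weights: np.ndarray | None = None  # prior mass per category

    def __post_init__(self):
        self.category_ids = _check_unique(self.category_ids, "category")
        self.gene_ids = _check_unique(self.gene_ids, "gene")
        profiles = np.asarray(self.profiles, dtype=np.float64)
        if profiles.shape != (len(self.gene_ids), len(self.category_ids)):
            raise ValueError("profile matrix shape mismatch")
        if profiles.min() < 0:
            raise ValueError("negative profile entries")
        colsums = profiles.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-9):
            raise ValueError("profile columns must sum to 1")
        self.profiles = profiles
        if self.category_weights is not None:
            w = np.asarray(self.category_weights, dtype=np.float64)
            if w.shape != (len(self.category_ids),) or (w < 0).any() or w.sum() <= 0:
                raise ValueError("invalid category weights")
            self.category_weights = w / w.sum()

    def parents(self) -> list:
        if self.parent_map is None:
            return list(self.category_ids)
        return [self.parent_map[c] for c in self.category_ids]

    def subset_genes(self, genes) -> "ReferenceProfiles":
        idx = pd.Index(self.gene_ids).get_indexer(genes)
        if (idx < 0).any():
            raise KeyError("unknown gene ids")
        sub = self.profiles[idx, :]
        colsums = sub.sum(axis=0)
        colsums[colsums == 0] = 1.0
        return ReferenceProfiles(
            self.category_ids,
            list(genes),
            sub / colsums,
            self.parent_map,
            self.category_weights,
        )


@dataclass
class CompositionMatrix:
    """Observation x category annotation weights rho_tb.

    ``units`` is either ``"probability"`` (rows sum to 1) or ``"counts"``.
    """

    obs_ids: list
    category_ids: list
    weights: np.ndarray
    units: str = "probability"

    def __post_init__(self):
        self.obs_ids = _check_unique(self.obs_ids, "observation")
        self.category_ids = _check_unique(self.category_ids, "category")
        w = np.asarray(self.weights, dtype=np.float64)
        if w.shape != (len(self.obs_ids), len(self.category_ids)):
            raise ValueError("weight matrix shape mismatch")
        if w.min() < -1e-12:
            raise ValueError("negative composition weights")
        w = np.clip(w, 0.0, None)
        if self.units == "probability":
            rowsums = w.sum(axis=1)
            if not np.allclose(rowsums[rowsums > 0], 1.0, atol=1e-6):
                raise ValueError("probability rows must sum to 1")
        elif self.units != "counts":
            raise ValueError(f"unknown units {self.units!r}")
        self.weights = w

    def to_probability(self) -> "CompositionMatrix":
        if self.units == "probability":
            return self
        rowsums = self.weights.sum(axis=1, keepdims=True)
        rowsums[rowsums == 0] = 1.0
        return CompositionMatrix(
            self.obs_ids, self.category_ids, self.weights / rowsums, "probability"
        )

    def to_counts(self, obs_totals: np.ndarray) -> "CompositionMatrix":
        p = self.to_probability()
        return CompositionMatrix(
            p.obs_ids,
            p.category_ids,
            p.weights * np.asarray(obs_totals)[:, None],
            "counts",
        )

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights, index=self.obs_ids, columns=self.category_ids
        )

    def argmax_labels(self) -> CategoricalAnnotation:
        """Categorical view: the maximum-weight category per observation.

        Ties break toward the lexicographically smallest category id because
        the category axis is scanned in sorted storage order.
        """
        order = np.argsort(self.category_ids)
        w = self.weights[:, order]
        cats = np.asarray(self.category_ids)[order]
        return CategoricalAnnotation(self.obs_ids, cats[np.argmax(w, axis=1)])


@dataclass
class SpatialPositions:
    """Per-observation spatial coordinates in micrometres (2D or 3D)."""

    obs_ids: list
    coords: np.ndarray

    def __post_init__(self):
        self.obs_ids = _check_unique(self.obs_ids, "observation")
        coords = np.atleast_2d(np.asarray(self.coords, dtype=np.float64))
        if coords.shape[0] != len(self.obs_ids):
            raise ValueError("coords/obs_ids length mismatch")
        if coords.shape[1] not in (2, 3):
            raise ValueError("coordinates must be 2- or 3-dimensional")
        if not np.isfinite(coords).all():
            raise ValueError("non-finite coordinates")
        self.coords = coords


@dataclass
class MoleculeTable:
    """Per-molecule table: x, y (um), gene, optional category / segment_id."""

    frame: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self):
        df = pd.DataFrame(self.frame).copy()
        for col in ("x", "y", "gene"):
            if col not in df.columns:
                raise ValueError(f"molecule table lacks required column {col!r}")
        if not np.isfinite(df[["x", "y"]].to_numpy(dtype=float)).all():
            raise ValueError("non-finite molecule coordinates")
        df["gene"] = df["gene"].astype(str)
        self.frame = df.reset_index(drop=True)

    def __len__(self):
        return len(self.frame)

    @property
    def coords(self) -> np.ndarray:
        return self.frame[["x", "y"]].to_numpy(dtype=float)

    @property
    def genes(self) -> np.ndarray:
        return self.frame["gene"].to_numpy()


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_count_matrix(path: str) -> CountMatrix:
    """Read a count matrix from a MatrixMarket triplet directory or a CSV.

    A directory must contain ``matrix.mtx`` (genes x obs or obs x genes —
    disambiguated by the label files), ``barcodes.tsv`` (observations) and
    ``features.tsv`` / ``genes.tsv`` (genes).  A CSV is read dense with a
    header row of genes and an index column of observation ids.
    """
    if os.path.isdir(path):
        mtx_path = os.path.join(path, "matrix.mtx")
        bc_path = os.path.join(path, "barcodes.tsv")
        ft_path = os.path.join(path, "features.tsv")
        if not os.path.exists(ft_path):
            ft_path = os.path.join(path, "genes.tsv")
        for p in (mtx_path, bc_path, ft_path):
            if not os.path.exists(p):
                raise FileNotFoundError(f"missing file for MTX triplet: {p}")
        mat = sp.csr_matrix(mmread(mtx_path))
        obs = pd.read_csv(bc_path, header=None, sep="\t")[0].astype(str).tolist()
        genes = pd.read_csv(ft_path, header=None, sep="\t")[0].astype(str).tolist()
        if mat.shape == (len(genes), len(obs)) and mat.shape[0] != mat.shape[1]:
            mat = mat.T.tocsr()
        if mat.shape != (len(obs), len(genes)):
            raise ValueError("MTX shape does not match label files")
        return CountMatrix(obs, genes, mat)
    df = pd.read_csv(path, index_col=0)
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("non-numeric entries in count CSV")
    if (values < 0).any():
        raise ValueError("negative entries in count CSV")
    return CountMatrix(
        df.index.astype(str).tolist(),
        df.columns.astype(str).tolist(),
        sp.csr_matrix(values),
    )


def write_count_matrix(counts: CountMatrix, path: str, fmt: str = "mtx") -> None:
    """Write counts as an MTX triplet directory (default) or a dense CSV."""
    if fmt == "mtx":
        os.makedirs(path, exist_ok=True)
        coo = counts.values.tocoo()
        if np.allclose(coo.data, np.round(coo.data)):
            coo = coo.astype(np.int64)
        mmwrite(os.path.join(path, "matrix.mtx"), coo)
        pd.Series(counts.obs_ids).to_csv(
            os.path.join(path, "barcodes.tsv"), index=False, header=False
        )
        pd.Series(counts.gene_ids).to_csv(
            os.path.join(path, "features.tsv"), index=False, header=False
        )
    elif fmt == "csv":
        pd.DataFrame(
            counts.to_dense(), index=counts.obs_ids, columns=counts.gene_ids
        ).to_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def mean_profiles(
    counts: CountMatrix, anno: CategoricalAnnotation
) -> ReferenceProfiles:
    """Column-normalized mean raw-count profile per annotation category.

    Means are taken on raw counts, then normalized to unit sum, keeping the
    bookkeeping in count units.
    """
    anno = anno.reindex(counts.obs_ids)
    labels = np.asarray(anno.labels)
    categories = sorted(set(labels))
    profiles = np.zeros((len(counts.gene_ids), len(categories)))
    for j, cat in enumerate(categories):
        mask = labels == cat
        if not mask.any():
            raise ValueError(f"empty category {cat!r}")
        mean = np.asarray(counts.values[mask].mean(axis=0)).ravel()
        total = mean.sum()
        if total == 0:
            raise ValueError(f"category {cat!r} has all-zero mean profile")
        profiles[:, j] = mean / total
    sizes = np.array([(labels == cat).sum() for cat in categories], dtype=float)
    return ReferenceProfiles(
        categories, counts.gene_ids, profiles, category_weights=sizes / sizes.sum()
    )


def log1p_normalize(counts, scale: float = 1e4) -> np.ndarray:
    """Scale each row to a total of ``scale`` then apply log(1 + x).

    Zero rows stay zero.  Accepts a CountMatrix, sparse or dense array;
    returns a dense array.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    values = counts.values if isinstance(counts, CountMatrix) else counts
    if sp.issparse(values):
        values = np.asarray(values.todense())
    else:
        values = np.asarray(values, dtype=np.float64)
    totals = values.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(values / totals * scale)


def intersect_genes(
    data: CountMatrix, other
) -> tuple:
    """Restrict two gene-indexed objects to their shared gene space.

    Genes present in only one of the two are dropped with a warning, since
    annotation transfer requires overlapping feature spaces.
    """
    shared = [g for g in data.gene_ids if g in set(other.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between data and reference")
    n_dropped = (len(data.gene_ids) - len(shared)) + (
        len(other.gene_ids) - len(shared)
    )
    if n_dropped:
        warnings.warn(
            f"dropping {n_dropped} genes not shared between data and reference"
        )
    return data.subset_genes(shared), other.subset_genes(shared)
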