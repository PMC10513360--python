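"""Synthetic-data generators for benchmarking the annotation pipeline.

Four generators cover the benchmark conditions:

* ``simulate_scrnaseq`` — Splatter-style scRNA-seq counts: gamma gene means,
  log-normal per-type differential-expression factors on a random gene
  subset, log-normal library sizes, Poisson sampling.
* ``apply_dropout`` — extra dropout from a sigmoid of log mean expression,
  shifted toward higher expression, applied by binomial thinning.
* ``add_ambient`` — negative-binomial counts with an additive ambient-RNA
  profile scaled per droplet.
* ``simulate_mixtures`` — Slide-seq-like beads as Gaussian-kernel mixtures
  of reference cells on a torus.
* ``simulate_fate_data`` — a clonal-fate dataset where early progenitors are
  mixtures of late fate profiles.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .data import CategoricalAnnotation, CompositionMatrix, CountMatrix

__all__ = [
    "MixtureSimParams",
    "ScsimParams",
    "DropoutParams",
    "AmbientParams",
    "simulate_mixtures",
    "simulate_scrnaseq",
    "type_profiles",
    "apply_dropout",
    "add_ambient",
    "simulate_fate_data",
]


@dataclass
class MixtureSimParams:
    """Bead-mixture simulation parameters.

    ``bead_size`` is dimensionless relative to the mean cell spacing; the
    Gaussian kernel width is l = bead_size / 2 * sqrt(1 / n_cells) on the
    unit torus.  ``capture_rate`` r is the fraction of a cell's counts
    captured by a bead at distance zero.
    """

    n_beads: int = 1000
    bead_size: float = 1.0
    capture_rate: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.bead_size <= 0:
            raise ValueError("bead_size must be positive")
        if not 0 < self.capture_rate <= 1:
            raise ValueError("capture_rate must be in (0, 1]")


@dataclass
class ScsimParams:
    """Splatter-style scRNA-seq generative parameters.

    Gene base means follow Gamma(mean_shape, mean_scale); per-type DE factors
    are LogNormal(de_loc, de_scale) applied to a de_prob fraction of genes
    (reciprocal with probability de_downprob); library sizes follow
    LogNormal(lib_loc, lib_scale); counts are Poisson.
    """

    n_cells: int = 1000
    n_genes: int = 10000
    n_types: int = 10
    de_loc: float = 5.0
    de_scale: float = 1.0
    de_prob: float = 0.025
    de_downprob: float = 0.0
    mean_shape: float = 0.34
    mean_scale: float = 0.13
    lib_loc: float = 7.64
    lib_scale: float = 0.78
    bcv_dispersion: float = 0.448
    bcv_dof: float = 22.087
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 2:
            raise ValueError("need at least two types")


@dataclass
class DropoutParams:
    """Dropout-enhancement parameters.

    ``midpoint_shift`` moves the fitted dropout sigmoid along the log-mean
    axis; negative values push the curve toward higher expression, i.e.
    enhance dropout (shift -1 is the mild setting of the dropout benchmark).
    """

    midpoint_shift: float = -1.0
    mode: str = "binomial"  # or "bernoulli": zero out whole entries
    seed: int = 0


@dataclass
class AmbientParams:
    """Ambient-RNA contamination parameters (droplet NB model).

    ``f_drop`` scales the per-droplet ambient contribution relative to the
    cell-size log-normal; ``phi`` is the NB dispersion (var = mu + phi mu^2).
    """

    f_drop: float = 0.1
    d_mu: float = 7.64
    d_sigma: float = 0.78
    phi: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.f_drop < 0:
            raise ValueError("f_drop must be >= 0")
        if self.phi <= 0:
            raise ValueError("phi must be positive")


# ---------------------------------------------------------------------------
# scRNA-seq counts
# ---------------------------------------------------------------------------

def _type_profiles(params: ScsimParams, rng: np.random.Generator) -> np.ndarray:
    """Relative expression profile per type (genes x types, columns sum 1)."""
    base = rng.gamma(params.mean_shape, params.mean_scale, size=params.n_genes)
    base = np.maximum(base, 1e-12)
    profiles = np.empty((params.n_genes, params.n_types))
    for t in range(params.n_types):
        de_mask = rng.random(params.n_genes) < params.de_prob
        factors = np.ones(params.n_genes)
        n_de = int(de_mask.sum())
        if n_de:
            f = rng.lognormal(params.de_loc, params.de_scale, size=n_de)
            down = rng.random(n_de) < params.de_downprob
            f[down] = 1.0 / f[down]
            factors[de_mask] = f
        prof = base * factors
        profiles[:, t] = prof / prof.sum()
    return profiles


def type_profiles(params: ScsimParams) -> np.ndarray:
    """The generative relative expression profiles implied by the seed."""
    return _type_profiles(params, np.random.default_rng(params.seed))


def simulate_scrnaseq(
    params: ScsimParams,
    profiles: np.ndarray | None = None,
) -> tuple[CountMatrix, CategoricalAnnotation, np.ndarray]:
    """Simulate typed scRNA-seq counts; returns (counts, types, mean matrix).

    The returned dense matrix holds the Poisson means lambda_ng (cell size
    times relative type profile) for reuse by the ambient-RNA generator.
    Passing ``profiles`` (genes x types, e.g. from another draw of the same
    generative model) samples new cells from those shared type profiles, as
    needed for reference/test pairs from one generative model.
    """
    rng = np.random.default_rng(params.seed)
    if profiles is None:
        profiles = _type_profiles(params, rng)
    elif profiles.shape != (params.n_genes, params.n_types):
        raise ValueError("profiles shape does not match params")
    types = rng.integers(0, params.n_types, size=params.n_cells)
    lib = rng.lognormal(params.lib_loc, params.lib_scale, size=params.n_cells)
    if params.bcv_dispersion > 0:
        # biological coefficient of variation: per-entry gamma noise whose
        # scale shrinks with the mean, gene-wise chi-square mixed
        chi_factor = np.sqrt(params.bcv_dof / rng.chisquare(params.bcv_dof, params.n_genes))
    else:
        chi_factor = None
    chunks = []
    lam_parts = []
    step = 2048  # bound peak memory on large simulations
    for lo in range(0, params.n_cells, step):
        hi = min(lo + step, params.n_cells)
        lam = lib[lo:hi, None] * profiles[:, types[lo:hi]].T  # cells x genes
        if chi_factor is not None:
            bcv = (
                params.bcv_dispersion + 1.0 / np.sqrt(np.maximum(lam, 1e-12))
            ) * chi_factor[None, :]
            lam = rng.gamma(shape=1.0 / bcv**2, scale=lam * bcv**2)
        chunks.append(sp.csr_matrix(rng.poisson(lam).astype(np.float64)))
        lam_parts.append(lam)
    counts = sp.vstack(chunks).tocsr()
    lam = np.vstack(lam_parts)
    obs = [f"cell{i}" for i in range(params.n_cells)]
    genes = [f"g{j}" for j in range(params.n_genes)]
    labels = [f"T{t}" for t in types]
    return (
        CountMatrix(obs, genes, counts),
        CategoricalAnnotation(obs, labels),
        lam,
    )


# ---------------------------------------------------------------------------
# dropout
# ---------------------------------------------------------------------------

def _dropout_sigmoid(x, shape, mid):
    return 1.0 / (1.0 + np.exp(shape * (x - mid)))


def fit_dropout_sigmoid(counts: CountMatrix) -> tuple[float, float]:
    """Fit zero fraction vs log mean count with a decreasing sigmoid.

    Returns (shape, midpoint) of p0(x) = 1 / (1 + exp(shape (x - mid))).
    Genes with zero mean are excluded from the fit.
    """
    dense = counts.values
    means = np.asarray(dense.mean(axis=0)).ravel()
    zero_frac = 1.0 - np.asarray((dense > 0).mean(axis=0)).ravel()
    ok = means > 0
    if ok.sum() < 3:
        raise ValueError("too few expressed genes to fit the dropout sigmoid")
    x = np.log(means[ok])
    y = zero_frac[ok]
    p0 = (1.0, float(np.median(x)))
    try:
        popt, _ = curve_fit(_dropout_sigmoid, x, y, p0=p0, maxfev=10000)
    except RuntimeError:
        popt = p0
    shape, mid = float(popt[0]), float(popt[1])
    if shape < 0:  # enforce the decreasing orientation
        shape, mid = abs(shape), mid
    return shape, mid


def apply_dropout(
    counts: CountMatrix,
    params: DropoutParams,
    means: np.ndarray | None = None,
) -> CountMatrix:
    """Thin counts with gene-wise extra dropout from a shifted sigmoid.

    The sigmoid p0 is fitted to (log mean count, zero fraction); shifting it
    by ``midpoint_shift`` (negative = toward higher expression = harsher)
    gives p1, and the extra dropout per gene is
    q_g = clip((p1 - p0) / (1 - p0), 0, 1).  Each count is then thinned
    binomially with retention 1 - q_g (or the whole entry zeroed with
    probability q_g in 'bernoulli' mode).
    """
    rng = np.random.default_rng(params.seed)
    shape, mid = fit_dropout_sigmoid(counts)
    if means is None:
        means = np.asarray(counts.values.mean(axis=0)).ravel()
    means = np.asarray(means, dtype=float)
    if means.ndim == 2:
        means = means.mean(axis=0)
    with np.errstate(divide="ignore"):
        x = np.where(means > 0, np.log(np.maximum(means, 1e-300)), -np.inf)
    p0 = _dropout_sigmoid(x, shape, mid)
    p1 = _dropout_sigmoid(x, shape, mid - params.midpoint_shift)
    q = np.clip((p1 - p0) / np.maximum(1.0 - p0, 1e-12), 0.0, 1.0)
    q[~np.isfinite(x)] = 0.0  # all-zero genes have nothing to drop
    out = counts.values.tocoo(copy=True)
    keep = 1.0 - q[out.col]
    if params.mode == "binomial":
        out.data = rng.binomial(out.data.astype(np.int64), keep).astype(np.float64)
    elif params.mode == "bernoulli":
        out.data = out.data * (rng.random(out.data.size) < keep)
    else:
        raise ValueError(f"unknown dropout mode {params.mode!r}")
    out.eliminate_zeros()
    return CountMatrix(counts.obs_ids, counts.gene_ids, out.tocsr())


# ---------------------------------------------------------------------------
# ambient RNA
# ---------------------------------------------------------------------------

def add_ambient(lam: np.ndarray, params: AmbientParams) -> CountMatrix:
    """Sample NB counts with a per-droplet ambient contribution.

    C_ng ~ NB(lambda_ng + d_n^drop * a_g, phi) where a_g is the ambient
    profile (the mean of lambda over cells, normalized to unit sum) and
    d_n^drop ~ LogNormal(d_mu + log f_drop, d_sigma).  With f_drop = 0 this
    reduces to plain NB noise around lambda.
    """
    rng = np.random.default_rng(params.seed)
    lam = np.asarray(lam, dtype=np.float64)
    n_cells, n_genes = lam.shape
    ambient = lam.mean(axis=0)
    total = ambient.sum()
    ambient = ambient / total if total > 0 else ambient
    if params.f_drop > 0:
        d_drop = rng.lognormal(
            params.d_mu + np.log(params.f_drop), params.d_sigma, size=n_cells
        )
        mu = lam + d_drop[:, None] * ambient[None, :]
    else:
        mu = lam
    n = 1.0 / params.phi
    p = n / (n + mu)
    counts = sp.csr_matrix(rng.negative_binomial(n, p).astype(np.float64))
    obs = [f"cell{i}" for i in range(n_cells)]
    genes = [f"g{j}" for j in range(n_genes)]
    return CountMatrix(obs, genes, counts)


# ---------------------------------------------------------------------------
# bead mixtures on a torus
# ---------------------------------------------------------------------------

def simulate_mixtures(
    ref_counts: CountMatrix,
    ref_anno: CategoricalAnnotation,
    params: MixtureSimParams,
) -> tuple[CountMatrix, CompositionMatrix, CompositionMatrix, np.ndarray]:
    """Mix reference cells into beads with Gaussian weights on a torus.

    Cells and beads are placed uniformly on the unit square with periodic
    boundary conditions.  Cell c contributes to bead b with weight
    w_cb = r exp(-(d_cb / l)^2 / 2) where d is the torus distance and
    l = bead_size / 2 * sqrt(1 / n_cells).  Every count of a cell is
    allocated among (beads..., uncaptured) by a single multinomial draw per
    gene, so counts are conserved.  Returns the bead counts, the
    cell-number-fraction truth, the count-fraction truth and bead positions.
    """
    if len(ref_counts.obs_ids) == 0:
        raise ValueError("empty reference")
    rng = np.random.default_rng(params.seed)
    ref_anno = ref_anno.reindex(ref_counts.obs_ids)
    n_cells = len(ref_counts.obs_ids)
    n_beads = params.n_beads
    cell_pos = rng.random((n_cells, 2))
    bead_pos = rng.random((n_beads, 2))
    l = 0.5 * params.bead_size * np.sqrt(1.0 / n_cells)
    cutoff = min(6.0 * l, 0.5)  # weights below ~1e-8 r are negligible
    tree = cKDTree(bead_pos, boxsize=1.0)
    neighbors = tree.query_ball_point(cell_pos, cutoff)

    categories = sorted(set(ref_anno.labels))
    cat_idx = {c: j for j, c in enumerate(categories)}
    labels = np.asarray(ref_anno.labels)
    cell_truth = np.zeros((n_beads, len(categories)))
    count_truth = np.zeros((n_beads, len(categories)))
    bead_rows, bead_cols, bead_vals = [], [], []
    X = ref_counts.values.tocsr()
    for c in range(n_cells):
        beads = np.asarray(neighbors[c], dtype=int)
        t = cat_idx[labels[c]]
        if beads.size == 0:
            continue
        delta = np.abs(bead_pos[beads] - cell_pos[c])
        delta = np.minimum(delta, 1.0 - delta)
        d = np.hypot(delta[:, 0], delta[:, 1])
        w = params.capture_rate * np.exp(-0.5 * (d / l) ** 2)
        wsum = w.sum()
        if wsum > 1.0:
            w = w / wsum
            wsum = 1.0
        cell_truth[beads, t] += w
        p = np.append(w, 1.0 - wsum)  # last slot: uncaptured
        row = X.getrow(c)
        for g, k in zip(row.indices, row.data.astype(np.int64)):
            alloc = rng.multinomial(k, p)[:-1]
            bz = np.flatnonzero(alloc)
            if bz.size:
                bead_rows.extend(beads[bz].tolist())
                bead_cols.extend([g] * bz.size)
                bead_vals.extend(alloc[bz].tolist())
                count_truth[beads[bz], t] += alloc[bz]
    bead_counts = sp.csr_matrix(
        (bead_vals, (bead_rows, bead_cols)),
        shape=(n_beads, len(ref_counts.gene_ids)),
    )
    bead_ids = [f"bead{i}" for i in range(n_beads)]

    def _normalize(mat):
        rowsums = mat.sum(axis=1, keepdims=True)
        out = np.divide(mat, rowsums, out=np.zeros_like(mat), where=rowsums > 0)
        return CompositionMatrix(bead_ids, categories, out, "probability")

    return (
        CountMatrix(bead_ids, ref_counts.gene_ids, bead_counts),
        _normalize(cell_truth),
        _normalize(count_truth),
        bead_pos,
    )


# ---------------------------------------------------------------------------
# clonal fate data
# ---------------------------------------------------------------------------

def simulate_fate_data(
    n_fates: int = 4,
    n_clones: int = 100,
    cells_per_clone: int = 4,
    mixing_kernel: float | np.ndarray = 1.0,
    seed: int = 0,
    scsim_params: ScsimParams | None = None,
) -> tuple[
    CountMatrix,
    CategoricalAnnotation,
    CountMatrix,
    np.ndarray,
    CompositionMatrix,
]:
    """Clonal-fate dataset: late pure fates, early bias-weighted mixtures.

    Fate expression profiles come from the scRNA-seq generator.  Each clone
    draws a Dirichlet(``mixing_kernel``) fate bias; its early cells' Poisson
    means are the bias-weighted convex combination of the fate mean profiles.
    Returns (late counts, late fate labels, early counts, early clone ids,
    truth per-early-cell fate bias), truth rows summing to 1.
    """
    if n_fates < 2:
        raise ValueError("need at least two fates")
    if scsim_params is None:
        scsim_params = ScsimParams(
            n_cells=n_fates * 200, n_genes=1000, n_types=n_fates, seed=seed
        )
    else:
        scsim_params = ScsimParams(**{**scsim_params.__dict__, "n_types": n_fates})
    late_counts, late_labels, _ = simulate_scrnaseq(scsim_params)
    rng = np.random.default_rng((seed, 1))
    profiles = _type_profiles(scsim_params, np.random.default_rng(scsim_params.seed))

    alpha = np.broadcast_to(np.asarray(mixing_kernel, dtype=float), (n_fates,))
    biases = rng.dirichlet(alpha, size=n_clones)
    n_early = n_clones * cells_per_clone
    clone_ids = np.repeat(np.arange(n_clones), cells_per_clone)
    lib = rng.lognormal(scsim_params.lib_loc, scsim_params.lib_scale, size=n_early)
    mean_early = (biases[clone_ids] @ profiles.T) * lib[:, None]
    early = sp.csr_matrix(rng.poisson(mean_early).astype(np.float64))
    early_ids = [f"early{i}" for i in range(n_early)]
    genes = late_counts.gene_ids
    fates = [f"T{t}" for t in range(n_fates)]
    truth = CompositionMatrix(early_ids, fates, biases[clone_ids], "probability")
    return (
        late_counts,
        late_labels,
        CountMatrix(early_ids, genes, early),
        clone_ids,
        truth,
    )
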