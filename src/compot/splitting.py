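"""Split compositionally annotated counts into pure per-category counts.

Data generation is modeled as drawing molecules with joint probability
p(g, t, b) over gene, category and observation.  The measured counts fix the
gene marginal per observation and the annotation fixes the category
marginal, so for each observation a matrix equivalence scaling (RAS /
iterative proportional fitting) problem is solved on the reference profile
matrix p(g|t): scale rows and columns until both marginals match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .data import CompositionMatrix, CountMatrix, ReferenceProfiles

__all__ = ["SplitCounts", "split_observation", "split_counts"]

_RAS_MAX_ITER = 1000
_RAS_TOL = 1e-8


@dataclass
class SplitCounts:
    """Per-category stack of count matrices sharing obs/gene ids."""

    obs_ids: list
    gene_ids: list
    category_ids: list
    matrices: dict  # category id -> csr_matrix (obs x genes)

    def total(self) -> sp.csr_matrix:
        out = None
        for m in self.matrices.values():
            out = m if out is None else out + m
        return out


def split_observation(
    counts_row: np.ndarray,
    composition_row: np.ndarray,
    profiles: np.ndarray,
    pseudocount: float | None = None,
) -> np.ndarray:
    """RAS-scale the profile matrix to the marginals of one observation.

    ``counts_row`` (per-gene counts) is the gene marginal, ``composition_row``
    times the total counts is the category marginal, and ``profiles`` is the
    genes x categories matrix p(g|t).  Returns the scaled joint (genes x
    categories) whose marginals match within 1e-8 relative.
    """
    counts_row = np.asarray(counts_row, dtype=np.float64)
    composition_row = np.asarray(composition_row, dtype=np.float64)
    total = counts_row.sum()
    if total == 0:
        return np.zeros_like(profiles)
    col_target = composition_row / composition_row.sum() * total
    if pseudocount is None:
        pseudocount = 1e-12 * profiles.max()
    joint = profiles + pseudocount
    # restrict to genes with counts: zero-count rows scale to zero anyway
    nz = counts_row > 0
    sub = joint[nz, :].copy()
    row_target = counts_row[nz]
    converged = False
    for _ in range(_RAS_MAX_ITER):
        colsum = sub.sum(axis=0)
        sub *= np.where(colsum > 0, col_target / np.maximum(colsum, 1e-300), 0.0)
        rowsum = sub.sum(axis=1)
        sub *= np.where(
            rowsum > 0, row_target / np.maximum(rowsum, 1e-300), 0.0
        )[:, None]
        colsum = sub.sum(axis=0)
        err = np.abs(colsum - col_target).max() / max(total, 1e-300)
        if err < _RAS_TOL:
            converged = True
            break
    if not converged:
        warnings.warn(f"RAS did not converge; residual {err:.2e}")
    out = np.zeros_like(profiles)
    out[nz, :] = sub
    return out


def split_counts(
    counts: CountMatrix,
    composition: CompositionMatrix,
    profiles: ReferenceProfiles,
    round: bool = False,
    seed: int = 0,
) -> SplitCounts:
    """Split every observation's counts into per-category counts.

    One RAS problem is solved per observation (results are independent of
    the order).  With ``round=True`` every entry is floored and the per-gene
    leftover reads are assigned to categories by multinomial sampling with
    probabilities proportional to the fractional remainders, so per-gene
    totals per observation are conserved exactly.  The multinomial stream is
    seeded per observation from (seed, observation index), making the result
    reproducible under any execution order.
    """
    if list(counts.obs_ids) != list(composition.obs_ids):
        raise ValueError("counts and composition observations mismatch")
    comp = composition.to_probability()
    idx = [profiles.category_ids.index(c) for c in comp.category_ids]
    prof = profiles.profiles[:, idx]
    if list(profiles.gene_ids) != list(counts.gene_ids):
        raise ValueError("counts and profiles gene space mismatch")
    n_obs, n_genes = counts.shape
    cats = list(comp.category_ids)
    builders = {c: ([], [], []) for c in cats}  # rows, cols, vals
    X = counts.values.tocsr()
    for i in range(n_obs):
        row = X.getrow(i)
        if row.nnz == 0:
            continue
        dense_row = np.zeros(n_genes)
        dense_row[row.indices] = row.data
        joint = split_observation(dense_row, comp.weights[i], prof)
        if round:
            joint = _round_joint(joint, dense_row, np.random.default_rng((seed, i)))
        for j, c in enumerate(cats):
            gz = np.flatnonzero(joint[:, j])
            if gz.size:
                builders[c][0].extend([i] * gz.size)
                builders[c][1].extend(gz.tolist())
                builders[c][2].extend(joint[gz, j].tolist())
    matrices = {}
    for c in cats:
        rows, cols, vals = builders[c]
        matrices[c] = sp.csr_matrix(
            (vals, (rows, cols)), shape=(n_obs, n_genes)
        )
    return SplitCounts(counts.obs_ids, counts.gene_ids, cats, matrices)


def _round_joint(
    joint: np.ndarray, counts_row: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Floor and redistribute leftover reads per gene multinomially."""
    floored = np.floor(joint)
    remainder = joint - floored
    leftover = np.rint(counts_row - floored.sum(axis=1)).astype(int)
    out = floored
    for g in np.flatnonzero(leftover > 0):
        p = remainder[g]
        total_p = p.sum()
        if total_p <= 0:
            p = np.ones_like(p)
            total_p = p.sum()
        out[g] += rng.multinomial(leftover[g], p / total_p)
    return out
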