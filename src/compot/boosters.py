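"""Boosters around the transport core and the `annotate` orchestrator.

The core solver maps observations to category mean profiles.  Three generic
wrappers improve it for real data:

* platform normalization — gene-wise scaling factors between the target and
  reference platforms, estimated from the target pseudobulk;
* multi-center profiles — k-means subclustering within each category to
  represent within-category heterogeneity by several mean profiles;
* bisectioning — iterated annotation of residuals so that subdominant
  contributions of a mixture are not swallowed by the dominant category.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import KMeans

from .data import (
    CategoricalAnnotation,
    CompositionMatrix,
    CountMatrix,
    ReferenceProfiles,
    intersect_genes,
    log1p_normalize,
    mean_profiles,
)
from .ot import OTParams, cost_matrix, plan_to_composition, sinkhorn_semi_unbalanced

__all__ = [
    "AnnotateConfig",
    "platform_factors",
    "platform_normalize_iterative",
    "multi_center_split",
    "bisection_annotate",
    "annotate",
    "annotate_with_profiles",
]

_PSEUDOCOUNT = 1e-12


@dataclass
class AnnotateConfig:
    """Configuration of the full annotation pipeline.

    Defaults follow the study-wide configuration: epsilon 0.005, lambda 0.1,
    10 k-means centers per category, four bisection iterations with divisor
    three, and platform normalization enabled.
    """

    ot_params: OTParams = field(default_factory=OTParams)
    platform_normalize: bool = True
    platform_iterations: int = 1
    multi_center: int = 10
    bisections: int = 4
    bisection_divisor: int = 3
    max_annotation: int | None = None
    seed: int = 42


def platform_factors(
    profiles_B: ReferenceProfiles,
    target_bulk: np.ndarray,
    type_marginals: np.ndarray,
) -> np.ndarray:
    """Gene-wise platform factors f_g = rho^A_g / sum_t pi^B_gt rho^A_t.

    ``target_bulk`` are per-gene counts (or fractions) on the target
    platform A; ``type_marginals`` is the assumed category composition of
    the target.  A pseudocount keeps the denominator positive.
    """
    bulk = np.asarray(target_bulk, dtype=np.float64)
    if bulk.sum() <= 0:
        raise ValueError("all-zero target bulk")
    rho_g = bulk / bulk.sum()
    rho_t = np.asarray(type_marginals, dtype=np.float64)
    if (rho_t < 0).any():
        raise ValueError("negative type marginals")
    rho_t = rho_t / rho_t.sum()
    denom = profiles_B.profiles @ rho_t + _PSEUDOCOUNT
    return rho_g / denom


def _rescale_profiles(
    profiles: ReferenceProfiles, factors: np.ndarray
) -> ReferenceProfiles:
    scaled = profiles.profiles * factors[:, None]
    colsums = scaled.sum(axis=0)
    colsums[colsums == 0] = 1.0
    return ReferenceProfiles(
        profiles.category_ids,
        profiles.gene_ids,
        scaled / colsums,
        profiles.parent_map,
        profiles.category_weights,
    )


def multi_center_split(
    counts: CountMatrix,
    anno: CategoricalAnnotation,
    k: int,
    seed: int = 42,
) -> ReferenceProfiles:
    """Represent each category by up to ``k`` k-means sub-profiles.

    Cells of each category are clustered with k-means (k-means++ init, 10
    restarts) on log1p-normalized expression; each subcluster contributes a
    normalized mean raw-count profile.  ``parent_map`` records subprofile ->
    category; ``category_weights`` carry subcluster cell fractions for use
    as a transport prior.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    anno = anno.reindex(counts.obs_ids)
    if k == 1:
        base = mean_profiles(counts, anno)
        base.parent_map = {c: c for c in base.category_ids}
        return base
    labels = np.asarray(anno.labels)
    categories = sorted(set(labels))
    sub_ids, columns, parent_map, sizes = [], [], {}, []
    for cat in categories:
        mask = labels == cat
        sub = counts.values[mask]
        n = int(mask.sum())
        k_eff = min(k, n)
        if k_eff == 1:
            assign = np.zeros(n, dtype=int)
        else:
            feats = log1p_normalize(sub)
            km = KMeans(n_clusters=k_eff, n_init=10, random_state=seed)
            assign = km.fit_predict(feats)
        for j in range(k_eff):
            cmask = assign == j
            if not cmask.any():
                continue
            mean = np.asarray(sub[cmask].mean(axis=0)).ravel()
            if mean.sum() == 0:
                continue
            sid = f"{cat}::{len([s for s in sub_ids if parent_map.get(s) == cat])}"
            sub_ids.append(sid)
            parent_map[sid] = cat
            columns.append(mean / mean.sum())
            sizes.append(cmask.sum())
    profiles = np.column_stack(columns)
    sizes = np.asarray(sizes, dtype=float)
    return ReferenceProfiles(
        sub_ids, counts.gene_ids, profiles, parent_map, sizes / sizes.sum()
    )


def bisection_annotate(
    core_fn,
    data: CountMatrix,
    profiles: ReferenceProfiles,
    bisections: int = 4,
    divisor: int = 3,
) -> CompositionMatrix:
    """Iterated annotation of residual counts.

    In each of ``bisections`` rounds the core is run on the current residual
    and a fraction 1 / divisor of the residual's annotation is kept; the
    corresponding reconstruction (counts redistributed through the profiles)
    is subtracted from the residual, clipped at zero.  A larger divisor
    therefore takes finer steps and resolves subdominant contributions more
    precisely, at the cost of more iterations being useful.  A final core
    call assigns whatever fraction of each observation's counts is still
    unaccounted for, so accumulated count fractions sum to the original
    totals exactly.
    """
    if bisections < 0:
        raise ValueError("bisections must be >= 0")
    n_obs = len(data.obs_ids)
    n_cat = len(profiles.category_ids)
    totals = data.obs_totals()
    if bisections == 0:
        return core_fn(data)
    phi = 1.0 / divisor
    residual = data.to_dense()
    acc = np.zeros((n_obs, n_cat))
    assigned_mass = np.zeros(n_obs)
    for _ in range(bisections):
        if residual.sum() == 0:
            break
        comp = core_fn(CountMatrix(data.obs_ids, data.gene_ids, sp.csr_matrix(residual)))
        res_tot = residual.sum(axis=1)
        step = phi * np.minimum(res_tot, totals - assigned_mass)
        assigned = step[:, None] * comp.weights
        acc += assigned
        assigned_mass += step
        reconstruction = assigned @ profiles.profiles.T
        residual = np.clip(residual - reconstruction, 0.0, None)
    comp = core_fn(CountMatrix(data.obs_ids, data.gene_ids, sp.csr_matrix(residual)))
    remainder = np.maximum(totals - assigned_mass, 0.0)
    acc += remainder[:, None] * comp.weights
    out = np.zeros_like(acc)
    rowsums = acc.sum(axis=1)
    pos = rowsums > 0
    out[pos] = acc[pos] / rowsums[pos, None]
    if (~pos).any():
        out[~pos] = 1.0 / n_cat
    return CompositionMatrix(data.obs_ids, profiles.category_ids, out, "probability")


def _ot_core(profiles: ReferenceProfiles, params: OTParams, prior: np.ndarray):
    """Build a core annotation function for the given (rescaled) profiles."""

    def core(batch: CountMatrix) -> CompositionMatrix:
        totals = batch.obs_totals()
        nonzero = totals > 0
        n_cat = len(profiles.category_ids)
        weights = np.tile(prior / prior.sum(), (len(batch.obs_ids), 1))
        if nonzero.any():
            sub = CountMatrix(
                [batch.obs_ids[i] for i in np.flatnonzero(nonzero)],
                batch.gene_ids,
                batch.values[nonzero],
            )
            M = cost_matrix(profiles, sub, params.metric)
            c_b = totals[nonzero]
            c_t = prior / prior.sum() * c_b.sum()
            plan = sinkhorn_semi_unbalanced(
                M, c_b, c_t, params, profiles.category_ids, sub.obs_ids
            )
            weights[nonzero] = plan_to_composition(plan).weights
        return CompositionMatrix(
            batch.obs_ids, profiles.category_ids, weights, "probability"
        )

    return core


def _platform_loop(
    data: CountMatrix,
    profiles: ReferenceProfiles,
    config: AnnotateConfig,
) -> tuple[np.ndarray, np.ndarray, CompositionMatrix]:
    prior = (
        profiles.category_weights
        if profiles.category_weights is not None
        else np.full(len(profiles.category_ids), 1.0 / len(profiles.category_ids))
    )
    rho_t = np.asarray(prior, dtype=float)
    bulk = data.gene_totals()
    factors = None
    comp = None
    for _ in range(max(config.platform_iterations, 1)):
        new_factors = platform_factors(profiles, bulk, rho_t)
        if factors is not None:
            rel = np.abs(new_factors - factors) / np.maximum(np.abs(factors), 1e-12)
            if rel.max() < 1e-3:
                factors = new_factors
                break
        factors = new_factors
        scaled = _rescale_profiles(profiles, factors)
        comp = bisection_annotate(
            _ot_core(scaled, config.ot_params, rho_t),
            data,
            scaled,
            config.bisections,
            config.bisection_divisor,
        )
        mass = comp.weights * data.obs_totals()[:, None]
        rho_t = mass.sum(axis=0)
        if rho_t.sum() == 0:
            warnings.warn("degenerate type marginals during platform normalization")
            rho_t = np.asarray(prior, dtype=float)
        rho_t = rho_t / rho_t.sum()
    return factors, rho_t, comp


def platform_normalize_iterative(
    data: CountMatrix,
    profiles: ReferenceProfiles,
    config: AnnotateConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate platform factors jointly with the target type marginals.

    Starting from the reference category composition as prior, platform
    factors are computed, the reference profiles rescaled into target units,
    the data annotated and the type marginals updated; the loop stops when
    the factors change by less than 1e-3 (max relative change) or after
    ``platform_iterations`` passes.  Returns (factors, type marginals).
    """
    config = config or AnnotateConfig()
    factors, rho_t, _ = _platform_loop(data, profiles, config)
    return factors, rho_t


def _truncate_composition(weights: np.ndarray, max_annotation: int) -> np.ndarray:
    """Keep the top-k weights per row and renormalize to the simplex."""
    if max_annotation >= weights.shape[1]:
        return weights
    out = np.zeros_like(weights)
    idx = np.argsort(weights, axis=1)[:, ::-1][:, :max_annotation]
    rows = np.arange(weights.shape[0])[:, None]
    out[rows, idx] = weights[rows, idx]
    rowsums = out.sum(axis=1, keepdims=True)
    rowsums[rowsums == 0] = 1.0
    return out / rowsums


def annotate(
    data: CountMatrix,
    ref: CountMatrix,
    ref_anno: CategoricalAnnotation,
    config: AnnotateConfig | None = None,
) -> CompositionMatrix:
    """Compositional annotation of ``data`` from an annotated reference.

    Pipeline: gene intersection -> (multi-center) mean profiles -> platform
    normalization -> bisectioned semi-unbalanced entropic OT -> summation of
    sub-categories -> optional max_annotation truncation.  Rows of the
    returned composition sum to 1.
    """
    config = config or AnnotateConfig()
    data, ref = intersect_genes(data, ref)
    ref_anno = ref_anno.reindex(ref.obs_ids)
    if config.multi_center and config.multi_center > 1:
        profiles = multi_center_split(ref, ref_anno, config.multi_center, config.seed)
    else:
        profiles = multi_center_split(ref, ref_anno, 1, config.seed)
    return annotate_with_profiles(data, profiles, config)


def annotate_with_profiles(
    data: CountMatrix,
    profiles: ReferenceProfiles,
    config: AnnotateConfig | None = None,
) -> CompositionMatrix:
    """Annotate against pre-built (possibly sub-categorized) profiles."""
    config = config or AnnotateConfig()
    if list(data.gene_ids) != list(profiles.gene_ids):
        data, profiles = intersect_genes(data, profiles)

    if config.platform_normalize:
        _, _, comp = _platform_loop(data, profiles, config)
    else:
        prior = (
            profiles.category_weights
            if profiles.category_weights is not None
            else np.full(len(profiles.category_ids), 1.0 / len(profiles.category_ids))
        )
        comp = bisection_annotate(
            _ot_core(profiles, config.ot_params, prior),
            data,
            profiles,
            config.bisections,
            config.bisection_divisor,
        )

    # sum sub-categories back to their parents
    parents = profiles.parents()
    parent_ids = sorted(set(parents))
    summed = np.zeros((len(data.obs_ids), len(parent_ids)))
    col = {p: j for j, p in enumerate(parent_ids)}
    for i, p in enumerate(parents):
        summed[:, col[p]] += comp.weights[:, i]
    if config.max_annotation is not None:
        summed = _truncate_composition(summed, config.max_annotation)
    rowsums = summed.sum(axis=1, keepdims=True)
    rowsums[rowsums == 0] = 1.0
    return CompositionMatrix(data.obs_ids, parent_ids, summed / rowsums, "probability")
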