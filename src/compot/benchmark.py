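"""Evaluation metrics, simple baselines and desk-scale benchmark drivers."""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd
from sklearn.svm import LinearSVC

from .boosters import AnnotateConfig, annotate
from .data import CategoricalAnnotation, CompositionMatrix, CountMatrix, log1p_normalize
from .simulate import (
    AmbientParams,
    DropoutParams,
    MixtureSimParams,
    ScsimParams,
    add_ambient,
    apply_dropout,
    simulate_fate_data,
    simulate_mixtures,
    simulate_scrnaseq,
    type_profiles,
)

__all__ = [
    "l2_error",
    "fraction_correct",
    "fate_correlation",
    "svm_baseline",
    "run_benchmark",
]


def _align(pred: CompositionMatrix, truth: CompositionMatrix):
    if set(pred.category_ids) != set(truth.category_ids):
        raise ValueError("category sets differ between prediction and truth")
    p = pred.to_probability().as_frame()
    t = truth.to_probability().as_frame()
    t = t.loc[p.index, p.columns]
    return p.to_numpy(), t.to_numpy()


def l2_error(pred: CompositionMatrix, truth: CompositionMatrix) -> float:
    """Mean over observations of the Euclidean norm of the row difference."""
    p, t = _align(pred, truth)
    return float(np.linalg.norm(p - t, axis=1).mean())


def fraction_correct(pred: CompositionMatrix, truth: CategoricalAnnotation) -> float:
    """Fraction of observations whose argmax annotation matches the truth.

    Argmax ties break lexicographically; a tie counts as correct only if the
    chosen category matches.
    """
    labels = pred.argmax_labels().as_series()
    truth_s = truth.as_series().reindex(labels.index)
    return float((labels == truth_s).mean())


def fate_correlation(pred: CompositionMatrix, truth: CompositionMatrix) -> float:
    """Pearson r between the flattened predicted and true fate matrices."""
    p, t = _align(pred, truth)
    return float(np.corrcoef(p.ravel(), t.ravel())[0, 1])


def svm_baseline(
    ref: CountMatrix,
    ref_anno: CategoricalAnnotation,
    test: CountMatrix,
) -> CategoricalAnnotation:
    """Linear support-vector classifier on log1p-normalized expression."""
    from .data import intersect_genes

    test, ref = intersect_genes(test, ref)
    ref_anno = ref_anno.reindex(ref.obs_ids)
    clf = LinearSVC()
    clf.fit(log1p_normalize(ref), ref_anno.labels)
    pred = clf.predict(log1p_normalize(test))
    return CategoricalAnnotation(test.obs_ids, list(pred))


# ---------------------------------------------------------------------------
# benchmark drivers
# ---------------------------------------------------------------------------

def _dropout_instance(
    shift: float,
    seed: int,
    n_ref: int = 16384,
    n_test: int = 8192,
    scsim: ScsimParams | None = None,
):
    """Reference/test pair from one generative model, dropout on test only."""
    base = scsim or ScsimParams()
    ref_params = replace(base, n_cells=n_ref, seed=seed)
    test_params = replace(base, n_cells=n_test, seed=seed + 1)
    shared = type_profiles(ref_params)
    ref, ref_anno, _ = simulate_scrnaseq(ref_params)
    test, test_anno, _ = simulate_scrnaseq(test_params, profiles=shared)
    if shift != 0:
        test = apply_dropout(test, DropoutParams(midpoint_shift=shift, seed=seed + 2))
    return ref, ref_anno, test, test_anno


def run_benchmark(
    task: str,
    grid=None,
    seeds=(0,),
    methods=("ot", "svm"),
    n_ref: int = 16384,
    n_test: int = 8192,
    config: AnnotateConfig | None = None,
    scsim: ScsimParams | None = None,
) -> pd.DataFrame:
    """Run a parameter sweep for one task; returns a tidy result table.

    Tasks: 'dropout' (grid of midpoint shifts, metric fraction_correct),
    'ambient' (grid of ambient fractions, fraction_correct), 'mixture'
    (grid of bead sizes, L2 error vs count-fraction truth), 'fates'
    (no grid, Pearson r of predicted vs clonal fate bias).
    """
    rows = []
    config = config or AnnotateConfig()
    for seed in seeds:
        if task == "dropout":
            for shift in grid if grid is not None else (0.0, -1.0):
                ref, ref_anno, test, test_anno = _dropout_instance(
                    shift, seed, n_ref, n_test, scsim
                )
                for method in methods:
                    value = _classify_and_score(
                        method, ref, ref_anno, test, test_anno, config
                    )
                    rows.append(
                        dict(
                            method=method,
                            task=task,
                            parameter=shift,
                            metric="fraction_correct",
                            value=value,
                            seed=seed,
                        )
                    )
        elif task == "ambient":
            base = scsim or ScsimParams()
            ref_params = replace(base, n_cells=n_ref, seed=seed)
            test_params = replace(base, n_cells=n_test, seed=seed + 1)
            shared = type_profiles(ref_params)
            _, ref_anno, ref_lam = simulate_scrnaseq(ref_params)
            _, test_anno, test_lam = simulate_scrnaseq(test_params, profiles=shared)
            for f_drop in grid if grid is not None else (0.0, 0.5):
                ref = add_ambient(ref_lam, AmbientParams(f_drop=0.0, seed=seed + 2))
                ref = CountMatrix(ref_anno.obs_ids, ref.gene_ids, ref.values)
                test = add_ambient(
                    test_lam, AmbientParams(f_drop=f_drop, seed=seed + 3)
                )
                test = CountMatrix(test_anno.obs_ids, test.gene_ids, test.values)
                for method in methods:
                    value = _classify_and_score(
                        method, ref, ref_anno, test, test_anno, config
                    )
                    rows.append(
                        dict(
                            method=method,
                            task=task,
                            parameter=f_drop,
                            metric="fraction_correct",
                            value=value,
                            seed=seed,
                        )
                    )
        elif task == "mixture":
            base = scsim or ScsimParams()
            ref_params = replace(base, n_cells=n_ref, seed=seed)
            ref, ref_anno, _ = simulate_scrnaseq(ref_params)
            for bead_size in grid if grid is not None else (0.5, 1.0, 1.5):
                beads, _, count_truth, _ = simulate_mixtures(
                    ref,
                    ref_anno,
                    MixtureSimParams(
                        n_beads=n_test, bead_size=bead_size, seed=seed + 1
                    ),
                )
                keep = beads.obs_totals() > 0
                beads_nz = CountMatrix(
                    [beads.obs_ids[i] for i in np.flatnonzero(keep)],
                    beads.gene_ids,
                    beads.values[keep],
                )
                truth_nz = CompositionMatrix(
                    beads_nz.obs_ids,
                    count_truth.category_ids,
                    count_truth.weights[keep],
                    "probability",
                )
                comp = annotate(beads_nz, ref, ref_anno, config)
                rows.append(
                    dict(
                        method="ot",
                        task=task,
                        parameter=bead_size,
                        metric="l2_error",
                        value=l2_error(comp, truth_nz),
                        seed=seed,
                    )
                )
        elif task == "fates":
            late, late_anno, early, _, truth = simulate_fate_data(seed=seed)
            comp = annotate(early, late, late_anno, config)
            rows.append(
                dict(
                    method="ot",
                    task=task,
                    parameter=np.nan,
                    metric="fate_correlation",
                    value=fate_correlation(comp, truth),
                    seed=seed,
                )
            )
        else:
            raise ValueError(f"unknown task {task!r}")
    return pd.DataFrame(rows)


def _classify_and_score(method, ref, ref_anno, test, test_anno, config):
    if method == "ot":
        comp = annotate(test, ref, ref_anno, config)
        return fraction_correct(comp, test_anno)
    if method == "svm":
        pred = svm_baseline(ref, ref_anno, test)
        return float(
            (pred.as_series() == test_anno.as_series().reindex(pred.obs_ids)).mean()
        )
    raise ValueError(f"unknown method {method!r}")
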