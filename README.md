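# compot

Compositional annotation transfer for single-cell and spatial omics by
semi-unbalanced entropic optimal transport — with count splitting into pure
per-category profiles, segmentation-free single-molecule annotation,
image-free segmentation, spatial statistics for compositional annotations,
and the synthetic-data generators used to benchmark all of it.

## The problem

Spatial capture technologies (Slide-seq beads, Visium spots) measure the
mixed expression of several neighboring cells; single cells themselves can
carry ambiguous identities through dropout, ambient RNA or differentiation
continua.  Transferring a reference's categorical labels (e.g. cell types
from an annotated scRNA-seq atlas) to such data therefore means assigning
each observation a *composition* — a weight vector over categories —
rather than a single label.

## The model

Given reference category profiles `pi_gt` (unit-sum over genes) and
observations with counts `x_gb`, the annotation `gamma_tb` solves

    min_gamma  <gamma, M> + eps * sum gamma log gamma + lam * KL(gamma 1 || c_t)
    s.t.       sum_t gamma_tb = c_b   (total counts per observation, exact)

with cost `M_tb = 1 - BC(pi_.t, x_.b)`, where `BC(p, q) = sum_g sqrt(p_g q_g)`
is the Bhattacharyya coefficient, `eps = 0.005` the entropic regularization
and `lam = 0.1` the strength of the Kullback–Leibler tie of the category
marginal to the reference composition `c_t`.  The problem is solved by
Sinkhorn–Knopp scaling with a damped category-side exponent
`lam / (lam + eps)`.  Around this core sit three boosters: gene-wise
platform normalization, k-means multi-center profiles per category, and
bisectioned annotation of residuals.  See `docs/methods.md` for the full
account.

## Worked example

```python
import numpy as np
from compot import (
    ScsimParams, MixtureSimParams, AnnotateConfig, CountMatrix, CompositionMatrix,
    simulate_scrnaseq, simulate_mixtures, annotate, l2_error, split_counts,
    mean_profiles,
)

# an annotated synthetic reference: 2,000 cells, 8 types
ref, ref_anno, _ = simulate_scrnaseq(
    ScsimParams(n_cells=2000, n_genes=2000, n_types=8, seed=0)
)

# Slide-seq-like beads mixing those cells on a torus
beads, cell_truth, count_truth, positions = simulate_mixtures(
    ref, ref_anno, MixtureSimParams(n_beads=1000, bead_size=1.0, seed=1)
)

# keep beads that captured at least one read
keep = np.flatnonzero(beads.obs_totals() > 0)
beads_nz = CountMatrix([beads.obs_ids[i] for i in keep],
                       beads.gene_ids, beads.values[keep])
truth_nz = CompositionMatrix(beads_nz.obs_ids, count_truth.category_ids,
                             count_truth.weights[keep])

# compositional annotation with the default configuration
comp = annotate(beads_nz, ref, ref_anno, AnnotateConfig())
print("mean L2 error vs count-fraction truth:",
      round(l2_error(comp, truth_nz), 3))

# split the bead counts into pure per-type count matrices
profiles = mean_profiles(ref, ref_anno).subset_genes(beads_nz.gene_ids)
split = split_counts(beads_nz, comp, profiles, round=True, seed=2)
print("split conserves counts:",
      (split.total() != beads_nz.values).nnz == 0)
```

Output:

```
mean L2 error vs count-fraction truth: 0.128
split conserves counts: True
```

An L2 error of 0.128 means a bead's inferred type fractions deviate from
the simulated truth by about 0.13 in Euclidean length on the probability
simplex — e.g. a dominant type estimated at 0.55 instead of 0.64.  The
split matrices sum back to the bead counts exactly (integer rounding
redistributes fractional reads multinomially), so downstream single-cell
tooling sees consistent pure-type count data.

A command line mirrors the library:

```sh
compot simulate mixtures --n-cells 2000 --n-beads 1000 --out sim/
compot annotate --data sim/ --ref ref/ --ref-anno ref/annotation.csv --out comp.csv
compot spatial cooccurrence --positions sim/positions.csv --anno comp.csv \
    --bins 0,20,100 --out cooc.csv
```

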