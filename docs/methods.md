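# Methods

`compot` transfers annotations from an annotated reference to unannotated
observations as *compositions* — per-observation weight vectors over
reference categories — and provides the downstream machinery those
compositions need: exact count splitting, single-molecule annotation,
image-free segmentation and compositional spatial statistics.  This note
documents the models, the defaults and the reasoning behind the open design
choices.

## Core model: semi-unbalanced entropic optimal transport

Observations `b` (cells, beads, molecule bins) and categories `t` live in a
shared expression space.  The annotation matrix `rho_tb` is found as the
coupling `gamma` of an optimal-transport problem

    argmin_gamma  <gamma, M> + epsilon * sum gamma log gamma
                  + lam * KL( sum_b gamma_tb || c_t )
    subject to    sum_t gamma_tb = c_b,  gamma >= 0

* `M_tb = 1 - similarity(pi_t, x_b)` — the similarity is the Bhattacharyya
  coefficient `BC(p, q) = sum_g sqrt(p_g q_g)` between the category profile
  and the observation's count fractions by default; cosine and
  log1p-cosine variants are available.  The 1-minus map keeps costs in
  [0, 1] with zero cost at identity.
* `c_b` is the observation's total count — enforced exactly, because the
  measured counts are known.  The category marginal is only tied softly
  (weight `lam`) to a prior `c_t`, by default the reference's per-category
  cell fractions.
* `epsilon` (default 0.005) makes the problem strictly convex; it is the
  smallest value at which the Sinkhorn scaling is numerically comfortable
  with costs of order 1.  `lam` defaults to 0.1 — enough prior to
  stabilize rare categories without forcing the reference composition
  onto the target.

The solver is Sinkhorn–Knopp alternating scaling with the damped
category-side exponent `lam / (lam + epsilon)`; the final update is on the
observation side, so the observation marginal holds to machine precision.
Marginals are normalized to unit mass internally so `epsilon` has the same
meaning regardless of sequencing depth.  When a scaling vector under- or
overflows, the iteration restarts in the log domain.  Convergence is
declared at a relative scaling change below 1e-8, capped at 10,000
iterations (a warning flags the rare non-converged case and the current
plan is returned).  The solution was validated against a generic convex
solver (SLSQP on the explicit objective) on small instances.

Observations with zero counts are excluded from the solve and receive the
prior composition.

## Boosters

**Platform normalization.**  Gene-wise factors
`f_g = rho^A_g / sum_t pi^B_gt rho^A_t` rescale reference profiles into
target units, where `rho^A_g` is the target pseudobulk and `rho^A_t` the
assumed target category composition (initially the reference composition).
A pseudocount of 1e-12 keeps the denominator positive.  With
`platform_iterations > 1` the factors and the composition estimate are
iterated to stability (max relative factor change below 1e-3); the first
pass captures almost all of the effect in practice.  Data stay in target
(test) units so integer counts are preserved for object splitting.

**Multi-center profiles.**  Within each category, cells are subclustered by
k-means (k-means++ initialization, 10 restarts, seeded; k clipped to the
category size) on log1p-normalized expression; each subcluster contributes
a normalized mean raw-count profile, and the annotation is summed back over
subclusters.  Default 10 centers per category.

**Bisectioning.**  The core annotator is applied repeatedly to a residual:
each round assigns `1/divisor` of the current residual's counts according
to the round's annotation, subtracts the corresponding profile
reconstruction (clipped at zero — negative counts are meaningless), and a
final pass assigns the remaining fraction, so assigned count fractions sum
to each observation's total exactly.  Defaults: 4 rounds, divisor 3.  The
per-round fraction is `1/divisor` rather than `(divisor-1)/divisor`: only
this orientation makes a larger divisor take *finer* steps, which is what
gives bisectioning its precision on mixtures; with the complementary
fraction a 50/50 two-profile mixture is recovered as (2/3, 1/3) instead of
(1/2, 1/2) when the core is categorical.

**max_annotation.**  Optional truncation to the top-k weights per
observation, renormalized to the simplex (k = 1 gives a categorical
annotator).

Profile means are computed on raw counts and then normalized — not on
per-cell-normalized data — so that all bookkeeping stays in count units;
bisection subtraction likewise operates in raw-count space, consistent with
object splitting.

## Object splitting

Count data are modeled as molecules drawn with joint probability
`p(g, t, b)`.  The measurement fixes the gene marginal per observation and
the annotation fixes the category marginal, so for each observation the
profile matrix `p(g|t)` (plus pseudocount `1e-12 * max(pi)`) is RAS-scaled
(iterative proportional fitting) until both marginals match within 1e-8
relative, capped at 1000 iterations.  Zero-count genes are dropped from the
scaling (their rows are zero by construction).  Optional integer rounding
floors every entry and assigns each gene's leftover reads multinomially
with probabilities proportional to the fractional remainders, conserving
per-gene totals exactly; the rounding stream is seeded per observation from
(seed, observation index) so results do not depend on execution order.

## Single-molecule annotation

Molecules are binned on a Cartesian grid (default 10 µm, the expected cell
size); each bin is annotated compositionally (platform normalization off by
default — molecule data and their profile reference share platform
effects); the bin annotation is distributed over molecule species by object
splitting, integer-rounded, and dealt randomly among the bin's molecules of
each species, so the molecule population reproduces the bin's annotation
probabilities.  The grid is then shifted by `1/n_shifts` of the spacing per
dimension (default 3 shifts, 9 grids in 2D) and each molecule's final label
is the modal vote.  Ties break toward the category with the highest mean
compositional weight over the molecule's bins, then lexicographically.
Votes are taken on categorical per-grid labels (not on full compositions);
the compositional information still enters through the tie-break.

## Image-free segmentation

Molecule affinities are `exp(-d_total^2 / (2 s^2))` with
`d_total^2 = d_spatial^2 + d_annotation^2`; `s` is a subcellular distance
scale (default 3 µm) and pairs beyond `max_distance` (default `4 s`) are
not connected.  The annotation distance is infinite between categories by
default (segments never mix categories); alternatively a matrix, or
profile-derived distances `(1 - BC) * s`.  Connected components are
processed independently.  Within a component, 2-way normalized cuts
(Fiedler vector of the normalized Laplacian, sweep over 32 thresholds) are
applied recursively.  A proposed cut is accepted only if both parts hold at
least `min_molecules` (default 20) molecules *and* its normalized-cut cost
is below the cost of the best cut of a homogeneous uniform point set of the
same size and density (Monte-Carlo calibrated with the same kernel, three
draws, cached by size/density octave).  The exact acceptance heuristics of
segmentation pipelines are necessarily approximate; both the threshold rule
and the supernode grid (default 20 µm) are configuration knobs.

## Spatial statistics

Pair statistics treat compositional annotations bilinearly: an ordered pair
(i, j) contributes `center_i[c] * anno_j[a]`.  Self-pairs are excluded;
distances are Euclidean with half-open bins.  Co-occurrence reports
`p(anno | center; bin) / p(anno)`.  Neighborhood z-scores compare observed
pair-weight sums with permutations of the annotation rows (the same
permutation is applied to both sides when anno and center are the same
annotation — permuting whole assignments — otherwise the center stays
fixed); `sd = 0` yields `z = 0`.

Region definition combines a feature-space kNN graph (across samples) and a
position-space kNN graph (within samples) as
`(1 - w) A_feat + w A_pos`, up-weighting cross-sample feature edges by the
ratio of within- to cross-sample feature edge weight, then Leiden
clustering.  Labels are invariant to observation order for well-separated
structure; for genuinely ambiguous data Leiden's tie-breaking can depend on
vertex order.

The annotation coordinate regularizes the minimum distance to a category:
cumulative occurrence histograms `N_A(d)` (bin width `bin_width`) are
crossed at threshold `N_l`, and the bias is removed with a homogeneous
category `H` by solving `N_H(d0) = N_H(d^l) - N_l` on the piecewise-linear
cumulative curve, taking the largest such distance and clipping at zero.
The observation itself is included in the histograms; this is what makes a
homogeneous annotation give `d0 = 0` exactly while noise-free categorical
annotations reproduce the minimum distance to the category within one bin
width.

Enrichments are tested across ensemble units — samples, or spatial
sub-blocks obtained by splitting each sample along its coordinate axes —
never across observations (which would inflate significance).  Per category
a two-sided Welch t-test compares unit-mean compositions between two
groups, with Benjamini–Hochberg correction; effects are log2 ratios of
group means.  The particular test is a package choice: units are
approximately independent replicates with unequal variances, and BH is the
standard multiplicity control at this scale.

## Synthetic data

**scRNA-seq counts** follow the Splatter/scsim generative family: gene base
means ~ Gamma(shape 0.34, scale 0.13); per-type differential-expression
factors ~ LogNormal(de_loc, de_scale) on a `de_prob` fraction of genes
(reciprocal with probability `de_downprob`); profiles normalized per type;
library sizes ~ LogNormal(7.64, 0.78) (about 2,000 counts per cell);
optional biological-coefficient-of-variation noise (dispersion 0.448, dof
22.087) as per-entry gamma mixing; Poisson sampling, generated in chunks of
2,048 cells to bound memory.  Defaults: 10,000 genes, 10 types, de_prob
0.025, de_loc 5.0, de_scale 1.0, de_downprob 0.  A reference/test pair from
*one* generative model is drawn by reusing the type profiles
(`type_profiles`) with a new seed.

**Dropout** fits a two-parameter sigmoid
`p0(x) = 1 / (1 + exp(shape (x - mid)))` to (log mean count, zero fraction)
per gene by least squares, shifts it along the log-mean axis (negative
`midpoint_shift` moves the curve toward higher expression, i.e. *more*
dropout; shift −1 is the mild benchmark setting), computes the extra
dropout `q_g = clip((p1 - p0) / (1 - p0), 0, 1)` and thins every count
binomially with retention `1 - q_g` (or zeroes whole entries with
probability `q_g` in `bernoulli` mode).  All-zero genes get `q = 0`.

**Ambient RNA** samples `C_ng ~ NB(lambda_ng + d_n^drop a_g, phi)` with the
ambient profile `a` the normalized mean of `lambda` over cells,
`d_n^drop ~ LogNormal(d_mu + log f_drop, d_sigma)` reusing the cell-size
parameters, and NB dispersion `phi` (default 0.3; variance
`mu + phi mu^2`).  The matching reference is generated with `f_drop = 0`.

**Bead mixtures** place cells and beads uniformly on the unit square with
periodic boundaries (torus distance).  Cell `c` contributes to bead `b`
with weight `w = r exp(-(d/l)^2 / 2)`, `l = bead_size / 2 * sqrt(1/n)`.
Each gene's counts are allocated by one multinomial draw over
(nearby beads..., uncaptured), with weights renormalized if they exceed 1,
so counts are conserved exactly; beads further than `6 l` are negligible
and skipped.  Both a cell-number-fraction truth (accumulated kernel weights
per type) and a count-fraction truth (allocated counts per type) are
returned; the count-fraction truth is the default benchmark target since it
describes the counts the bead actually received.

**Clonal fate data** draw per-clone fate biases from a Dirichlet
(concentration 1 by default); late cells are pure draws from the fate
profiles and early cells are Poisson draws around the bias-weighted convex
combination of fate mean profiles.

What the generators do *not* emulate: batch effects beyond gene-wise
scaling, spatial expression gradients within a cell type, segmentation
artifacts, doublet-specific chimeras, and empty droplets.  Passing
benchmarks on these simulations therefore demonstrates correctness of the
algorithms under the stated generative assumptions, not performance on any
particular real tissue.

## Benchmarks and problem sizes

The dropout benchmark uses 16,384 reference and 8,192 test cells at the
generator defaults (10,000 genes, 10 types), dropout shift −1 applied to
the test set only, and scores argmax agreement; the linear-SVM baseline
(`LinearSVC`, library defaults, log1p-normalized features) is trained on
the unperturbed reference.  The mixture benchmark at desk scale uses a
fully synthetic reference (2,000 cells, 2,000 genes, 8 types) and 1,000
beads per bead size; the fate benchmark uses 4 fates, 150 clones of 4 early
cells.  These sizes are the package's standing benchmark configuration;
larger sweeps are available through `run_benchmark` / the CLI.

## Known limitations

* Annotation requires overlapping feature spaces; there is no
  cross-modality translation.
* The OT core has no spatial-smoothness prior; spatial structure enters
  only through binning and the downstream tools.
* The segmentation cut-acceptance rule is a calibrated heuristic; on
  marginal data the number of segments can vary within a small range.
* Under the simulated dropout perturbations the linear-SVM baseline
  degrades far more gracefully than published comparisons on other
  datasets suggest; see the benchmark tables produced by
  `scripts/acceptance.py` for the numbers this code actually measures.
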