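# Methods

This note records the model assumptions, parameter choices and numerical
conventions behind `profilex`, and what the synthetic benchmarks do and do
not demonstrate.

## Problem setting

The input is a samples × genes matrix of log-scale expression values with a
binary sample annotation (healthy = 0, tumor = 1).  The goal is a compact
cluster of mutually correlated genes whose expression separates the two
classes, extracted by a fixed sequence of stages rather than a joint
optimisation: filtering, hierarchical clustering of gene profiles, per-level
cluster selection, supervised evaluation, and fuzzy fusion of classifier
outputs.  Internally the matrix is always samples × genes; on-disk tables may
be gene-major (the common convention for expression exports), hence the
explicit orientation flag on the readers.

## Cluster-validity criterion

All selection steps use one criterion,

    QC_int = K (K − 1) QC_W² / ((N − K) QC_B²),

a multiplicative composite of the WB-index (within/between ratio) and the
reciprocal of the Calinski–Harabasz ratio, under the correlation distance
d(x, y) = 1 − r(x, y).  Lower is better: compact clusters with well-separated
centers.  Conventions: cluster centers are arithmetic means in expression
space (the metric is correlational but no other center definition is
implied by the construction); the correlation of a constant vector is
undefined, so its distance to anything is fixed at 1 (neutral — constant
profiles are uninformative, not infinitely far) with a warning; coincident
centers give QC_B = 0 and the criterion is reported as +inf rather than an
error.  The implementation is vectorised; the test suite pins it to
plain-loop evaluations of the defining formulas at 1e-10 relative tolerance.

## Filtering stage

Per-gene statistics: unbiased (n−1) sample variance; mean absolute
expression; Shannon entropy in nats of the profile discretised into B = 10
equal-width bins over its own [min, max] range (B is configurable; the
ordering of genes by entropy, which is all the filter uses, is insensitive
to moderate B).  Entropy uses the James–Stein shrinkage estimator: raw bin
frequencies are shrunk toward the uniform target with intensity
λ = (1 − Σθ̂²)/((n−1) Σ(1/B − θ̂)²) clipped to [0, 1] (λ = 1 when the
denominator vanishes); a constant profile has entropy 0 by convention.  A
practical consequence worth knowing: profiles that are nearly uniform over
their range (chaotic genes) get λ ≈ 1 and collapse onto ln B almost exactly,
which makes the entropy boundary extremely effective at separating chaotic
genes from structured ones.

The scan advances all three boundaries together over one shared linear grid
of 50 steps (configurable) from the observed minimum to maximum of each
statistic (entropy reversed).  The first step keeps every gene by
construction — with strict keep-inequalities the exact extremes would
otherwise drop the boundary genes themselves.  A gene is kept iff variance
and mean absolute value exceed, and entropy falls below, the current
boundaries (keep-if-all-pass); the dual reading, remove-only-if-all-fail, is
available as `filter_mode="all_fail_removed"`.  Steps keeping fewer than 3
genes cannot be scored under a correlation distance over genes and are
recorded as +inf.  Ties in the argmin break toward the earliest step, which
retains the most genes.

A property of this design observed consistently on synthetic data: because a
class mean shift contributes to a gene's variance, tightening the variance
boundary preferentially keeps strongly shifted genes and the criterion can
keep improving well past the point where the chaotic genes are gone.  The
fixed boundary set therefore tends to keep a high-variance, strongly
informative subset rather than every informative gene, and its size varies
substantially between random draws.  Downstream stages are evaluated with
this in mind (see the benchmark section).

## SOTA clustering

Gene profiles are clustered by a level-wise Self-Organizing Tree: at each
level every leaf with at least `min_split_size` (default 2) members is split
by a two-cell competitive layer.  The two daughter cells start at the parent
centroid displaced by ±1e-6 on alternating coordinates; profiles are
presented in input order; per presentation the nearer cell (correlation
distance) moves toward the profile with rate `lr_winner` = 0.1 and its
sister with `lr_sister` = 0.01 (`lr_mother` = 0.05 is retained for
deeper-tree variants where the parent also updates; it is a no-op in a pure
two-cell split).  Training stops when the relative change of the total
winner distance falls below `tol` = 1e-6 or after 100 epochs.  These
magnitudes are conventional for competitive learning; on separable data the
resulting partition is insensitive to them, and there is no randomness
anywhere in the clustering — reruns are bit-identical.  Degenerate splits
(one empty daughter) collapse back to the unsplit leaf, so 2^L is an upper
bound on the cluster count at level L, attained when every split succeeds.

Per-level selection scores each cluster by QC_int with samples as objects
restricted to the cluster's genes and picks the minimum within size bounds
(default: at least 10 genes, no upper bound; an upper bound is available for
excluding very large clusters).

## Classifier bank

Stratified 60/40 split with per-class round-half-up training counts (65 + 91
samples at 0.6 give 39 + 55 = 94 training samples), deterministic per seed.
Classifiers: logistic regression (scikit-learn default L2 regularisation —
an unpenalised fit does not converge on separable high-dimensional data, and
the ridge penalty is the standard numerical remedy); linear-kernel SVM with
the cost tuned by 10-fold cross-validation over {0.01, 0.1, 1, 10, 100};
a single unpruned decision tree; a random forest of 10 trees.  Every model
exposes a tumor probability, and the hard decision is defined as
probability ≥ 0.5 so score and decision can never disagree.  Metrics (AC,
PR, RC, F, MCC) follow the standard confusion-matrix formulas with 0/0 → 0
conventions (warned); AUC is the Mann–Whitney two-sample statistic with ties
counted one half, equivalent to the trapezoidal area under the empirical ROC.

## Fuzzy fusion

The three tumor probabilities (SVM, CART, RF) are the crisp inputs of a
Mamdani system on [0, 1].  Input terms: Healthy = trapezoid(0, 0, 0.2,
0.55) and Tumor = trapezoid(0.45, 0.8, 1, 1).  The ramps overlap on
[0.45, 0.55]: every crisp input must carry positive membership in at least
one term, and exactly abutting supports would leave the midpoint dead and
put a non-monotone dimple in the inference surface.  Output terms on the
final state FS: Healthy = trapezoid(0, 0, 0.15, 0.35), Probably Healthy =
triangle(0.25, 0.4, 0.55), Probably Tumor = triangle(0.45, 0.6, 0.75),
Tumor = trapezoid(0.65, 0.85, 1, 1).  The 8-rule base is the complete
majority structure over the 2³ input-term combinations: Tumor iff all three
vote tumor, Probably Tumor iff exactly two, mirrored on the healthy side.
Inference: min for rule activation, consequents clipped at their activation,
max accumulation, and centroid defuzzification by discrete summation on a
uniform 1001-point grid (bit-stable given the grid size; the grid error
against the closed-form trapezoid centroid at the crisp corners is below
3e-4).  The decision is tumor iff FS ≥ 0.5, with the tie going to tumor —
the conservative direction for a diagnostic.  Feeding hard 0/1 predictions
instead of probabilities is a configuration option; a four-input rule-base
builder (including the GLM) exists, with an exact tie of votes mapping to
Probably Tumor for the same conservative reason, but the default system
fuses the three strong classifiers only.

The default surface is monotone in each input and point-symmetric
(FS(a,b,c) + FS(1−a,1−b,1−c) ≈ 1), and the defuzzified value always lies
within the hull of the active consequents' supports; all three properties
are enforced by tests.

## Synthetic data

The generator emulates three gene regimes on a cohort of 50 + 50 samples
(log2-scale, base mean 8):

* 4 correlated blocks of 25 genes; gene g of block k in sample s is
  `8 + class_s · 2 · sign_k + 0.45 · z_{k,s} + N(0, 0.5²)`, with z a shared
  per-block latent factor and sign_k alternating so blocks are up- or
  down-regulated in turn;
* 50 chaotic genes, uniform over the base mean ± 3 effect sizes,
  class-independent (the uniform law guarantees near-maximal entropy);
* 50 weakly expressed genes at a tenth of the base mean and variance.

The latent loading 0.45 puts just under half of the non-class residual
variance into the shared factor: within-block co-expression ≈ 0.82 (a tight
co-regulated module) with per-gene class separation d′ ≈ 3 (a strong
effect).  The shared factor is a floor on what averaging genes of one block
can achieve, which is exactly the trade-off real modules impose.

What the benchmarks show: under these conditions the boundary scan removes
essentially all chaotic and weakly expressed genes (median 100% over seeds);
level-2 SOTA clustering of the block genes recovers the planted blocks with
ARI 1.0; the selected cluster is essentially purely informative; and the
SVM, forest and fused decisions reach ≥ 0.95 median test accuracy on the
selected cluster.  What they do not show: performance under batch effects,
heavy-tailed noise, probe-level artifacts, unbalanced classes, or weak
effects — none of which the generator emulates — nor stability of the
*number* of genes the filter keeps, which is seed-sensitive by the argmin
property described above.

A second constructor builds 2^depth hierarchically nested gene blocks from
orthogonal Hadamard sign patterns with geometrically decreasing weights
(ratio 0.7, per-gene noise 1e-3), used to verify that ten levels of binary
splitting yield exactly 1024 clusters on separable data; with faster decay
or larger noise the deepest patterns drown and the count falls short, so
those two values are part of the construction, not tuning knobs.

## Pipeline conventions

One seed fans out to the split and all classifier fits; reports echo the
configuration (minus the output directory) and reruns are byte-identical.
The final level is chosen by a declared rule — maximal fused F within the
size bounds, ties toward the shallowest level — rather than by inspection;
the full per-level table is always retained for the analyst, and a
`profilex score` command re-derives every reported criterion value from the
persisted tree to guard against report drift.  Problem sizes in the test
suite (100 × 200 matrices, hierarchy depth ≤ 2 in chained runs, 11 seeds for
median properties) are chosen to exercise every stage at desk scale.
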