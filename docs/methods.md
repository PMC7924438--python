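# Methods

## The resampling model

CluSMOTE treats class imbalance as two coupled problems: the majority
class is too large (so classifiers ignore the minority) but also
structured (so random undersampling loses information). The method
therefore undersamples the majority *per density cluster* and closes the
remaining gap with SMOTE interpolation.

Let `MI` and `MA` be the minority and majority counts. After clustering
the majority class, each cluster `Ci` of size `M_ci` receives the quota

    Size_Ci = r · MI · M_ci / MA

so that the retained majority sample is proportional to cluster mass and
the retained total is `r · MI`. The oversampling degree `r` is the
majority:minority ratio after undersampling; SMOTE then raises the
minority to the same count, so the output is always exactly balanced.
`r = 1` retains `MI` negatives and creates no synthetic points — pure
cluster-based undersampling.

### Numerical choices in the quota rule

The raw quotas are real numbers. They are integerized by
largest-remainder (Hamilton) rounding: floor every quota, then hand the
leftover units to the largest fractional remainders, breaking ties by
ascending cluster id. This conserves the total exactly and is fully
reproducible. Two clamp rules keep the plan feasible:

* if `round(r · MI) > MA` the target is clamped to `MA` (the entire
  majority class is retained and the minority is SMOTEd up to `MA`);
* a quota can never exceed its cluster size; excess is redistributed
  proportionally among clusters with headroom (water-filling), and if no
  headroom remains the total is clamped to the capacity.

### Clustering

The majority class is clustered with HDBSCAN
(`sklearn.cluster.HDBSCAN`, `min_cluster_size = 5`), which extracts flat
clusters by density stability and needs no preset cluster count. Points
labeled noise are kept as one pseudo-cluster eligible for sampling
(`include_noise = True` by default): discarding them would reintroduce
exactly the information loss the method exists to avoid. If clustering
finds no structure at all (everything noise), the fallback is a single
cluster — i.e. plain random undersampling — with a log message. Features
are standardized (zero mean, unit variance) before clustering by default
because density structure is scale-sensitive and typical inputs mix
scales (solvent accessibilities against log-odds scores).

### SMOTE

Synthetic minority points are `x + u (x_nn − x)` with `u ~ U(0,1)` and
`x_nn` one of the `k = 5` Euclidean nearest minority neighbors of `x`
(`k` capped at `MI − 1`). Interpolation happens in the raw feature
space. Only minority rows are interpolated; sampled majority rows pass
through untouched and every original minority row survives. One master
seed is split into independent substreams for majority sampling and
SMOTE, so the full pipeline is deterministic.

## Evaluation protocol

Evaluation mimics complex-based leave-one-out cross-validation: rows
carry a group id (one antigen–antibody complex), each fold tests on one
whole group and trains on the rest. Resampling is refit inside every
training fold; test folds keep their natural imbalance. Reported
metrics per fold: TPR, TNR, precision, FPR, ROC AUC (Mann–Whitney
concordance, ties = ½), `Gmean = √(TNR·TPR)`, the adjusted Gmean

    AGm = (Gmean + TNR · Nn) / (1 + Nn)   if TPR > 0, else 0

with `Nn` the negative-class proportion of the evaluated set, and the
F-measure in count form `2TP / (2TP + FN + FP)`. Aggregation over folds
is macro (arithmetic mean of per-fold metrics), which is why an
aggregated Gmean is generally not the Gmean of the aggregated rates.
Zero-division conventions: precision is 0 when nothing is predicted
positive; Gmean and AGm use the TPR = 0 branch; all such events are
logged.

### Classifiers

The harness wraps two off-the-shelf learners behind a small spec; the
resampler, not the learner, is the subject of study.

* **Decision tree** — CART with cost-complexity pruning; the pruning
  strength is selected to maximize accuracy on a held-out 10 % of the
  training fold (`dt_prune_fraction = 0.1`), echoing error-based pruning
  on a reserved pruning set. The AUC score is the positive-class leaf
  proportion.
* **Linear SVM** — hinge-loss SGD (`alpha = 1e-4`, 5 epochs, per-sample
  updates), the standard primal formulation of a Pegasos-style linear
  SVM. The AUC score is the signed margin.

Features are standardized on the (resampled) training fold before
fitting; this is configurable since some pipelines pre-scale.

Grid cells are seeded from
`(master seed, strategy, r, classifier, fold, cell seed)` so every cell
is independently reproducible; strategies that do not use `r` receive an
r-independent seed, so their rows are identical across the r sweep.

## Synthetic data: what it emulates and what it does not

`make_imbalanced` draws the majority class from a mixture of
`n_majority_clusters = 3` unit-variance Gaussians with Dirichlet(2)
weights — unequal cluster sizes, so proportional quotas actually differ —
and the minority from one offset Gaussian, with an `overlap` fraction of
minority mass relocated *into* majority components. That overlap is the
hard-boundary regime the resampler targets: minority points sitting in
majority density are exactly the ones a classifier sacrifices under
imbalance.

Defaults: `n_minority = 50`, `imbalance_ratio = 10` (the class ratio of
surface-residue epitope data), `dim = 12`, `cluster_separation = 5`
(center distance in within-cluster standard deviations),
`overlap = 0.4`. The dimensionality matters: in very low dimension even
a small retained majority sample covers the majority support, so the
choice of `r` barely moves the decision boundary. Real feature tables
here have hundreds of correlated physicochemical columns with much lower
effective coverage; `dim = 12` abstract dimensions put the default
generator in a comparable regime — the decision-tree operating range on
these defaults (TPR ≈ 0.65–0.75, TNR ≈ 0.8–0.9 across the r sweep) sits
in the band reported for real epitope data. What the generator does
**not** emulate: correlated features, the 544-dimensional AAindex
geometry, per-complex heterogeneity beyond random group assignment, or
label noise. Passing trend tests on this data shows the resampler moves
the sensitivity/specificity trade-off the way the method intends, not
that any particular real-data metric will be attained.

`make_grouped` deals each class round-robin over `n_groups`
pseudo-complexes after a seeded shuffle, guaranteeing both classes in
every group (requires `n_groups ≤ n_minority`).

`make_toy_structure` emits minimal single-chain PDB files: an ideal
α-helix Cα trace (2.3 Å radius, 100°/residue, 1.5 Å rise → 3.83 Å
consecutive Cα–Cα distances), a Fibonacci-lattice sphere surface with
radial pseudo-side-chain atoms (for contact tests), or a self-avoiding
random coil. Coordinates and B factors are pre-rounded to PDB column
precision (3 and 2 decimals) so a parse of the emitted text reproduces
the in-memory table exactly. The epitope is a spatially contiguous
patch: the residue farthest from the centroid plus its nearest
neighbors, `round(fraction · n)` residues in all.

## Structural features

All microsphere features use a default radius of 13 Å, the customary
half-sphere-exposure radius; the source description leaves the radius
open, so it is exposed as a parameter.

* **CN** — number of other Cα within the radius (inclusive boundary).
* **HSE** — the same neighbors split by the Cα-only pseudo-side-chain
  vector `u_i = (Cα_i − Cα_{i−1}) + (Cα_i − Cα_{i+1})`; a neighbor is
  "up" iff its displacement has positive dot product with `u_i`.
  Termini have no direction vector and are flagged missing.
* **QSE** — neighbors assigned to the eight octants of the local
  right-handed frame `e1 = û_i`,
  `e2 = normalize((Cα_{i+1} − Cα_{i−1}) ⊥ e1)`, `e3 = e1 × e2`.
  Degenerate (collinear) frames are flagged missing.

Tie handling: dot products within `1e-6` Å of zero count as the
negative side (down / negative octant). The tolerance exists because
exact-plane neighbors are structural, not accidental — each residue's
two chain neighbors satisfy `d = (t − u)/2` and therefore lie exactly in
the `e1`–`e2` plane — and a strict sign test would let floating-point
noise flip them after a rigid motion of the coordinates. With the
tolerance, CN, HSE and QSE are invariant under rotation and translation,
and the partition identities `up + down = CN` and `Σ octants = CN` hold
exactly.

Other features: B factor of the Cα and the all-atom residue mean;
AAindex1 physicochemical values (flat-file `H`/`I` blocks parsed in the
canonical two-row amino-acid order, `NA` imputed with the index mean and
flagged); and an amino-acid log-odds score contrasting epitope-centered
against non-epitope 9-residue sequence windows. A window enters the
counts only when its center (position 5) is exposed; with Laplace
pseudocount `pc = 1`,

    score(a) = log2 (n_epi(a) + pc)/(N_epi + 20pc)
             − log2 (n_non(a) + pc)/(N_non + 20pc)

which is antisymmetric under swapping the class labels. The exact
functional form of this feature is not pinned down by its source; the
pooled (non-position-specific) log2 form above is this package's
documented choice.

Epitope labels use the plain contact criterion: an antigen residue is an
epitope residue iff any heavy atom lies within 4 Å of any antibody heavy
atom. Surface filtering keeps residues with RSA strictly above 0.01; RSA
itself (like ASA and the depth/protrusion indices) is accepted as a
precomputed input column and never computed here — those quantities
belong to dedicated accessibility software, and the feature builder
passes such columns through keyed by (chain, residue number).

## Known limitations

* Binary classification only; no multi-class quota rule.
* HDBSCAN's `min_cluster_size` and SMOTE's `k` are conventional defaults,
  not derived quantities; both are exposed in `ResamplerConfig`.
* The linear SVM is a standard SGD hinge-loss learner, not a
  re-implementation of a specific Pegasos variant; with few epochs on
  hard problems its r-sweep trends are noisier than the tree's.
* Synthetic rows inherit a placeholder group id (the first minority
  group); group-aware SMOTE is out of scope.
* The toy structures are Cα-trace caricatures: no side-chain chemistry,
  no secondary-structure mixing, single chain, no altlocs or insertion
  codes beyond what Biopython resolves.
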