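# Methods

## Patch networks

A registered, skull-stripped volume is partitioned into axis-aligned
`l1 × l2 × l3` boxes ("patches"). The two hemispheres are tiled separately:
the midsagittal plane is taken as sagittal index `floor(X/2)` of the
lateral axis, and tiling proceeds outward from that plane (and from the
volume origin along the other two axes), so medial tissue is covered first
and a mirror-symmetric mask receives mirrored tilings with equal left/right
patch counts. A candidate box becomes a network node iff it contains at
least one in-mask voxel and its in-mask fraction is at least the retention
threshold (default 0.5; how boundary patches should be kept is a genuine
free choice, so the rule is exposed rather than hard-coded). Node order is
deterministic: hemisphere, then origin lexicographic.

Defaults: patch dims (10, 15, 20) assigned to (lateral, anterior–posterior,
inferior–superior) — a 3000-voxel patch at 1 mm isotropic resolution, the
intermediate granularity between voxel-wise and ROI analyses at which
patch-feature classifiers discriminate patient groups well. Coordinates are
0-based, boxes half-open, volumes assumed 1 mm isotropic (voxels ≡ mm³).

Connectivity: patch voxels are serialized in fixed C order (axis 0
slowest); entry `c_ij` is the Pearson correlation of the two patch vectors.
The matrix is symmetric with unit diagonal by construction. A zero-variance
patch vector leaves Pearson undefined; its off-diagonal entries are set to
0 and the node is flagged and logged rather than dropped, because the
downstream subject-space statistics require a uniform node set across
subjects. Per-subject global affine intensity rescalings leave the matrix
unchanged (Pearson invariance); this is tested.

Strength is the mean |entry| over all N² entries, diagonal included (the
literal "all entries" convention); the unit diagonal contributes the same
N/N² to every subject and therefore cancels from group comparisons.

## MDMR

For node *i* the subject-pair distance is `d = sqrt(2 (1 − r))`, with `r`
the Pearson correlation between the two subjects' node-*i* pattern rows
(all N columns; the own-diagonal entry, a constant 1 for every subject, is
included by default and an `include_diagonal=False` option exists). The
Spearman variant rank-transforms the rows first, with average ranks for
ties. `d` is exactly the Euclidean distance between centered, unit-norm
pattern vectors, which has two consequences used throughout:

* `SST = SSW + SSA` is a genuine sum-of-squares partition and `SSA ≥ 0`
  always (Euclidean embeddability); both are asserted at run time, and the
  distance-route values are tested against an independent embedding-space
  ANOVA oracle at 1e-10 relative tolerance.
* The `(n − 1)` scaling of the pseudo-F differs from the conventional
  PERMANOVA `[SSA/(k−1)]/[SSW/(n−k)]` only by a constant at fixed group
  sizes; since SST is permutation-invariant and F is monotone in SSW given
  SST, permutation p-values under either scaling are identical (tested).

The permutation test draws `n_perm` uniformly random label permutations
(default 9,999; at least 99 enforced). The default p-value is the add-one,
`≥` convention `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`, which is a
valid p in (0, 1]; the plain `>`/`n_perm` counting rule is available via
`add_one=False`. Ties between permuted and observed statistics are counted
as exceedances, with a 1e-10 relative guard against float round-off; the
observed statistic is computed through the same vectorized code path as the
permuted ones so the comparison is exact. Per-node permutation streams are
spawned from the master seed (`numpy.random.SeedSequence`), making results
independent of worker count and bitwise reproducible.

Multiple testing across the node family uses Benjamini–Hochberg step-up
q-values, significant at q ≤ α (default α = 0.01). The k-group
generalization adds one `(1/n_g)` within-group term per group; every group
needs at least 2 subjects or the design is rejected.

Complexity of the hot loop is O(N · n_perm · n²); a 30-node, 40-subject,
9,999-permutation run takes on the order of a second on one core, and node
parallelism is available via `n_jobs`.

## Downstream analyses

*Projection.* `c_i(u)` is the Pearson correlation between subject *u*'s
node-*i* pattern and the reference-group (healthy) mean pattern for that
node; values far from 1 indicate alteration. Group A vs B at each node uses
the one-sided Wilcoxon rank-sum alternative "A's scores are stochastically
larger" (A = the less-altered group); significance is Bonferroni,
`p ≤ α / family size`, with the family defaulting to the full grid N.
Rank-sum p-values are computed exactly (null enumeration) when the combined
sample is ≤ 25 without ties, otherwise by normal approximation with
continuity and tie correction. Both tests are invariant under strictly
monotone transforms of the scores, and swapping the groups flips the
one-sided alternative; both properties are tested.

*Strength comparison* uses the same one-sided rank-sum machinery with the
reference group hypothesized stochastically larger.

*MDS.* Group-mean (sub)connectomes — optionally restricted to a node
subset, e.g. the nodes significant in several comparisons — are compared by
the mean absolute difference of entries, and the group layout is classical
(Torgerson) MDS: double-center the squared distance matrix, eigendecompose,
embed on the top non-negative eigenvalues. Classical rather than
stress-minimizing MDS because it is deterministic and exact for
Euclidean-embeddable inputs (verified on planar configurations; four
equidistant points yield the closed-form strain 1/3 in 2-D). Orientation is
fixed by requiring the first group's coordinate to be non-negative on each
axis. Strain is reported as the fraction of total |eigenvalue| mass outside
the used axes.

The pipeline driver (`patchconn run`) executes grid → connectivity
(skipped when matrices are supplied) → MDMR for every configured group pair
→ overlap bookkeeping → projection, strength and MDS stages, and writes a
manifest with a config echo, content hashes of every output, and all
zero-variance warnings. Re-runs with identical config and seed reproduce
identical files.

## Synthetic data

The generator exists so every stage is testable against known ground truth;
it emulates the *statistical shape* of patch-network cohorts, not MRI
physics (no bias fields, motion, registration error, or longitudinal
change).

**Volumes branch.** The template is a superposition of low-frequency cosine
modes (seeded amplitudes/phases), positive inside a fixed ellipsoidal mask
symmetric about the midsagittal plane. A subject volume is template +
smooth subject-specific field (Gaussian-filtered noise, σ = 3 voxels,
default SD 2) + i.i.d. voxel noise (default SD 1). Atrophy in case groups
is injected at patch granularity as intensity attenuation toward the
mask-interior mean plus partial replacement by independent matched-moment
noise (decorrelation), both scaled by the effect size — the two modes that
patch-correlation connectivity responds to. Because every node's pattern
contains one entry per affected patch, image-level effects spill weakly
into neighboring nodes' tests; the volumes branch is therefore used for
construction/smoke properties, while quantitative recovery claims use the
matrices branch.

**Matrices branch.** Subjects share a latent template `B` (low-rank Gram
structure scaled to off-diagonal spread ±0.6, unit diagonal); a subject's
matrix is `B` plus symmetric i.i.d. entry noise (SD 0.12), clipped to
[−1, 1]. With effect size 0 all subjects are i.i.d., so group labels are
exchangeable — empirically, pooled null permutation p-values are uniform
(KS-tested) and the 1% rejection rate is compatible with 1%. For case
subjects the affected rows/columns are perturbed in two tiers:

* entries between two affected nodes move toward a sign-flipped target of
  fixed magnitude 0.2 — a strong shift that only affected nodes' own
  patterns contain, giving unambiguous ground truth for recovery tests;
* entries between affected and unaffected nodes rotate weakly (weight
  0.06 × effect) toward an independent alternative template — enough to
  make a *single* affected node detectable (a whole-row reshaping) and to
  lower case-group strength, while the per-coordinate spill into other
  nodes' patterns stays well below the entry noise.

This two-tier split is forced by symmetry: any change to entry `c_ij`
appears in both node *i*'s and node *j*'s patterns, so a generator that
perturbed affected rows strongly would make *every* node's test reject,
and one that perturbed only the affected block would make a lone affected
node invisible. The constants above were fixed by design simulations and
then frozen.

All randomness derives from one master seed via `SeedSequence.spawn` (one
child per subject); identical config + seed reproduces bitwise-identical
cohorts. Truth bookkeeping: the affected set is recorded as ground truth
only when the effect size is positive and a case group exists.

`REFERENCE_GROUP_SIZES` records the four-arm reference design (HC 80,
ncMCI 82, cMCI 70, AD 84; total 316) that the group-comparison defaults
emulate.

## Problem sizes and known limitations

Statistical test-suite runs use 30-node, 20–40-subject cohorts with 999 or
1,999 permutations (the package default is 9,999) and 100-replicate
batches; results quoted in the test suite were measured at those sizes.

Limitations worth keeping in mind:

* The recovery property ("FDR-significant set equals truth, no false
  positives") is intrinsically marginal at 1% FDR with 30 nodes and a
  3-node truth set: the rank-4 step-up cutoff is 0.00133, so ≈2.7–3.5% of
  replicates contain a purely null-driven false positive regardless of the
  generator, and the weak row spill adds a little more. Expect ~94–97% of
  replicates false-positive-free, not 100%.
* Synthetic cohorts have homogeneous noise and a single shared template;
  real cohorts add site effects, registration error, and demographic
  structure that the generator does not model, so passing tests demonstrate
  correctness of the statistics, not field performance.
* MDMR here supports categorical designs only (no continuous covariates),
  and distances are limited to the Pearson/Spearman correlation forms.
* Patch connectivity is image similarity; no topological graph metrics are
  computed, and no anatomical (atlas) labeling of nodes is provided.
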