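# Methods

`connparc` implements a connectivity-based parcellation pipeline for a small
bilateral seed region (modeled on the substantia nigra, SN) together with its
downstream analyses, and a synthetic-data generator that plants the structure
each stage is supposed to recover. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic tests
do and do not establish about real data.

## Parcellation model

Each subject contributes a seed-voxel × target matrix of streamline counts
(the connectivity profile of every seed voxel, as produced upstream by
probabilistic tractography with ~5000 streamlines per voxel). Within one
hemisphere:

1. **Similarity.** Pearson correlation between voxel profiles. Rows with
   zero variance (empty tract maps) get similarity 0 to all other voxels
   and a warning, not an exception; a post-pass (`reassign_isolated`) can
   hand such voxels the label of their nearest spatial neighbor when
   coordinates are available. Counts enter raw; a log-transform before
   correlation is a config choice left to the caller, since the effect on
   rank-based block structure is minor for the count scales simulated here.
2. **Affinity.** Spectral clustering needs nonnegative affinities. The
   default dialect maps r → (r + 1)/2 (monotone, keeps anti-correlation
   information); `affinity="clip"` (max(r, 0)) is available for comparison.
3. **Spectral clustering.** Random-walk normalized Laplacian: the top-k
   eigenvectors of D⁻¹W (computed through the symmetric form
   D^(-1/2) W D^(-1/2), dense `eigh` — the seed has only a few hundred
   voxels) are clustered with k-means, 50 restarts at a fixed seed. The
   k-means is a vectorized multi-restart Lloyd implementation: all restarts
   advance in parallel, restarts stop when their labels stabilize,
   equidistant points go to the lowest-index centroid, an emptied cluster is
   re-seeded with the point farthest from its centroid, and the
   lowest-inertia restart wins with ties going to the lowest restart index.
   Everything is deterministic given the seed, and invariant to voxel order
   up to label permutation.
4. **Group consensus.** Each subject's parcellation becomes a binary
   co-assignment matrix S (S_ij = 1 iff voxels i, j share a cluster); the
   subject-mean consensus matrix (entries = co-assignment frequency, already
   a valid nonnegative affinity) is re-clustered at the same k to give the
   group parcellation.

Labels are 1..k throughout; 0 is reserved for background/unassigned in
label volumes.

## Choosing the number of subdivisions

Stability selection: the subject group is split into two non-overlapping
halves 100 times; at every K in 2..8 the two half-group parcellations are
compared with three partition indices —

* **NMI** 2·I(a;b)/(H(a)+H(b)) (arithmetic normalization; max-normalization
  switchable). Two single-cluster partitions score 1; a single-cluster
  partition against a non-trivial one scores 0 (continuity of
  "identical ⇒ 1").
* **Matched Dice**: Hungarian assignment on the pairwise Dice matrix, then
  the unweighted mean of matched-pair Dice values. Matching on the Dice
  matrix (rather than raw overlap counts) makes the index symmetric in its
  two arguments. Dice needs equal cluster counts; a repeat where the halves
  disagree is recorded as missing for Dice only.
* **Cramér's V** sqrt(χ²/(n·(min(r,c)−1))) on the label contingency table.

The three per-K mean curves are rank-transformed across K (scale-free) and
averaged; K is selected at the strict local peak with the highest
rank-averaged stability (ties → smaller K). Endpoints of the K range can be
peaks against their single neighbor, but an endpoint selection — like the
fallback to the global maximum when no strict peak exists — sets a flag in
the report, because the curve may continue rising outside the scanned range.
Inter-hemispheric similarity (NMI between left labels and mirrored right
labels over mirror-paired voxels) is computed as an additional stability
signal but does not enter the peak rule.

With an odd subject count the shuffled-out last subject is simply dropped
for that repeat. Per-subject parcellations are computed once per K and
cached; only the consensus averaging and the final clustering depend on the
split, which is what makes 100 repeats over seven K values affordable.

## Projection maps

Per-subdivision whole-brain streamline-count volumes (10,000 launched
streamlines per subdivision) are normalized to relative tracing strength
count/total and thresholded at 0.001 (10 of 10,000) to remove tracking
noise. Population maps hold the fraction of subjects whose thresholded map
includes each voxel, zeroed below 50%. The maximum probability map (MPM)
binarizes each subdivision's group map at 0.01, takes the union as the
connectome mask, and labels each voxel in it by the subdivision with the
highest group connectivity (ties → lowest subdivision index, logged;
outside-mask voxels → 0). Raising the binarization threshold can only
shrink the mask. The group map fed to the MPM is the population-fraction
map by default (the mean relative map is an equally valid choice the caller
can make; the normalization "per subdivision launch total" keeps the
printed 0.001 = 10/10,000 example exact, and a per-voxel-seeding variant
dividing by n_voxels × streams-per-voxel is available in the same
function by passing that product as the total).

Subject-level subdivision assignments are aggregated into per-voxel
assignment probabilities after matching each subject's clusters to the
group clusters by the same Hungarian/Dice matching; rows are probability
vectors by construction.

## Fingerprints

Raw tracing strength from subdivision s to atlas target t is
count/(size_s · size_t · total_streams). Column-normalizing over
subdivisions yields, per target, the proportion of its total seed
connectivity contributed by each subdivision; targets with no seed
connectivity are flagged undefined rather than imputed 0/0. Group
fingerprints average per-subject proportions (the alternative — proportions
of subject-mean strengths — is obtained by averaging raw strengths and
normalizing once). The atlas is any integer label volume plus names.

## Task contrasts and univariate statistics

From per-subject, per-ROI effect sizes under reward and punishment:
value = reward − punishment, salience = (reward + punishment)/2, exactly
(no tolerance beyond machine arithmetic). When a neutral condition exists a
versus-neutral salience can be formed by the caller; the average form is
what feeds the multivariate analysis. One-sample t statistics flag
zero-variance inputs instead of dividing by zero. Behavior correlations
exclude subjects outside 2 SD of the mean on any behavioral measure
(jointly over measures), require ≥ 10 retained subjects, and control the
ROI family per measure with Holm–Bonferroni step-down; dependent
correlation differences are assessed by a subject-resampling bootstrap.

## Behavioral PLS

X (n × p brain) and Y (n × q behavior) are z-scored column-wise; the SVD of
the q × p cross-correlation matrix R = U S Vᵀ yields latent variables
pairing behavior weights (U) with brain weights (V). Signs are fixed by
making the largest-magnitude brain weight positive per LV. Effect size per
LV is s²/Σs². Significance: subject rows of Y are permuted (default 1000
times; the fit recomputes R and its singular values each time) and
p = (#{s_perm ≥ s} + 1)/(n_perm + 1) — the add-one form avoids an
impossible exact zero at finite n_perm. Reliability: subjects are resampled
with replacement (default 1000); each resample's weights are aligned to the
originals by orthogonal Procrustes rotation of the stacked (U; V) matrix
before accumulating, and bootstrap ratios = original weight / bootstrap SE
are thresholded at 1.96 (≈ z-score under approximate normality).
Percentile CIs are returned for weights and for the per-LV brain-behavior
score correlations. Latent scores are projections of the standardized data
onto the weights.

**A calibration caveat, measured rather than assumed.** When no real
brain-behavior signal exists, the singular vectors of R are not identified
(R is pure noise), and bootstrap SEs of their entries are not calibrated:
aligning resamples to the original (Procrustes or sign-flip) shrinks the
bootstrap scatter toward the data's arbitrary direction and makes
|ratio| > 1.96 fire an order of magnitude above the nominal 5%, while
skipping alignment (each resample keeping only its internal sign
convention, `align="none"`) over-disperses the scatter and is conservative
(~1%). The 1.96 threshold is therefore trustworthy only for LVs that carry
signal (e.g. a significant permutation p); the package keeps the
conventional Procrustes default, exposes `sign` and `none` dialects, and
the test suite documents the measured null behavior. The permutation test,
by contrast, is calibrated under the null (empirical rejection ≈ 5% at
α = 0.05) and is the gate to interpret first.

## Synthetic data: what it emulates, and what it does not

* **Seed geometry**: the n closest lattice points to a hemisphere center
  (a compact blob), exactly mirrored into the other hemisphere; 150 voxels
  per hemisphere matches the ~300 mm³-per-hemisphere scale of the real SN
  mask at 1.25 mm. Voxel storage order is shuffled so nothing can rely on
  spatial ordering.
* **Connectivity profiles**: k_true = 3 mirror-symmetric contiguous slabs
  per hemisphere; prototype profiles are flat with a 10× elevation on a
  per-cluster block of 500 targets. Counts are Dirichlet-multinomial: per
  subject and voxel, the prototype proportions are perturbed by a Dirichlet
  draw with concentration prototype/noise_scale, then 5000 streamlines are
  multinomially assigned. The default noise_scale = 0.005 puts the
  within-cluster profile correlation near 0.35 — recoverable but far from
  clean, so half-group parcellations at the wrong K genuinely disagree
  (near noise_scale 0 even K = 2 becomes perfectly reproducible, because
  the merge of two true clusters is deterministic, and stability no longer
  discriminates K). noise_scale = 0 short-circuits to exact
  prototype-proportional counts for noiseless oracle tests. There is no
  spatial autocorrelation beyond cluster membership, no distance or
  curvature bias, and no partial-volume effect — passing recovery tests
  shows the algorithms are correct under the planted model, not that real
  tractography counts satisfy that model.
* **Tract-count volumes**: one smooth spatial bump per subdivision; every
  launched streamline visits exactly 20 voxels (WAYPOINT_FACTOR), so
  per-subdivision counts sum to total_streams × 20 — a crude but bounded
  stand-in for streamline path lengths.
* **Brain-behavior data**: one standard-normal latent trait loads on both
  sides with amplitude sqrt(latent_strength); columns are topped up to unit
  variance, making the population cross-correlation exactly
  latent_strength · outer(behavior_weights, brain_weights). Defaults —
  latent_strength 0.2, n = 450, p = 7, q = 2, brain weights concentrated on
  3 of 7 regions, behavior weights (0.8, −0.6) — reproduce the
  correlation-of-order-0.1 regime the method is used in, where effects are
  real but individual-subject prediction is hopeless.

## Problem sizes used by the test suite and acceptance script

Recovery and stability checks run at 150 voxels/hemisphere, 20 subjects,
500 targets; model-selection replication uses 20 independent datasets at
100 split-half repeats each; PLS calibration uses 200 null datasets
(n = 200) at 500 permutations / 200 bootstraps, and recovery 50 datasets at
n = 450. These sizes make every stochastic check reproducible on a single
CPU in minutes while keeping Monte-Carlo standard errors small relative to
the asserted margins.

## Known limitations

* Bootstrap ratios under a signal-free decomposition (above).
* The matched-Dice index is undefined across different cluster counts by
  design; reports carry an explicit missing count instead.
* The spectral embedding uses a dense eigensolver — appropriate for seeds
  of a few hundred voxels, not for whole-brain parcellation.
* The generator's Dirichlet-multinomial noise is a modeling choice, not an
  inference about the noise distribution of real streamline counts.
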