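# connparc

Connectivity-based parcellation of a small bilateral brain nucleus and the
analyses that follow from it, as used to subdivide the human substantia
nigra (SN) from diffusion-MRI tractography: spectral clustering of voxel
connectivity profiles, split-half stability selection of the subdivision
count, probabilistic and winner-takes-all projection maps, connectivity
fingerprints against an atlas, value/salience task contrasts, and a
behavioral partial-least-squares (PLS) analysis linking regional brain
responses to impulsivity measures.

The package is aimed at researchers who want the *analysis machinery* of
such a study as tested, reusable code. No restricted subject data is
required or bundled: a first-class synthetic-data module generates every
input with planted ground truth (cluster structure, mirrored hemispheres,
nonnegative streamline counts, a low-rank brain-behavior correlation), so
every stage can be validated by recovery, calibration, and oracle tests.

## The method in brief

**Parcellation.** For each subject and hemisphere, a seed-voxel × target
streamline-count matrix is turned into a voxel similarity matrix by Pearson
correlation of rows; normalized spectral clustering (random-walk Laplacian,
k-means with 50 restarts) of the affinity (r+1)/2 yields k subdivisions.
Subject partitions are combined through binary co-assignment (consensus)
matrices, S_ij = 1 iff voxels i and j share a cluster; the subject-mean
consensus matrix is re-clustered to give the group parcellation.

**Model selection.** The group is split in half 100 times; the two
half-group parcellations at each K ∈ {2..8} are compared with NMI
(2I/(H₁+H₂)), cluster-matched Dice, and Cramér's V. K is selected at the
strict local peak of the rank-averaged stability curve; inter-hemispheric
NMI over mirror-paired voxels is an additional stability readout.

**Projection maps.** Per-subdivision tract maps are normalized to relative
strength count/10,000, thresholded at 0.001, aggregated into population
maps (≥ 50% of subjects), and combined winner-takes-all into a maximum
probability map (MPM) over the union of maps binarized at 0.01.

**Fingerprints.** strength(s,t) = count/(size_s·size_t·total_streams),
column-normalized into the proportion of each target's seed connectivity
contributed by each subdivision.

**Behavioral PLS.** With X (n×p ROI contrasts) and Y (n×q behavior scores)
z-scored, the SVD of corr(Y, X) = U S Vᵀ gives latent variables; effect
size per LV is s²/Σs²; significance comes from permuting subjects
(p = (#{s_perm ≥ s}+1)/(n_perm+1)) and weight reliability from bootstrap
ratios (weight / bootstrap SE, |ratio| > 1.96), with Procrustes alignment
of resampled singular vectors. See `docs/methods.md` for the measured
caveat on bootstrap ratios when no signal is present.

## Worked example

```python
import numpy as np
from connparc import (make_seed_geometry, make_planted_truth,
                      simulate_connectivity, build_similarity,
                      spectral_parcellate, group_parcellation,
                      split_half_stability, select_k, nmi,
                      simulate_brain_behavior, BehavioralPLS)

geo = make_seed_geometry(150, rng_seed=1)          # ~300-voxel bilateral seed
truth = make_planted_truth(geo)                    # 3 planted subdivisions
conns = simulate_connectivity(geo, truth, n_subjects=20, rng_seed=2)
left = [c.subset(geo.indices("left")) for c in conns]

report = split_half_stability(left, k_range=range(2, 9),
                              n_repeats=100, rng_seed=3)
k = select_k(report)
print("selected K:", k)
print(report.table.loc[k, ["nmi_mean", "dice_mean", "cramers_v_mean"]])

parcs = [spectral_parcellate(build_similarity(c), k, rng_seed=0) for c in left]
group = group_parcellation(parcs, k, rng_seed=0)
print("NMI vs planted labels:",
      nmi(group.labels, truth.labels_true[geo.indices("left")]))

X, Y = simulate_brain_behavior(450, 7, 2, truth, rng_seed=4)
pls = BehavioralPLS(n_perm=500, n_boot=500, random_state=5).fit(X, Y)
print("effect sizes:", np.round(pls.effect_sizes_, 3))
print("LV1 permutation p:", pls.perm_pvalues_[0])
print("LV1 score correlation:", round(pls.score_correlations_[0], 3))
```

Output:

```
selected K: 3
nmi_mean          1.0
dice_mean         1.0
cramers_v_mean    1.0
Name: 3, dtype: float64
NMI vs planted labels: 1.0
effect sizes: [0.727 0.273]
LV1 permutation p: 0.027944111776447105
LV1 score correlation: 0.194
```

The stability curve peaks at the planted K = 3 with perfect split-half
agreement, the group parcellation recovers the planted subdivisions exactly
(NMI = 1), and PLS finds a dominant first latent variable (73% of
cross-block covariance, permutation p ≈ 0.028) whose brain-behavior score
correlation (0.19) sits in the weak-correlation regime the generator
plants (latent strength 0.2).

A command-line interface mirrors the stages
(`connparc simulate|parcellate|group|stability|maps|fingerprint|contrasts|pls|run`);
`connparc run --out results/ --seed 0` executes the whole pipeline on
synthetic data and writes a manifest with SHA-256 checksums of every
artifact, so a rerun with the same config is verifiably identical.

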