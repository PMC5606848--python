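"""Synthetic data generators with planted structure.

Every downstream stage of the pipeline (parcellation, stability selection,
projection maps, fingerprints, behavioral PLS) is exercised on data produced
here, so each generator plants a known ground truth that recovery tests can
score against:

* a mirrored two-hemisphere seed geometry standing in for a bilateral
  midbrain mask (~150 voxels per hemisphere at 1.25 mm emulates a ~300 mm^3
  substantia-nigra mask),
* K-cluster block structure in voxel connectivity profiles, with
  Dirichlet-multinomial count noise per subject and per voxel,
* nonnegative streamline-count volumes per seed subdivision, and
* a brain/behavior dataset with a planted rank-one latent cross-correlation
  of prescribed strength.

All generators are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .parcellation import ConnectivityProfileMatrix

__all__ = [
    "SeedGeometry",
    "PlantedTruth",
    "make_seed_geometry",
    "make_planted_truth",
    "simulate_connectivity",
    "simulate_tract_counts",
    "simulate_brain_behavior",
    "simulate_roi_conditions",
    "WAYPOINT_FACTOR",
    "DEFAULT_STREAMS_PER_VOXEL",
    "DEFAULT_TOTAL_STREAMS",
]

#: Streamlines launched from each seed voxel during per-voxel tractography.
DEFAULT_STREAMS_PER_VOXEL = 5000

#: Streamlines launched from each subdivision during whole-brain tractography.
DEFAULT_TOTAL_STREAMS = 10_000

#: Upper bound on the number of voxels a single streamline may visit; the
#: per-subdivision sum of simulated visit counts is exactly
#: ``total_streams * WAYPOINT_FACTOR`` and therefore bounded by it.
WAYPOINT_FACTOR = 20


@dataclass(frozen=True)
class SeedGeometry:
    """Mirrored two-hemisphere voxel grid for the seed region.

    Attributes
    ----------
    voxel_coords : (n, 3) int array
        Integer grid coordinates; left-hemisphere voxels have negative x,
        right-hemisphere voxels positive x.
    hemisphere : (n,) str array
        ``"left"`` or ``"right"`` per voxel.
    mirror_map : (m, 2) int array
        Pairs ``(left_index, right_index)`` of voxels related by x-reflection
        (reflected x, equal y and z). May be a partial pairing.
    """

    voxel_coords: np.ndarray
    hemisphere: np.ndarray
    mirror_map: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.voxel_coords)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("voxel_coords must be an (n, 3) array")
        for hemi in ("left", "right"):
            sub = coords[self.hemisphere == hemi]
            if len(sub) != len({tuple(c) for c in sub}):
                raise ValueError(f"duplicate coordinates in {hemi} hemisphere")
        mm = np.asarray(self.mirror_map)
        if mm.size:
            if len(np.unique(mm[:, 0])) != len(mm) or len(np.unique(mm[:, 1])) != len(mm):
                raise ValueError("mirror_map must be injective")
            left, right = coords[mm[:, 0]], coords[mm[:, 1]]
            if not (np.array_equal(left[:, 0], -right[:, 0])
                    and np.array_equal(left[:, 1:], right[:, 1:])):
                raise ValueError("mirrored pairs must have reflected x and equal y,z")

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_coords)

    def indices(self, hemisphere: str) -> np.ndarray:
        """Indices of the voxels in one hemisphere, in storage order."""
        return np.flatnonzero(self.hemisphere == hemisphere)


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by the generators, used by recovery tests.

    ``labels_true`` holds one cluster label (1..k_true) per voxel, aligned to
    a :class:`SeedGeometry`; ``prototypes`` holds the k_true mean connectivity
    profiles; ``brain_weights`` / ``behavior_weights`` are the unit-norm
    saliences of the planted brain-behavior latent factor and
    ``latent_strength`` its cross-correlation scale (in [0, 1]).
    """

    k_true: int
    labels_true: np.ndarray
    prototypes: np.ndarray
    noise_scale: float
    brain_weights: np.ndarray
    behavior_weights: np.ndarray
    latent_strength: float = 0.2

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels_true)
        if len(np.unique(labels)) != self.k_true:
            raise ValueError("labels_true must take exactly k_true distinct values")
        proto = np.asarray(self.prototypes, dtype=float)
        if proto.ndim != 2 or proto.shape[0] != self.k_true:
            raise ValueError("prototypes must be a (k_true, n_targets) matrix")
        if np.any(proto < 0):
            raise ValueError("prototypes must be nonnegative")
        for a in range(self.k_true):
            for b in range(a + 1, self.k_true):
                if np.array_equal(proto[a], proto[b]):
                    raise ValueError("prototype rows must be pairwise non-identical")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be nonnegative")
        if not 0.0 <= self.latent_strength <= 1.0:
            raise ValueError("latent_strength must lie in [0, 1]")
        for name in ("brain_weights", "behavior_weights"):
            w = np.asarray(getattr(self, name), dtype=float)
            if not np.isclose(np.linalg.norm(w), 1.0):
                raise ValueError(f"{name} must have unit norm")


def make_seed_geometry(n_per_hemisphere: int, rng_seed: int = 0) -> SeedGeometry:
    """Build a compact, mirror-symmetric two-hemisphere voxel blob.

    Voxels in each hemisphere are the ``n_per_hemisphere`` lattice points
    closest to a hemisphere center (a rough ball, like a small nucleus);
    the right hemisphere is the exact x-reflection of the left, so the
    mirror map is a complete pairing. Voxel storage order is randomly
    permuted (seeded) so downstream code cannot silently rely on spatial
    ordering.
    """
    if n_per_hemisphere <= 0:
        raise ValueError("n_per_hemisphere must be positive")
    rng = np.random.default_rng(rng_seed)

    # candidate lattice: generous cube around the left-hemisphere center
    r = int(np.ceil((n_per_hemisphere * 3.0) ** (1.0 / 3.0))) + 2
    center = np.array([-(r + 1), 0, 0], dtype=float)
    grid = np.stack(np.meshgrid(
        np.arange(-2 * r - 1, 0),          # x strictly negative: left side
        np.arange(-r, r + 1),
        np.arange(-r, r + 1),
        indexing="ij"), axis=-1).reshape(-1, 3)
    d2 = ((grid - center) ** 2).sum(axis=1)
    # deterministic tie-break: distance, then lexicographic coordinate
    order = np.lexsort((grid[:, 2], grid[:, 1], grid[:, 0], d2))
    left = grid[order[:n_per_hemisphere]]
    right = left * np.array([-1, 1, 1])

    coords = np.vstack([left, right])
    hemisphere = np.array(["left"] * n_per_hemisphere + ["right"] * n_per_hemisphere)
    mirror = np.column_stack([np.arange(n_per_hemisphere),
                              np.arange(n_per_hemisphere) + n_per_hemisphere])

    perm = rng.permutation(2 * n_per_hemisphere)
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    return SeedGeometry(voxel_coords=coords[perm], hemisphere=hemisphere[perm],
                        mirror_map=inv[mirror])


def make_planted_truth(
    geometry: SeedGeometry,
    k_true: int = 3,
    n_targets: int = 500,
    noise_scale: float = 0.005,
    block_boost: float = 10.0,
    latent_strength: float = 0.2,
    n_brain: int = 7,
    n_behavior: int = 2,
    rng_seed: int = 0,
) -> PlantedTruth:
    """Plant mirror-symmetric contiguous clusters and a latent factor.

    Cluster labels are assigned by slicing each hemisphere into ``k_true``
    contiguous slabs along y (mirror-paired voxels share y and z, so the two
    hemispheres receive mirror-symmetric labels). Prototype profiles are flat
    with a ``block_boost``-fold elevation on a per-cluster block of targets;
    with the default boost and ``noise_scale`` the within-cluster profile
    correlation sits near 0.35 — structure that is clear but far from
    noiseless, so half-group parcellations at the wrong K genuinely disagree.

    Brain-side latent weights load on the first three of ``n_brain`` regions;
    behavior-side weights are ``(0.8, -0.6)``-style over ``n_behavior``
    measures (opposite signs, as when one impulsivity score rises and the
    other falls with the same latent trait).
    """
    if k_true < 2:
        raise ValueError("k_true must be at least 2")
    if n_targets < k_true:
        raise ValueError("n_targets must be at least k_true")
    del rng_seed  # construction is fully deterministic; kept for API symmetry

    labels = np.zeros(geometry.n_voxels, dtype=int)
    left = geometry.indices("left")
    keys = np.abs(geometry.voxel_coords[left])  # |x| so both sides sort alike
    order = left[np.lexsort((keys[:, 0], keys[:, 2], keys[:, 1]))]  # slabs along y
    for c, chunk in enumerate(np.array_split(order, k_true)):
        labels[chunk] = c + 1
    # right hemisphere labels are copied through the mirror pairing; any
    # unpaired right voxel inherits the label of the nearest mirrored left one
    for li, ri in geometry.mirror_map:
        labels[ri] = labels[li]
    right = geometry.indices("right")
    unpaired = right[labels[right] == 0]
    if unpaired.size:
        mirrored_left = geometry.voxel_coords[left] * np.array([-1, 1, 1])
        for v in unpaired:
            d2 = ((mirrored_left - geometry.voxel_coords[v]) ** 2).sum(axis=1)
            labels[v] = labels[left[np.argmin(d2)]]

    prototypes = np.ones((k_true, n_targets))
    for c, block in enumerate(np.array_split(np.arange(n_targets), k_true)):
        prototypes[c, block] += block_boost - 1.0

    wx = np.zeros(n_brain)
    wx[: min(3, n_brain)] = 1.0
    wx /= np.linalg.norm(wx)
    wy = np.array([0.8, -0.6] + [0.0] * (n_behavior - 2)) if n_behavior >= 2 \
        else np.ones(n_behavior)
    wy /= np.linalg.norm(wy)

    return PlantedTruth(k_true=k_true, labels_true=labels, prototypes=prototypes,
                        noise_scale=noise_scale, brain_weights=wx, behavior_weights=wy,
                        latent_strength=latent_strength)


def simulate_connectivity(
    geometry: SeedGeometry,
    truth: PlantedTruth,
    n_subjects: int,
    streams_per_voxel: int = DEFAULT_STREAMS_PER_VOXEL,
    rng_seed: int = 0,
) -> list[ConnectivityProfileMatrix]:
    """Draw per-subject seed-voxel x target streamline-count matrices.

    Each voxel's expected profile is its cluster prototype. Noise has two
    stages, respecting the integer fixed-total nature of probabilistic
    tractography counts: the prototype proportions are perturbed by a
    Dirichlet draw with concentration ``prototype / noise_scale`` (one draw
    per subject per voxel — subject variability, no spatial autocorrelation
    beyond cluster membership), then ``streams_per_voxel`` streamlines are
    assigned to target bins by a multinomial draw. ``noise_scale = 0``
    short-circuits both stages and yields the exact prototype-proportional
    counts for every subject.
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    if streams_per_voxel <= 0:
        raise ValueError("streams_per_voxel must be positive")
    if len(truth.labels_true) != geometry.n_voxels:
        raise ValueError("truth labels do not cover the geometry's voxels")

    proto = np.asarray(truth.prototypes, dtype=float)
    probs = proto / proto.sum(axis=1, keepdims=True)
    n_targets = proto.shape[1]
    target_ids = np.arange(n_targets)
    seed_ids = np.arange(geometry.n_voxels)

    subjects = []
    for child in np.random.SeedSequence(rng_seed).spawn(n_subjects):
        rng = np.random.default_rng(child)
        counts = np.empty((geometry.n_voxels, n_targets))
        for v in range(geometry.n_voxels):
            p = probs[truth.labels_true[v] - 1]
            if truth.noise_scale == 0:
                counts[v] = np.rint(streams_per_voxel * p)
            else:
                q = rng.dirichlet(p / truth.noise_scale)
                counts[v] = rng.multinomial(streams_per_voxel, q)
        subjects.append(ConnectivityProfileMatrix(
            counts=counts, seed_ids=seed_ids, target_ids=target_ids))
    return subjects


def _bump_profiles(n_subdivisions: int, shape: tuple[int, int, int],
                   rng: np.random.Generator) -> np.ndarray:
    """Smooth nonnegative visit-intensity profiles, one 3-D bump per subdivision."""
    axes = np.indices(shape).reshape(3, -1).T.astype(float)
    span = np.array(shape, dtype=float)
    centers = rng.uniform(0.2, 0.8, size=(n_subdivisions, 3)) * span
    width = span.mean() / 3.0
    d2 = ((axes[None, :, :] - centers[:, None, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * width ** 2)).reshape(n_subdivisions, *shape)


def tract_volume_shape(n_brain_voxels: int) -> tuple[int, int, int]:
    """Smallest near-cubic grid holding at least ``n_brain_voxels`` voxels."""
    side = int(np.ceil(n_brain_voxels ** (1.0 / 3.0)))
    return (side, side, max(1, int(np.ceil(n_brain_voxels / side ** 2))))


def simulate_tract_counts(
    n_subdivisions: int,
    n_brain_voxels: int,
    n_subjects: int,
    total_streams: int = DEFAULT_TOTAL_STREAMS,
    rng_seed: int = 0,
    profiles: np.ndarray | None = None,
) -> np.ndarray:
    """Draw per-subject, per-subdivision whole-brain streamline-count volumes.

    Returns an array of shape ``(n_subjects, n_subdivisions, nx, ny, nz)``.
    A streamline visits several voxels on its way, so voxel counts may sum
    to more than the number of launched streamlines; here every streamline
    visits exactly :data:`WAYPOINT_FACTOR` voxels, so each subject/subdivision
    volume sums to ``total_streams * WAYPOINT_FACTOR`` (the documented bound).

    ``profiles`` optionally supplies the planted visit intensities
    (``n_subdivisions`` x volume, nonnegative); an all-zero profile produces
    an all-zero count volume. By default, one smooth spatial bump per
    subdivision is drawn from the seed.
    """
    if total_streams < 1:
        raise ValueError("total_streams must be >= 1")
    if n_subdivisions <= 0 or n_brain_voxels <= 0 or n_subjects <= 0:
        raise ValueError("sizes must be positive")

    shape = tract_volume_shape(n_brain_voxels)
    rng = np.random.default_rng(rng_seed)
    if profiles is None:
        profiles = _bump_profiles(n_subdivisions, shape, rng)
    else:
        profiles = np.asarray(profiles, dtype=float)
        if profiles.shape[0] != n_subdivisions:
            raise ValueError("profiles must have one volume per subdivision")
        shape = profiles.shape[1:]
        if np.any(profiles < 0):
            raise ValueError("profiles must be nonnegative")

    flat = profiles.reshape(n_subdivisions, -1)
    out = np.zeros((n_subjects, n_subdivisions) + tuple(shape), dtype=np.int64)
    n_visits = total_streams * WAYPOINT_FACTOR
    for s, child in enumerate(np.random.SeedSequence(rng_seed).spawn(n_subjects)):
        subj_rng = np.random.default_rng(child)
        # mild per-subject amplitude jitter, renormalized, so subjects differ
        jitter = subj_rng.lognormal(mean=0.0, sigma=0.2, size=flat.shape)
        for d in range(n_subdivisions):
            intensity = flat[d] * jitter[d]
            total = intensity.sum()
            if total == 0:
                continue
            out[s, d] = subj_rng.multinomial(n_visits, intensity / total).reshape(shape)
    return out


def simulate_brain_behavior(
    n: int,
    p_brain: int,
    q_behavior: int,
    truth: PlantedTruth,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw aligned brain (n x p) and behavior (n x q) matrices.

    A single standard-normal latent trait ``z`` loads on both sides with
    amplitude ``sqrt(latent_strength)``; independent Gaussian noise tops each
    column up to unit population variance. The population cross-correlation
    matrix is therefore exactly
    ``latent_strength * outer(behavior_weights, brain_weights)``.
    """
    if n < 3:
        raise ValueError("n must be at least 3 (correlations undefined below)")
    wx = np.asarray(truth.brain_weights, dtype=float)
    wy = np.asarray(truth.behavior_weights, dtype=float)
    if len(wx) != p_brain or len(wy) != q_behavior:
        raise ValueError("latent weight lengths must match p_brain / q_behavior")

    rng = np.random.default_rng(rng_seed)
    s = np.sqrt(truth.latent_strength)
    z = rng.standard_normal(n)
    X = s * np.outer(z, wx) + rng.standard_normal((n, p_brain)) \
        * np.sqrt(1.0 - (s * wx) ** 2)
    Y = s * np.outer(z, wy) + rng.standard_normal((n, q_behavior)) \
        * np.sqrt(1.0 - (s * wy) ** 2)
    return X, Y


def simulate_roi_conditions(
    value: np.ndarray,
    roi_names: list[str] | None = None,
    rng_seed: int = 0,
):
    """Expand per-subject ROI value signals into a tidy ROI x condition table.

    Given the planted value contrasts (subjects x ROIs, e.g. the brain matrix
    from :func:`simulate_brain_behavior`), draws an independent salience level
    per cell and emits reward/punishment effect sizes with
    ``reward - punishment == value`` and ``(reward + punishment)/2 ==
    salience`` exactly, so the downstream contrast construction recovers the
    planted signals to machine precision.
    """
    import pandas as pd

    value = np.asarray(value, dtype=float)
    n, p = value.shape
    if roi_names is None:
        roi_names = [f"roi{i + 1}" for i in range(p)]
    rng = np.random.default_rng(rng_seed)
    salience = rng.standard_normal((n, p))
    reward = salience + value / 2.0
    punishment = salience - value / 2.0
    rows = []
    for i in range(n):
        for j, roi in enumerate(roi_names):
            rows.append((i, roi, "reward", reward[i, j]))
            rows.append((i, roi, "punishment", punishment[i, j]))
    return pd.DataFrame(rows, columns=["subject", "roi", "condition", "effect_size"])
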