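"""Connectivity-based parcellation of a seed region.

A subject's seed-voxel x target streamline-count matrix is turned into a
voxel-by-voxel Pearson similarity matrix, clustered with normalized spectral
clustering, and summarized across subjects through binary co-assignment
(consensus) matrices whose average is re-clustered to give the group
parcellation. Parcellation always operates within one hemisphere.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator, ClusterMixin

from .errors import DegenerateInputError

__all__ = [
    "ConnectivityProfileMatrix",
    "Parcellation",
    "SpectralParcellator",
    "build_similarity",
    "spectral_parcellate",
    "consensus_matrix",
    "group_parcellation",
    "reassign_isolated",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConnectivityProfileMatrix:
    """Seed-voxel x target streamline counts for one subject.

    ``counts[i, j]`` is the number of streamlines seeded at voxel
    ``seed_ids[i]`` that reached target ``target_ids[j]`` — row i is the
    connectivity profile of seed voxel i.
    """

    counts: np.ndarray
    seed_ids: np.ndarray
    target_ids: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (n_seed x n_target)")
        if counts.shape[0] < 2:
            raise ValueError("need at least 2 seed voxels")
        if np.any(counts < 0):
            raise ValueError("streamline counts cannot be negative")
        if len(self.seed_ids) != counts.shape[0] or len(self.target_ids) != counts.shape[1]:
            raise ValueError("seed_ids / target_ids do not match counts shape")
        object.__setattr__(self, "counts", counts)

    def subset(self, rows: np.ndarray) -> "ConnectivityProfileMatrix":
        """Restrict to a subset of seed voxels (e.g. one hemisphere)."""
        rows = np.asarray(rows)
        return ConnectivityProfileMatrix(
            counts=self.counts[rows], seed_ids=np.asarray(self.seed_ids)[rows],
            target_ids=self.target_ids)


@dataclass
class Parcellation:
    """Cluster label (1..k) per seed voxel, with provenance tags."""

    labels: np.ndarray
    k: int
    hemisphere: str = "both"
    subject: str = "group"

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=int)
        present = np.unique(labels)
        if not np.array_equal(present, np.arange(1, self.k + 1)):
            raise ValueError("labels must take every value in 1..k (no empty cluster)")
        self.labels = labels

    @property
    def n_voxels(self) -> int:
        return len(self.labels)


def _as_labels(parc) -> np.ndarray:
    return parc.labels if isinstance(parc, Parcellation) else np.asarray(parc, dtype=int)


def build_similarity(conn: ConnectivityProfileMatrix | np.ndarray,
                     log_transform: bool = False) -> np.ndarray:
    """Pearson correlation between seed-voxel connectivity profiles.

    ``log_transform`` correlates log(1 + count) instead of raw counts — a
    dialect for data whose count distribution is heavy-tailed enough that a
    few huge targets would dominate the correlation. Rows with zero variance
    (a voxel whose tract-count map is empty or flat) get similarity 0 to
    every other voxel, with a logged warning, rather than raising; the
    diagonal stays 1 everywhere.
    """
    counts = conn.counts if isinstance(conn, ConnectivityProfileMatrix) \
        else np.asarray(conn, dtype=float)
    if log_transform:
        counts = np.log1p(counts)
    if counts.ndim != 2 or counts.shape[0] < 2:
        raise ValueError("need an (n_seed >= 2) x n_target matrix")
    sd = counts.std(axis=1)
    flat = sd == 0
    if flat.any():
        msg = f"{int(flat.sum())} zero-variance profile row(s); similarities set to 0"
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.corrcoef(counts)
    sim[flat, :] = 0.0
    sim[:, flat] = 0.0
    np.fill_diagonal(sim, 1.0)
    return np.clip(sim, -1.0, 1.0)


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel clusters 1..k in order of first occurrence (determinism)."""
    mapping: dict[int, int] = {}
    out = np.empty(len(raw), dtype=int)
    for i, lab in enumerate(raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def _kmeans_restarts(X: np.ndarray, k: int, n_init: int,
                     rng: np.random.Generator, max_iter: int = 100,
                     tol: float = 1e-10) -> np.ndarray:
    """Multi-restart Lloyd k-means, all restarts advanced in parallel.

    Restarts start from k distinct random points; the restart with the
    lowest inertia wins (ties: lowest restart index). Equidistant points go
    to the lowest-index centroid (argmin), and a cluster emptied during an
    update is re-seeded with the point farthest from its current centroid.
    The spectral embeddings clustered here are tiny (n <= a few hundred,
    dim = k), which is why a vectorized dense implementation is the right
    tool.
    """
    del tol  # convergence is detected by label stability, which is exact
    n = X.shape[0]
    if k == n:
        return np.arange(n)
    x2 = (X ** 2).sum(axis=1)
    centers = np.stack([X[rng.choice(n, size=k, replace=False)]
                        for _ in range(n_init)])  # (R, k, d)

    def _d2(c):
        return np.maximum(
            x2[None, :, None] + (c ** 2).sum(-1)[:, None, :]
            - 2.0 * np.einsum("nd,rkd->rnk", X, c), 0.0)

    labels = np.full((n_init, n), -1)
    active = np.arange(n_init)
    for _ in range(max_iter):
        d2 = _d2(centers[active])
        new_labels = d2.argmin(-1)
        changed = np.any(new_labels != labels[active], axis=1)
        labels[active] = new_labels
        active = active[changed]
        if active.size == 0:
            break
        sub = labels[active]
        onehot = sub[:, :, None] == np.arange(k)[None, None, :]
        counts = onehot.sum(axis=1)
        sums = np.einsum("rnk,nd->rkd", onehot, X)
        new = np.where(counts[:, :, None] > 0,
                       sums / np.maximum(counts[:, :, None], 1), centers[active])
        if np.any(counts == 0):
            d2a = d2[changed]
            assigned = np.take_along_axis(d2a, sub[:, :, None], axis=2)[:, :, 0]
            for r, j in zip(*np.nonzero(counts == 0)):
                new[r, j] = X[assigned[r].argmax()]
        centers[active] = new
    d2 = _d2(centers)
    inertia = np.take_along_axis(d2, labels[:, :, None], axis=2)[:, :, 0].sum(axis=1)
    best = labels[int(inertia.argmin())].copy()
    # guarantee k nonempty clusters even in degenerate geometries
    for j in range(k):
        if not np.any(best == j):
            free = np.flatnonzero(np.bincount(best, minlength=k)[best] > 1)
            best[free[-1]] = j
    return best


def _spectral_labels(affinity: np.ndarray, k: int, random_state, n_init: int = 50
                     ) -> np.ndarray:
    """Normalized (random-walk Laplacian) spectral clustering on an affinity.

    Embeds the voxels with the top-k eigenvectors of the random-walk
    transition operator D^-1 W (computed through the symmetric form
    D^-1/2 W D^-1/2) and clusters the embedding with k-means using ``n_init``
    restarts at a fixed seed. Returns canonical labels 1..k.
    """
    A = np.asarray(affinity, dtype=float)
    n = A.shape[0]
    if A.ndim != 2 or A.shape[1] != n:
        raise ValueError("affinity must be square")
    if np.any(A < 0):
        raise ValueError("affinity must be nonnegative")
    if not (2 <= k <= n):
        raise ValueError(f"k={k} outside valid range [2, {n}]")
    if not np.any(A):
        raise DegenerateInputError("affinity matrix is all-zero")

    d = A.sum(axis=1)
    d[d == 0] = 1.0  # isolated voxels keep a finite embedding coordinate
    d_isqrt = 1.0 / np.sqrt(d)
    M = d_isqrt[:, None] * A * d_isqrt[None, :]
    M = (M + M.T) / 2.0
    _, vecs = scipy.linalg.eigh(M, subset_by_index=(n - k, n - 1))
    embedding = d_isqrt[:, None] * vecs[:, ::-1]

    rng = np.random.default_rng(random_state)
    return _canonical_labels(_kmeans_restarts(embedding, k, n_init, rng))


class SpectralParcellator(ClusterMixin, BaseEstimator):
    """Spectral clustering of seed voxels by connectivity-profile similarity.

    Parameters
    ----------
    n_clusters : int
        Number of subdivisions k (the seed's small size keeps useful values
        in roughly 2..8 per hemisphere).
    affinity : {"shift", "clip", "precomputed"}
        How the Pearson similarity r is mapped to the nonnegative affinity
        spectral clustering needs: ``"shift"`` uses (r + 1)/2 (monotone,
        keeps anti-correlation information; the default dialect), ``"clip"``
        uses max(r, 0). ``"precomputed"`` treats X passed to :meth:`fit` as
        a ready nonnegative affinity (e.g. a consensus matrix).
    n_init : int
        k-means restarts on the spectral embedding.
    random_state : int or None
        Seed for k-means; fixing it makes the fit deterministic.

    Attributes
    ----------
    labels_ : (n_seed,) int array of cluster labels in 1..n_clusters.
    similarity_ : Pearson similarity matrix (absent for precomputed input).
    affinity_matrix_ : the nonnegative affinity that was clustered.
    """

    def __init__(self, n_clusters: int = 3, affinity: str = "shift",
                 n_init: int = 50, random_state: int | None = None):
        self.n_clusters = n_clusters
        self.affinity = affinity
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        data = X.counts if isinstance(X, ConnectivityProfileMatrix) else X
        if self.affinity == "precomputed":
            A = np.asarray(data, dtype=float)
        else:
            sim = build_similarity(data)
            self.similarity_ = sim
            if self.affinity == "shift":
                A = (sim + 1.0) / 2.0
            elif self.affinity == "clip":
                A = np.maximum(sim, 0.0)
            else:
                raise ValueError(f"unknown affinity dialect {self.affinity!r}")
        self.affinity_matrix_ = A
        self.labels_ = _spectral_labels(A, self.n_clusters, self.random_state,
                                        n_init=self.n_init)
        self.n_features_in_ = np.asarray(data).shape[1]
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def spectral_parcellate(sim: np.ndarray, k: int, rng_seed: int | None = 0,
                        hemisphere: str = "both", subject: str = "group",
                        precomputed_affinity: bool = False) -> Parcellation:
    """Cluster a similarity (or nonnegative affinity) matrix into k parcels.

    Thin wrapper over :class:`SpectralParcellator`; ``sim`` is a Pearson
    similarity in [-1, 1] mapped through the shift dialect unless
    ``precomputed_affinity`` marks it as already nonnegative.
    """
    sim = np.asarray(sim, dtype=float)
    A = sim if precomputed_affinity else (np.clip(sim, -1.0, 1.0) + 1.0) / 2.0
    labels = _spectral_labels(A, k, rng_seed)
    return Parcellation(labels=labels, k=k, hemisphere=hemisphere, subject=subject)


def consensus_matrix(parc: Parcellation | np.ndarray) -> np.ndarray:
    """Binary co-assignment matrix: S[i, j] = 1 iff voxels i, j share a cluster."""
    labels = _as_labels(parc)
    return (labels[:, None] == labels[None, :]).astype(float)


def group_parcellation(parcs: list, k: int, rng_seed: int | None = 0,
                       hemisphere: str = "both") -> Parcellation:
    """Group parcellation: average subject consensus matrices, re-cluster.

    The mean consensus matrix (entries in [0, 1] = fraction of subjects
    co-assigning each voxel pair) is fed directly to spectral clustering as
    the affinity.
    """
    if len(parcs) == 0:
        raise ValueError("need at least one subject parcellation")
    label_arrays = [_as_labels(p) for p in parcs]
    n = len(label_arrays[0])
    if any(len(lab) != n for lab in label_arrays):
        raise ValueError("all parcellations must cover the same voxel set")
    mean_consensus = np.mean([consensus_matrix(lab) for lab in label_arrays], axis=0)
    labels = _spectral_labels(mean_consensus, k, rng_seed)
    return Parcellation(labels=labels, k=k, hemisphere=hemisphere, subject="group")


def reassign_isolated(labels: np.ndarray, coords: np.ndarray,
                      isolated: np.ndarray) -> np.ndarray:
    """Give isolated voxels the label of their nearest non-isolated neighbor.

    Used as a post-pass for voxels whose connectivity profile was flat (their
    similarities were zeroed): spatial proximity stands in for the missing
    connectivity evidence. Ties go to the lowest voxel index.
    """
    labels = np.array(labels, dtype=int)
    isolated = np.asarray(isolated, dtype=bool)
    keep = np.flatnonzero(~isolated)
    if keep.size == 0:
        raise DegenerateInputError("every voxel is isolated; nothing to anchor to")
    coords = np.asarray(coords, dtype=float)
    for i in np.flatnonzero(isolated):
        d2 = ((coords[keep] - coords[i]) ** 2).sum(axis=1)
        labels[i] = labels[keep[np.argmin(d2)]]
    return labels
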