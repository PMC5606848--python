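"""Probabilistic subdivision maps, normalized tract maps, and the MPM.

Whole-brain tractograms seeded from each subdivision are normalized to
relative tracing strengths, noise-thresholded, aggregated into population
maps, and combined winner-takes-all into a maximum probability map (MPM).
Subject-level subdivision assignments are aggregated into a per-voxel
assignment-probability map over the population.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np

from .errors import DegenerateInputError
from .parcellation import Parcellation, _as_labels
from .stability import match_clusters

__all__ = [
    "probabilistic_map",
    "normalize_tract",
    "population_map",
    "max_probability_map",
]

logger = logging.getLogger(__name__)


def probabilistic_map(parcs: list, group: Parcellation) -> np.ndarray:
    """Per-voxel probability of subdivision assignment over the population.

    Each subject's cluster labels are first matched one-to-one to the group
    parcellation's labels by overlap-maximizing assignment; the returned
    (n_voxel, k) matrix holds, per voxel and group subdivision, the fraction
    of subjects assigning that voxel to that subdivision — a value of 1
    means every subject agrees. Rows sum to 1. Subjects whose cluster count
    differs from the group's are excluded with a warning.
    """
    group_labels = _as_labels(group)
    k = group.k if isinstance(group, Parcellation) else len(np.unique(group_labels))
    counts = np.zeros((len(group_labels), k))
    n_used = 0
    for s, parc in enumerate(parcs):
        labels = _as_labels(parc)
        if len(np.unique(labels)) != k:
            warnings.warn(f"subject {s}: cluster count differs from group; excluded",
                          RuntimeWarning, stacklevel=2)
            continue
        m = match_clusters(group_labels, labels)  # m[j] = group cluster for subj j+1
        relabeled = m[labels - 1] + 1
        counts[np.arange(len(labels)), relabeled - 1] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no subject parcellation could be matched to the group")
    return counts / n_used


def normalize_tract(counts: np.ndarray, total_streams: int,
                    noise_threshold: float = 0.001) -> np.ndarray:
    """Relative tracing strength: count / total_streams, noise-thresholded.

    With the default threshold 0.001 a voxel needs at least 10 of 10,000
    launched streamlines to survive — the standard cut that removes spurious
    single-streamline tracking noise. Values below the threshold are zeroed.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("streamline counts cannot be negative")
    if total_streams <= 0:
        raise ValueError("total_streams must be positive")
    if not 0.0 <= noise_threshold <= 1.0:
        raise ValueError("noise_threshold must lie in [0, 1]")
    rel = counts / float(total_streams)
    rel[rel < noise_threshold] = 0.0
    return rel


def population_map(maps: list[np.ndarray] | np.ndarray,
                   subject_fraction: float = 0.5) -> np.ndarray:
    """Fraction of subjects whose thresholded tract map includes each voxel.

    Voxels present in fewer than ``subject_fraction`` of subjects (default
    50%: at least half the subjects must show the tract) are zeroed.
    """
    stack = np.asarray(maps, dtype=float)
    if stack.shape[0] < 1:
        raise ValueError("need at least one subject map")
    frac = (stack > 0).mean(axis=0)
    frac[frac < subject_fraction] = 0.0
    return frac


def max_probability_map(group_maps: np.ndarray,
                        binarize_threshold: float = 0.01) -> np.ndarray:
    """Winner-takes-all subdivision labeling of the combined connectome mask.

    ``group_maps`` stacks one group-level tract map per subdivision along
    axis 0. Each subdivision's map is binarized at ``binarize_threshold``;
    the union of these masks is the connectome mask. Within it every voxel
    gets the label (1..k) of the subdivision with the highest group
    connectivity, ties broken deterministically toward the lowest
    subdivision index (and logged); voxels outside the mask are 0
    (unassigned).
    """
    stack = np.asarray(group_maps, dtype=float)
    if stack.ndim < 2:
        raise ValueError("group_maps must stack per-subdivision maps on axis 0")
    mask = (stack >= binarize_threshold).any(axis=0)
    if not mask.any():
        raise DegenerateInputError("no voxel survives the binarization threshold")
    winner = np.argmax(stack, axis=0) + 1
    n_tied = int((((stack == stack.max(axis=0)).sum(axis=0) > 1) & mask).sum())
    if n_tied:
        logger.info("%d voxel(s) had tied maximal connectivity; lowest index kept",
                    n_tied)
    return np.where(mask, winner, 0)
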