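"""Parcellation reproducibility scoring and subdivision-count selection.

The number of subdivisions K is chosen by repeatedly splitting the subject
group into two non-overlapping halves, building the group parcellation of
each half at every candidate K, and scoring their agreement with three
partition-similarity indices (normalized mutual information, cluster-matched
Dice, Cramér's V). Topological similarity between the two hemispheres'
parcellations (NMI over mirror-paired voxels) is an additional stability
signal. K is selected at a strict local peak of the rank-averaged stability
curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import normalized_mutual_info_score
from sklearn.metrics.cluster import contingency_matrix

from .parcellation import (ConnectivityProfileMatrix, Parcellation, _as_labels,
                           _spectral_labels, build_similarity, consensus_matrix)

__all__ = [
    "StabilityReport",
    "nmi",
    "dice_matched",
    "match_clusters",
    "cramers_v",
    "split_half_stability",
    "interhemispheric_similarity",
    "select_k",
]


def nmi(a, b, variant: str = "arithmetic") -> float:
    """Normalized mutual information between two partitions, in [0, 1].

    Default normalization is the arithmetic mean of the entropies,
    2 I(a;b) / (H(a) + H(b)); ``variant="max"`` switches to max-entropy
    normalization. Equals 1 iff the partitions are identical up to
    relabeling (two single-cluster partitions count as identical); a
    single-cluster partition against a non-trivial one scores 0.
    """
    a, b = _as_labels(a), _as_labels(b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same voxel set")
    return float(normalized_mutual_info_score(a, b, average_method=variant))


def _dice_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    overlap = contingency_matrix(a, b)
    size_a = overlap.sum(axis=1, keepdims=True)
    size_b = overlap.sum(axis=0, keepdims=True)
    return 2.0 * overlap / (size_a + size_b)


def match_clusters(a, b) -> np.ndarray:
    """One-to-one cluster matching maximizing the total Dice coefficient.

    Hungarian assignment on the pairwise Dice matrix (symmetric in the two
    partitions, unlike raw overlap counts). Returns an array ``m`` with
    ``m[j] = i`` meaning cluster ``j+1`` of ``b`` is matched to cluster
    ``i+1`` of ``a``. Requires equal cluster counts.
    """
    a, b = _as_labels(a), _as_labels(b)
    dice = _dice_matrix(a, b)
    if dice.shape[0] != dice.shape[1]:
        raise ValueError("cluster counts differ; one-to-one matching undefined")
    rows, cols = linear_sum_assignment(-dice)
    m = np.empty(dice.shape[1], dtype=int)
    m[cols] = rows
    return m


def dice_matched(a, b) -> float:
    """Mean Dice coefficient over Hungarian-matched cluster pairs.

    Clusters of ``b`` are matched one-to-one to clusters of ``a`` by
    maximizing the summed Dice coefficient; each matched pair contributes
    2|X ∩ Y| / (|X| + |Y|) and the unweighted mean is returned. Label
    permutations are absorbed by the matching, and the index is symmetric.
    """
    a, b = _as_labels(a), _as_labels(b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same voxel set")
    dice = _dice_matrix(a, b)
    if dice.shape[0] != dice.shape[1]:
        raise ValueError("cluster counts differ; one-to-one matching undefined")
    rows, cols = linear_sum_assignment(-dice)
    return float(dice[rows, cols].mean())


def cramers_v(a, b) -> float:
    """Cramér's V association between two labelings: sqrt(χ² / (n (min(r,c)−1))).

    A single-cluster partition on either side makes the statistic undefined;
    by convention identical trivial partitions score 1 and any other pairing
    with a trivial side scores 0 (continuity of "identical ⇒ 1").
    """
    a, b = _as_labels(a), _as_labels(b)
    if len(a) != len(b):
        raise ValueError("partitions must cover the same voxel set")
    table = contingency_matrix(a, b)
    r, c = table.shape
    if min(r, c) == 1:
        return 1.0 if (r == 1 and c == 1) else 0.0
    chi2 = scipy.stats.chi2_contingency(table, correction=False)[0]
    v2 = chi2 / (table.sum() * (min(r, c) - 1))
    return float(np.sqrt(max(v2, 0.0)))


@dataclass
class StabilityReport:
    """Per-K reproducibility summary from split-half resampling.

    ``table`` is indexed by K and carries mean and standard deviation of
    each index over repeats (plus how many repeats were missing for Dice);
    ``interhemispheric`` optionally holds per-K inter-hemispheric NMI.
    ``selected_k`` is filled by :func:`select_k`, together with a flag when
    the peak rule had to fall back (no strict interior peak, or the peak sits
    at an end of the K range).
    """

    table: pd.DataFrame
    n_repeats: int
    interhemispheric: pd.Series | None = None
    selected_k: int | None = None
    flagged: bool = False
    flag_reason: str = ""

    @property
    def k_values(self) -> np.ndarray:
        return self.table.index.to_numpy()


def _precompute_subject_consensus(subject_conns, k_values, rng_seed):
    """Parcellate every subject at every K once; cache consensus matrices."""
    out = {}
    for k in k_values:
        mats = []
        for s, conn in enumerate(subject_conns):
            sim = build_similarity(conn)
            labels = _spectral_labels((sim + 1.0) / 2.0, k,
                                      random_state=rng_seed + 1000 * s)
            mats.append(consensus_matrix(labels))
        out[k] = mats
    return out


def split_half_stability(
    subject_conns: list[ConnectivityProfileMatrix],
    k_range=range(2, 9),
    n_repeats: int = 100,
    rng_seed: int = 0,
    collect_raw: bool = False,
) -> StabilityReport:
    """Score split-half reproducibility of the group parcellation per K.

    For each repeat the subjects are randomly split into two non-overlapping
    halves (an odd subject out is dropped at random via the shuffle); each
    half's group parcellation is built at every K and the two compared with
    NMI, matched Dice and Cramér's V; means over repeats summarize stability.
    Per-subject parcellations are computed once and reused across repeats —
    only the consensus averaging and final clustering depend on the split.
    """
    n_subjects = len(subject_conns)
    if n_subjects < 4:
        raise ValueError("need at least 4 subjects to form two informative halves")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    k_values = list(k_range)
    n_vox = subject_conns[0].counts.shape[0]
    if max(k_values) > n_vox:
        raise ValueError("k_range exceeds the number of seed voxels")

    cache = _precompute_subject_consensus(subject_conns, k_values, rng_seed)
    rng = np.random.default_rng(rng_seed)
    half = n_subjects // 2

    records = {k: {"nmi": [], "dice": [], "cramers_v": []} for k in k_values}
    raw_rows = []
    for rep in range(n_repeats):
        perm = rng.permutation(n_subjects)
        ha, hb = perm[:half], perm[half:2 * half]
        for k in k_values:
            mats = cache[k]
            la = _spectral_labels(np.mean([mats[i] for i in ha], axis=0), k,
                                  random_state=rng_seed + rep)
            lb = _spectral_labels(np.mean([mats[i] for i in hb], axis=0), k,
                                  random_state=rng_seed + rep + 1)
            rec = records[k]
            rec["nmi"].append(nmi(la, lb))
            rec["cramers_v"].append(cramers_v(la, lb))
            if len(np.unique(la)) == len(np.unique(lb)):
                rec["dice"].append(dice_matched(la, lb))
            else:  # halves disagree on nonempty-cluster count: Dice undefined
                rec["dice"].append(np.nan)
            if collect_raw:
                raw_rows.append((rep, k, rec["nmi"][-1], rec["dice"][-1],
                                 rec["cramers_v"][-1]))

    rows = []
    for k in k_values:
        rec = records[k]
        dice = np.asarray(rec["dice"], dtype=float)
        rows.append({
            "k": k,
            "nmi_mean": np.mean(rec["nmi"]), "nmi_std": np.std(rec["nmi"]),
            "dice_mean": np.nanmean(dice) if np.any(~np.isnan(dice)) else np.nan,
            "dice_std": np.nanstd(dice) if np.any(~np.isnan(dice)) else np.nan,
            "dice_n_missing": int(np.isnan(dice).sum()),
            "cramers_v_mean": np.mean(rec["cramers_v"]),
            "cramers_v_std": np.std(rec["cramers_v"]),
        })
    table = pd.DataFrame(rows).set_index("k")
    report = StabilityReport(table=table, n_repeats=n_repeats)
    if collect_raw:
        report.raw = pd.DataFrame(
            raw_rows, columns=["repeat", "k", "nmi", "dice", "cramers_v"])
    return report


def interhemispheric_similarity(left: Parcellation, right: Parcellation,
                                geometry) -> float:
    """NMI between left labels and mirrored right labels over paired voxels.

    ``left`` / ``right`` label vectors are assumed ordered like
    ``geometry.indices(hemisphere)``. Only mirror-paired voxels enter.
    """
    pairs = np.asarray(geometry.mirror_map)
    if pairs.size == 0:
        raise ValueError("geometry has an empty mirror pairing")
    left_idx = geometry.indices("left")
    right_idx = geometry.indices("right")
    pos_left = {v: i for i, v in enumerate(left_idx)}
    pos_right = {v: i for i, v in enumerate(right_idx)}
    la = _as_labels(left)[[pos_left[v] for v in pairs[:, 0]]]
    lb = _as_labels(right)[[pos_right[v] for v in pairs[:, 1]]]
    return nmi(la, lb)


def select_k(report: StabilityReport) -> int:
    """Pick K at the best strict local peak of the rank-averaged curve.

    The three split-half index means are each rank-transformed across K
    (scale-free) and averaged into one stability curve. Strict local maxima
    (greater than both neighbors; endpoints compared to their single
    neighbor) are candidate peaks; the peak with the highest rank-averaged
    stability wins, ties going to the smaller K. Falling back to the global
    maximum when no strict peak exists — or selecting a peak at an end of
    the K range, where the curve may continue rising outside it — sets the
    report's flag. The result is stored on the report and returned.
    """
    k_values = report.k_values
    if len(k_values) < 3:
        raise ValueError("K range must contain at least 3 values")
    means = report.table[["nmi_mean", "dice_mean", "cramers_v_mean"]].to_numpy()
    ranks = np.column_stack([scipy.stats.rankdata(means[:, j]) for j in range(3)])
    curve = ranks.mean(axis=1)

    peaks = []
    for i in range(len(curve)):
        left_ok = i == 0 or curve[i] > curve[i - 1]
        right_ok = i == len(curve) - 1 or curve[i] > curve[i + 1]
        if left_ok and right_ok:
            peaks.append(i)

    if peaks:
        best = peaks[int(np.argmax(curve[peaks]))]
        report.flagged = best in (0, len(curve) - 1)
        report.flag_reason = "peak at end of K range" if report.flagged else ""
    else:
        best = int(np.argmax(curve))
        report.flagged = True
        report.flag_reason = "no strict local peak; global maximum returned"
    report.selected_k = int(k_values[best])
    return report.selected_k
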