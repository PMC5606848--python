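"""Connectivity fingerprints of seed subdivisions against atlas targets.

Streamline counts from each subdivision to each target parcel are normalized
by the sizes of both regions and by the number of launched streamlines
("raw" tracing strength), then column-normalized so each target's strengths
become the proportions of its total seed connectivity contributed by each
subdivision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["FingerprintTable", "raw_strength", "fingerprint", "group_fingerprint"]


@dataclass(frozen=True)
class FingerprintTable:
    """Subdivision x target proportions, with per-target definedness flags.

    ``proportions[s, t]`` is the share of target t's total seed connectivity
    that originates in subdivision s; columns of defined targets sum to 1.
    Targets with no seed connectivity at all are flagged undefined (their
    column is NaN, not 0/0) and listed in :attr:`undefined_targets`.
    """

    proportions: np.ndarray
    defined: np.ndarray
    subdivisions: list
    targets: list

    @property
    def undefined_targets(self) -> list:
        return [t for t, ok in zip(self.targets, self.defined) if not ok]

    def to_tidy(self, raw: np.ndarray | None = None) -> pd.DataFrame:
        """Tidy (subdivision, target, [raw_strength,] proportion) table."""
        rows = []
        for i, s in enumerate(self.subdivisions):
            for j, t in enumerate(self.targets):
                row = {"subdivision": s, "target": t,
                       "proportion": self.proportions[i, j],
                       "defined": bool(self.defined[j])}
                if raw is not None:
                    row["raw_strength"] = raw[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def raw_strength(counts: np.ndarray, subdivision_sizes: np.ndarray,
                 target_sizes: np.ndarray, total_streams: int) -> np.ndarray:
    """Size- and launch-normalized tracing strength per (subdivision, target).

    strength(s, t) = count(s, t) / (size_s * size_t * total_streams), making
    strengths comparable across subdivisions and targets of different volume.
    """
    counts = np.asarray(counts, dtype=float)
    sub = np.asarray(subdivision_sizes, dtype=float)
    tgt = np.asarray(target_sizes, dtype=float)
    if counts.ndim != 2 or counts.shape != (len(sub), len(tgt)):
        raise ValueError("counts must be (n_subdivisions, n_targets)")
    if np.any(counts < 0):
        raise ValueError("streamline counts cannot be negative")
    if np.any(sub <= 0) or np.any(tgt <= 0):
        raise ValueError("subdivision and target sizes must be positive")
    if total_streams <= 0:
        raise ValueError("total_streams must be positive")
    return counts / (sub[:, None] * tgt[None, :] * total_streams)


def fingerprint(raw: np.ndarray, subdivisions: list | None = None,
                targets: list | None = None) -> FingerprintTable:
    """Column-normalize raw strengths into per-target subdivision proportions."""
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("raw strengths must be nonnegative")
    totals = raw.sum(axis=0)
    defined = totals > 0
    proportions = np.full_like(raw, np.nan)
    proportions[:, defined] = raw[:, defined] / totals[defined]
    if subdivisions is None:
        subdivisions = [f"subdivision{i + 1}" for i in range(raw.shape[0])]
    if targets is None:
        targets = [f"target{j + 1}" for j in range(raw.shape[1])]
    return FingerprintTable(proportions=proportions, defined=defined,
                            subdivisions=list(subdivisions), targets=list(targets))


def group_fingerprint(tables: list[FingerprintTable],
                      method: str = "mean_of_proportions") -> FingerprintTable:
    """Aggregate per-subject fingerprints into a group fingerprint.

    ``"mean_of_proportions"`` (default) averages each subject's proportions,
    ignoring subjects for whom a target was undefined; a target is defined in
    the group if it was defined for at least one subject.
    """
    if not tables:
        raise ValueError("need at least one subject fingerprint")
    if method != "mean_of_proportions":
        raise ValueError(f"unknown aggregation method {method!r}")
    stack = np.stack([t.proportions for t in tables])
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(stack, axis=0)
    defined = np.any([t.defined for t in tables], axis=0)
    return FingerprintTable(proportions=mean, defined=np.asarray(defined),
                            subdivisions=tables[0].subdivisions,
                            targets=tables[0].targets)
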