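"""Value/salience contrast construction and univariate ROI statistics.

From per-subject, per-ROI effect sizes under reward and punishment outcomes,
two contrasts are formed: the value signal (reward − punishment: how much
more a region responds to wins than losses) and the salience signal (the
average response to reward and punishment: how much a region responds to
motivationally relevant outcomes of either sign). Simple one-sample t
statistics and behavior correlations with Holm–Bonferroni control complete
the univariate stage that precedes the multivariate PLS.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "build_contrasts",
    "roi_one_sample_t",
    "correlate_with_behavior",
    "correlation_difference_bootstrap",
    "TTestResult",
]


def build_contrasts(table: pd.DataFrame) -> pd.DataFrame:
    """Build value and salience contrasts from a tidy ROI x condition table.

    ``table`` has columns (subject, roi, condition, effect_size) with
    conditions including ``"reward"`` and ``"punishment"``. Returns a tidy
    frame (subject, roi, value, salience) with value = reward − punishment
    and salience = (reward + punishment) / 2, exactly. (subject, roi) cells
    missing either condition are dropped with a warning.
    """
    required = {"subject", "roi", "condition", "effect_size"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    wide = table.pivot_table(index=["subject", "roi"], columns="condition",
                             values="effect_size", aggfunc="first")
    for cond in ("reward", "punishment"):
        if cond not in wide.columns:
            raise ValueError(f"condition {cond!r} absent from table")
    incomplete = wide[["reward", "punishment"]].isna().any(axis=1)
    if incomplete.any():
        warnings.warn(f"dropping {int(incomplete.sum())} (subject, roi) cell(s) "
                      "missing a condition", RuntimeWarning, stacklevel=2)
        wide = wide[~incomplete]
    out = pd.DataFrame({
        "value": wide["reward"] - wide["punishment"],
        "salience": (wide["reward"] + wide["punishment"]) / 2.0,
    }).reset_index()
    return out


class TTestResult(NamedTuple):
    t: float
    p: float
    zero_variance: bool


def roi_one_sample_t(values) -> TTestResult:
    """Classical one-sample t of the mean against zero.

    Zero-variance samples are flagged: an all-zero sample gives t = 0 and an
    all-equal nonzero sample gives an infinite t of the mean's sign.
    """
    values = np.asarray(values, dtype=float)
    if len(values) < 3:
        raise ValueError("need at least 3 observations")
    if values.std(ddof=1) == 0:
        mean = values.mean()
        if mean == 0:
            return TTestResult(0.0, 1.0, True)
        return TTestResult(float(np.inf * np.sign(mean)), 0.0, True)
    t, p = scipy.stats.ttest_1samp(values, 0.0)
    return TTestResult(float(t), float(p), False)


def _pearson_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if abs(r) >= 1.0:
        return r, r
    z = np.arctanh(r)
    half = scipy.stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    return float(np.tanh(z - half)), float(np.tanh(z + half))


def correlate_with_behavior(
    contrasts: pd.DataFrame,
    behavior: pd.DataFrame | pd.Series,
    exclusion_sd: float = 2.0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate per-ROI contrast values with behavioral scores.

    ``contrasts`` is wide (subjects x ROIs, index = subject); ``behavior``
    holds one or more score columns on the same subject index. Subjects
    falling outside ``exclusion_sd`` standard deviations of the mean on any
    behavioral measure are excluded first (outlying scores usually reflect
    non-compliance rather than trait extremes). Pearson r, two-sided p and a
    95% Fisher-z CI are reported per (ROI, measure); Holm–Bonferroni
    step-down is applied over the ROI family within each measure.
    """
    if isinstance(behavior, pd.Series):
        behavior = behavior.to_frame(name=behavior.name or "behavior")
    common = contrasts.index.intersection(behavior.index)
    contrasts = contrasts.loc[common]
    behavior = behavior.loc[common]

    z = (behavior - behavior.mean()) / behavior.std(ddof=1)
    keep = (z.abs() <= exclusion_sd).all(axis=1)
    n = int(keep.sum())
    if n < 10:
        raise ValueError(f"only {n} subjects retained after the "
                         f"{exclusion_sd}-SD exclusion; refusing to correlate")
    contrasts, behavior = contrasts[keep], behavior[keep]

    rows = []
    for measure in behavior.columns:
        y = behavior[measure].to_numpy()
        pvals, partial = [], []
        for roi in contrasts.columns:
            r, p = scipy.stats.pearsonr(contrasts[roi].to_numpy(), y)
            lo, hi = _pearson_ci(r, n)
            partial.append({"roi": roi, "measure": measure, "n": n,
                            "r": float(r), "p": float(p),
                            "ci_low": lo, "ci_high": hi})
            pvals.append(p)
        reject, p_holm, _, _ = multipletests(pvals, alpha=alpha, method="holm")
        for row, ph, rej in zip(partial, p_holm, reject):
            row.update(p_holm=float(ph), reject=bool(rej))
            rows.append(row)
    return pd.DataFrame(rows)


def correlation_difference_bootstrap(
    x: np.ndarray, y1: np.ndarray, y2: np.ndarray,
    n_boot: int = 2000, rng_seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap test for a difference of two dependent correlations.

    Resamples subjects with replacement and compares corr(x, y1) with
    corr(x, y2) on each resample; returns (observed difference, two-sided
    bootstrap p for the difference being zero).
    """
    x, y1, y2 = (np.asarray(v, dtype=float) for v in (x, y1, y2))
    n = len(x)
    obs = scipy.stats.pearsonr(x, y1)[0] - scipy.stats.pearsonr(x, y2)[0]
    rng = np.random.default_rng(rng_seed)
    diffs = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        with np.errstate(invalid="ignore"):
            diffs[b] = (scipy.stats.pearsonr(x[idx], y1[idx])[0]
                        - scipy.stats.pearsonr(x[idx], y2[idx])[0])
    # two-sided: how often the bootstrap distribution straddles zero
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return float(obs), float(min(p, 1.0))
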