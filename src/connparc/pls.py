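"""Behavioral partial least squares linking brain responses to behavior.

The method: z-score the brain matrix X (n x p) and behavior matrix Y
(n x q) column-wise, form the q x p cross-correlation matrix R, and take
its SVD, R = U S V'. Each latent variable (LV) pairs a behavior weight
vector (column of U) with a brain weight vector (column of V); its effect
size is s_l^2 / sum s^2, the share of cross-block covariance it explains.
Significance per LV comes from permuting subject rows of Y and recording
how often the permuted singular value exceeds the observed one; weight
reliability comes from bootstrap resampling of subjects, with each
resample's singular vectors aligned to the originals (orthogonal Procrustes
by default) before accumulating, and is summarized as bootstrap ratios
(weight / bootstrap SE, read like z-scores and conventionally thresholded
at 1.96).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

__all__ = [
    "PlsResult",
    "BehavioralPLS",
    "brain_behavior_correlation",
    "pls_svd",
    "permutation_test",
    "bootstrap_ratios",
    "latent_scores",
    "BOOTSTRAP_RATIO_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: |bootstrap ratio| above this marks a weight as reliable (~95% confidence).
BOOTSTRAP_RATIO_THRESHOLD = 1.96


def _zscore(M: np.ndarray, name: str) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    sd = M.std(axis=0)
    if np.any(sd == 0):
        cols = np.flatnonzero(sd == 0).tolist()
        raise ValueError(f"{name} column(s) {cols} are constant; "
                         "correlations undefined")
    return (M - M.mean(axis=0)) / sd


def brain_behavior_correlation(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """q x p Pearson correlation matrix between behavior and brain columns."""
    Xz = _zscore(X, "brain")
    Yz = _zscore(Y, "behavior")
    if Xz.shape[0] != Yz.shape[0]:
        raise ValueError("brain and behavior must have aligned rows")
    return Yz.T @ Xz / Xz.shape[0]


def _svd_with_sign(R: np.ndarray):
    """SVD of R with a deterministic sign convention per LV.

    The brain weight of largest magnitude is made positive in each LV
    (ties resolved by the first such index), so results do not depend on
    LAPACK's arbitrary sign choices.
    """
    U, s, Vt = np.linalg.svd(np.asarray(R, dtype=float), full_matrices=False)
    V = Vt.T
    for l in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, l])))
        if V[j, l] < 0:
            V[:, l] *= -1.0
            U[:, l] *= -1.0
    return U, s, V


@dataclass
class PlsResult:
    """Full output of a behavioral PLS fit.

    Weight matrices are (features x n_components); confidence intervals are
    stacked as (..., 2) with the lower bound first. ``score_correlations``
    holds the per-LV Pearson correlation between brain and behavior latent
    scores.
    """

    singular_values: np.ndarray
    effect_sizes: np.ndarray
    brain_weights: np.ndarray
    behavior_weights: np.ndarray
    perm_pvalues: np.ndarray | None = None
    bootstrap_ratios_brain: np.ndarray | None = None
    bootstrap_ratios_behavior: np.ndarray | None = None
    brain_weight_se: np.ndarray | None = None
    behavior_weight_se: np.ndarray | None = None
    brain_weight_ci: np.ndarray | None = None
    behavior_weight_ci: np.ndarray | None = None
    brain_scores: np.ndarray | None = None
    behavior_scores: np.ndarray | None = None
    score_correlations: np.ndarray | None = None
    score_correlation_ci: np.ndarray | None = None
    n_perm: int = 0
    n_boot: int = 0

    @property
    def reliable_brain(self) -> np.ndarray:
        """Boolean mask of brain weights with |bootstrap ratio| > 1.96."""
        return np.abs(self.bootstrap_ratios_brain) > BOOTSTRAP_RATIO_THRESHOLD

    @property
    def reliable_behavior(self) -> np.ndarray:
        return np.abs(self.bootstrap_ratios_behavior) > BOOTSTRAP_RATIO_THRESHOLD


def pls_svd(R: np.ndarray) -> PlsResult:
    """Core decomposition of a brain-behavior correlation matrix.

    Returns singular values, behavior (U) and brain (V) weights under the
    deterministic sign convention, and effect sizes s^2 / sum s^2.
    """
    R = np.asarray(R, dtype=float)
    if not np.all(np.isfinite(R)):
        raise ValueError("correlation matrix must be finite")
    U, s, V = _svd_with_sign(R)
    total = (s ** 2).sum()
    effect = s ** 2 / total if total > 0 else np.zeros_like(s)
    return PlsResult(singular_values=s, effect_sizes=effect,
                     brain_weights=V, behavior_weights=U)


class BehavioralPLS(BaseEstimator):
    """Behavioral PLS with permutation inference and bootstrap reliability.

    Parameters
    ----------
    n_perm : int
        Permutations of Y's subject rows for per-LV p-values (0 disables).
    n_boot : int
        Bootstrap resamples of subjects for weight SEs, bootstrap ratios and
        percentile CIs (0 disables).
    align : {"procrustes", "sign", "none"}
        How each bootstrap resample's singular vectors are aligned to the
        original before accumulating: a full orthogonal Procrustes rotation
        of the stacked weight matrix (default, the PLS-toolbox practice), a
        per-LV sign flip, or no alignment beyond each resample's internal
        deterministic sign convention. Alignment to the original shrinks
        bootstrap scatter when the decomposition is weakly identified (no
        real signal), making bootstrap ratios anti-conservative there;
        ``"none"`` is the conservative choice for null-heavy settings.
    random_state : int or None
        Seed for permutation and bootstrap draws; fixing it makes the fit
        bit-reproducible.

    Attributes (after :meth:`fit`)
    ------------------------------
    result_ : :class:`PlsResult` with every computed quantity.
    singular_values_, effect_sizes_, x_weights_ (brain, p x L),
    y_weights_ (behavior, q x L), perm_pvalues_, x_scores_, y_scores_,
    score_correlations_ : convenience views onto ``result_``.
    """

    def __init__(self, n_perm: int = 1000, n_boot: int = 1000,
                 align: str = "procrustes", random_state: int | None = None):
        self.n_perm = n_perm
        self.n_boot = n_boot
        self.align = align
        self.random_state = random_state

    # -- internals -------------------------------------------------------

    @staticmethod
    def _aligned(U_b, V_b, U, V, mode: str):
        W = np.vstack([U, V])
        W_b = np.vstack([U_b, V_b])
        if mode == "procrustes":
            A, _, Bt = np.linalg.svd(W_b.T @ W)
            rot = A @ Bt
            W_b = W_b @ rot
        elif mode == "sign":
            signs = np.sign(np.einsum("il,il->l", W_b, W))
            signs[signs == 0] = 1.0
            W_b = W_b * signs
        elif mode == "none":
            pass  # each resample keeps only its own deterministic sign convention
        else:
            raise ValueError(f"unknown alignment mode {mode!r}")
        q = U.shape[0]
        return W_b[:q], W_b[q:]

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        n, p = X.shape
        q = Y.shape[1]
        if n != Y.shape[0]:
            raise ValueError("X and Y must have aligned rows")
        if n <= max(p, q):
            logger.warning("n=%d does not exceed max(p, q)=%d; estimates will "
                           "be unstable", n, max(p, q))
        rng = np.random.default_rng(self.random_state)

        R = brain_behavior_correlation(X, Y)
        result = pls_svd(R)
        U, s, V = result.behavior_weights, result.singular_values, result.brain_weights
        L = len(s)

        Xz, Yz = _zscore(X, "brain"), _zscore(Y, "behavior")
        result.brain_scores = Xz @ V
        result.behavior_scores = Yz @ U
        result.score_correlations = np.array([
            np.corrcoef(result.brain_scores[:, l], result.behavior_scores[:, l])[0, 1]
            for l in range(L)])

        if self.n_perm:
            if self.n_perm < 100:
                raise ValueError("n_perm must be at least 100")
            exceed = np.zeros(L)
            for _ in range(self.n_perm):
                perm = rng.permutation(n)
                s_perm = np.linalg.svd(Yz[perm].T @ Xz / n, compute_uv=False)
                exceed += s_perm >= s
            # add-one correction keeps p away from an impossible exact zero
            result.perm_pvalues = (exceed + 1.0) / (self.n_perm + 1.0)
            result.n_perm = self.n_perm

        if self.n_boot:
            if self.n_boot < 100:
                raise ValueError("n_boot must be at least 100")
            boot_U = np.empty((self.n_boot, q, L))
            boot_V = np.empty((self.n_boot, p, L))
            boot_rho = np.empty((self.n_boot, L))
            b = 0
            while b < self.n_boot:
                idx = rng.integers(0, n, size=n)
                Xb, Yb = X[idx], Y[idx]
                if np.any(Xb.std(axis=0) == 0) or np.any(Yb.std(axis=0) == 0):
                    logger.info("bootstrap resample had a constant column; redrawn")
                    continue
                Rb = brain_behavior_correlation(Xb, Yb)
                U_b, _, V_b = _svd_with_sign(Rb)
                U_b, V_b = self._aligned(U_b, V_b, U, V, self.align)
                boot_U[b], boot_V[b] = U_b, V_b
                Xbz, Ybz = _zscore(Xb, "brain"), _zscore(Yb, "behavior")
                bs, hs = Xbz @ V_b, Ybz @ U_b
                boot_rho[b] = [np.corrcoef(bs[:, l], hs[:, l])[0, 1]
                               for l in range(L)]
                b += 1
            result.brain_weight_se = boot_V.std(axis=0, ddof=1)
            result.behavior_weight_se = boot_U.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                result.bootstrap_ratios_brain = np.where(
                    result.brain_weight_se > 0, V / result.brain_weight_se, 0.0)
                result.bootstrap_ratios_behavior = np.where(
                    result.behavior_weight_se > 0, U / result.behavior_weight_se, 0.0)
            result.brain_weight_ci = np.stack(
                np.percentile(boot_V, [2.5, 97.5], axis=0), axis=-1)
            result.behavior_weight_ci = np.stack(
                np.percentile(boot_U, [2.5, 97.5], axis=0), axis=-1)
            result.score_correlation_ci = np.stack(
                np.percentile(boot_rho, [2.5, 97.5], axis=0), axis=-1)
            result.n_boot = self.n_boot

        self.result_ = result
        self.singular_values_ = s
        self.effect_sizes_ = result.effect_sizes
        self.x_weights_ = V
        self.y_weights_ = U
        self.perm_pvalues_ = result.perm_pvalues
        self.x_scores_ = result.brain_scores
        self.y_scores_ = result.behavior_scores
        self.score_correlations_ = result.score_correlations
        self.n_features_in_ = p
        return self

    def transform(self, X, Y=None):
        """Project (standardized) new data onto the fitted weights."""
        Xs = _zscore(X, "brain") @ self.x_weights_
        if Y is None:
            return Xs
        return Xs, _zscore(Y, "behavior") @ self.y_weights_


# -- thin functional wrappers over the estimator -------------------------

def permutation_test(X, Y, n_perm: int = 1000, rng_seed: int | None = 0
                     ) -> np.ndarray:
    """Per-LV permutation p-values, (count of s_perm >= s + 1)/(n_perm + 1)."""
    est = BehavioralPLS(n_perm=n_perm, n_boot=0, random_state=rng_seed).fit(X, Y)
    return est.perm_pvalues_


def bootstrap_ratios(X, Y, n_boot: int = 1000, rng_seed: int | None = 0,
                     align: str = "procrustes") -> PlsResult:
    """Fit with bootstrap only; the result carries ratios, SEs and CIs."""
    est = BehavioralPLS(n_perm=0, n_boot=n_boot, align=align,
                        random_state=rng_seed).fit(X, Y)
    return est.result_


def latent_scores(X, Y, result: PlsResult):
    """Brain/behavior latent scores of standardized data and their correlation."""
    Xs = _zscore(X, "brain") @ result.brain_weights
    Ys = _zscore(Y, "behavior") @ result.behavior_weights
    rho = np.array([np.corrcoef(Xs[:, l], Ys[:, l])[0, 1]
                    for l in range(Xs.shape[1])])
    return Xs, Ys, rho
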