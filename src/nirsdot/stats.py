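"""Voxelwise left-vs-right activation statistics.

Unpaired two-sample t-maps of the mean [0, 10] s response, with
familywise error controlled by the max-t permutation method: trial
labels are randomly reassigned (preserving group sizes) 2000 times, and
the 99.5th percentile of the permutation distribution of the image-wide
maximum t (and the 0.5th percentile of the minimum, for the L < R side)
thresholds the observed map at the 0.5% level per side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

L_GT_R, NONE, L_LT_R = 1, 0, -1


@dataclass
class TValueImage:
    """Per-voxel unpaired t statistic, positive where left > right."""

    t: np.ndarray
    df: int
    contrast: str = "L minus R"
    hb_species: str = "HbO"


@dataclass
class ActivationMap:
    """Classified voxels: +1 (L>R), -1 (L<R), 0 (not significant)."""

    classes: np.ndarray
    threshold_hi: float
    threshold_lo: float
    level: float
    t: np.ndarray


def trial_mean_response(
    hb_trials: np.ndarray, times: np.ndarray, window: tuple[float, float] = (0.0, 10.0)
) -> np.ndarray:
    """Time-average each trial's voxel series over the task window.

    ``hb_trials`` is (n_trials, n_voxels, n_times); returns
    (n_trials, n_voxels).
    """
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError("empty averaging window")
    return hb_trials[..., mask].mean(axis=-1)


def _tvals(X: np.ndarray, is_L: np.ndarray) -> np.ndarray:
    """Pooled-variance unpaired t per voxel; zero-variance voxels -> 0."""
    nL = int(is_L.sum())
    nR = len(is_L) - nL
    mL = X[is_L].mean(axis=0)
    mR = X[~is_L].mean(axis=0)
    ssL = ((X[is_L] - mL) ** 2).sum(axis=0)
    ssR = ((X[~is_L] - mR) ** 2).sum(axis=0)
    sp2 = (ssL + ssR) / (nL + nR - 2)
    denom = np.sqrt(sp2 * (1.0 / nL + 1.0 / nR))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mL - mR) / denom
    bad = ~np.isfinite(t)
    if bad.any():
        logger.warning("zero variance in both groups at %d voxels; t set to 0", bad.sum())
        t[bad] = 0.0
    return t


def voxel_ttest(means_L: np.ndarray, means_R: np.ndarray, hb_species: str = "HbO") -> TValueImage:
    """Classical unpaired t per voxel, left minus right."""
    means_L = np.atleast_2d(means_L)
    means_R = np.atleast_2d(means_R)
    if len(means_L) < 2 or len(means_R) < 2:
        raise ValueError("need at least 2 trials per hand")
    X = np.vstack([means_L, means_R])
    is_L = np.zeros(len(X), dtype=bool)
    is_L[: len(means_L)] = True
    t = _tvals(X, is_L)
    return TValueImage(t=t, df=len(X) - 2, hb_species=hb_species)


def maxt_threshold(
    means_L: np.ndarray,
    means_R: np.ndarray,
    n_perm: int = 2000,
    level: float = 0.005,
    seed: int | None = None,
    block: int = 200,
) -> ActivationMap:
    """Max-t permutation thresholds and the resulting activation map.

    Separate one-sided null distributions: the image-wide maximum t for
    the L > R side and the minimum for L < R, each thresholded at
    ``level``.  Seed-reproducible; permutations preserve group sizes.
    """
    if not (0.0 < level < 0.5):
        raise ValueError("level must lie in (0, 0.5)")
    if seed is None:
        raise ValueError("a seed is required for reproducible permutations")
    means_L = np.atleast_2d(means_L)
    means_R = np.atleast_2d(means_R)
    X = np.vstack([means_L, means_R])
    n, nL = len(X), len(means_L)
    if n < 4:
        raise ValueError("need at least 4 trials in total")
    rng = np.random.default_rng(seed)
    t_obs = _tvals(X, np.arange(n) < nL)

    nR = n - nL
    s_tot = X.sum(axis=0)
    q_tot = (X**2).sum(axis=0)
    X2 = X**2
    max_t = np.empty(n_perm)
    min_t = np.empty(n_perm)
    inv = 1.0 / nL + 1.0 / nR
    for start in range(0, n_perm, block):
        nb = min(block, n_perm - start)
        P = np.zeros((nb, n))
        for b in range(nb):
            P[b, rng.permutation(n)[:nL]] = 1.0
        sL = P @ X  # (nb, V)
        qL = P @ X2
        mL = sL / nL
        mR = (s_tot - sL) / nR
        ssL = qL - nL * mL**2
        ssR = (q_tot - qL) - nR * mR**2
        sp2 = (ssL + ssR) / (n - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (mL - mR) / np.sqrt(sp2 * inv)
        t[~np.isfinite(t)] = 0.0
        max_t[start:start + nb] = t.max(axis=1)
        min_t[start:start + nb] = t.min(axis=1)
    thr_hi = float(np.quantile(max_t, 1.0 - level))
    thr_lo = float(np.quantile(min_t, level))

    classes = np.zeros(X.shape[1], dtype=int)
    classes[t_obs > thr_hi] = L_GT_R
    classes[t_obs < thr_lo] = L_LT_R
    return ActivationMap(
        classes=classes, threshold_hi=thr_hi, threshold_lo=thr_lo, level=level, t=t_obs
    )


def core_map(t_image: TValueImage | np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Top/bottom ``fraction`` of voxels by t ("core activated areas").

    Returns +1 for the top tail, -1 for the bottom tail, 0 elsewhere.
    Ties are broken deterministically by voxel index (stable sort).
    """
    t = t_image.t if isinstance(t_image, TValueImage) else np.asarray(t_image)
    n = len(t)
    k = max(1, int(round(fraction * n)))
    order = np.argsort(t, kind="stable")
    if np.ptp(t) == 0:
        logger.info("core_map: degenerate (all-equal) t image; index tie-break")
    core = np.zeros(n, dtype=int)
    core[order[-k:]] = 1
    core[order[:k]] = -1
    return core
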