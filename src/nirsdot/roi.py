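"""ROI time-series analysis: parcellation, left-minus-right difference
time courses with bootstrap confidence intervals, peak-latency
extraction within [0, 10] s, latency comparisons between regions
(Wilcoxon rank-sum on top-modulation voxels), and cross-correlation
grouping of regional response timing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)


@dataclass
class Parcellation:
    """Per-retained-voxel parcel assignment (0 = unassigned/dropped)."""

    parcel_id: np.ndarray
    names: dict[int, str] = field(default_factory=dict)
    min_size: int = 50

    @property
    def ids(self) -> np.ndarray:
        ids = np.unique(self.parcel_id)
        return ids[ids > 0]

    def mask(self, pid: int) -> np.ndarray:
        return self.parcel_id == pid


def parcellate(
    coords: np.ndarray,
    scheme: str | np.ndarray = "tiles",
    tile_mm: float = 6.0,
    min_size: int = 50,
    names: dict[int, str] | None = None,
) -> Parcellation:
    """Assign retained voxels to parcels.

    ``scheme`` is either an explicit per-voxel label array (e.g. the
    generator's blob labels) or ``"tiles"`` for a geometric x-y tiling.
    Parcels not exceeding ``min_size`` voxels are dropped with a log.
    """
    coords = np.asarray(coords)
    if isinstance(scheme, str):
        if scheme != "tiles":
            raise ValueError(f"unknown parcellation scheme {scheme!r}")
        ij = np.floor(coords[:, :2] / tile_mm).astype(int)
        ij -= ij.min(axis=0)
        labels = 1 + ij[:, 0] + ij[:, 1] * (ij[:, 0].max() + 1)
    else:
        labels = np.asarray(scheme, dtype=int).copy()
        if len(labels) != len(coords):
            raise ValueError("label array does not match the voxel set")
    labels = labels.copy()
    dropped = 0
    for pid in np.unique(labels):
        if pid <= 0:
            continue
        n = (labels == pid).sum()
        if n <= min_size:
            labels[labels == pid] = 0
            dropped += 1
    if dropped:
        logger.info("parcellate: dropped %d parcels of <= %d voxels", dropped, min_size)
    if not (labels > 0).any():
        raise ValueError("empty parcellation (all parcels below minimum size)")
    return Parcellation(parcel_id=labels, names=names or {}, min_size=min_size)


@dataclass
class LRSeries:
    """Per-parcel left-minus-right difference time courses with CIs."""

    times: np.ndarray
    parcel_ids: np.ndarray
    diff: np.ndarray  # (P, T)
    ci_lo: np.ndarray
    ci_hi: np.ndarray

    def to_tsv(self, path: str) -> None:
        import pandas as pd

        rows = {"time_s": self.times}
        for p, pid in enumerate(self.parcel_ids):
            rows[f"parcel{pid}_diff"] = self.diff[p]
            rows[f"parcel{pid}_lo"] = self.ci_lo[p]
            rows[f"parcel{pid}_hi"] = self.ci_hi[p]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def lr_difference_series(
    hb_trials: np.ndarray,
    labels: list[str],
    times: np.ndarray,
    parcellation: Parcellation,
    n_boot: int = 1000,
    ci: float = 95.0,
    seed: int | None = None,
) -> LRSeries:
    """Voxel-average per parcel, trial-average per hand, difference L-R.

    The confidence band comes from ``n_boot`` seeded bootstrap resamples
    over trials (within each hand).
    """
    if seed is None:
        raise ValueError("a seed is required for the bootstrap")
    labels = np.asarray(labels)
    iL = np.flatnonzero(labels == "left")
    iR = np.flatnonzero(labels == "right")
    if len(iL) == 0 or len(iR) == 0:
        raise ValueError("both trial types must be present")
    pids = parcellation.ids
    # parcel-average voxel series: (n_trials, P, T)
    parc = np.stack(
        [hb_trials[:, parcellation.mask(pid), :].mean(axis=1) for pid in pids], axis=1
    )
    diff = parc[iL].mean(axis=0) - parc[iR].mean(axis=0)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot,) + diff.shape)
    for b in range(n_boot):
        bl = rng.choice(iL, size=len(iL), replace=True)
        br = rng.choice(iR, size=len(iR), replace=True)
        boots[b] = parc[bl].mean(axis=0) - parc[br].mean(axis=0)
    lo = np.percentile(boots, (100.0 - ci) / 2.0, axis=0)
    hi = np.percentile(boots, 100.0 - (100.0 - ci) / 2.0, axis=0)
    return LRSeries(times=times, parcel_ids=pids, diff=diff, ci_lo=lo, ci_hi=hi)


@dataclass
class LatencyResult:
    parcel_ids: np.ndarray
    latency_s: np.ndarray  # NaN where excluded
    amplitude: np.ndarray
    excluded: np.ndarray
    reasons: list[str]
    at_boundary: np.ndarray


def peak_latency(
    series: np.ndarray,
    times: np.ndarray,
    parcel_ids: np.ndarray | None = None,
    window: tuple[float, float] = (0.0, 10.0),
    expected_sign: np.ndarray | int | str = "auto",
    exclusion_factor: float = 10.0,
) -> LatencyResult:
    """Extremum location of each parcel's series within the task window.

    ``expected_sign`` +1 takes the maximum (contralateral HbO), -1 the
    minimum (HbR), "auto" the largest absolute extremum.  Parcels whose
    peak magnitude is ``exclusion_factor`` times smaller than the
    largest peak are excluded (no-modulation rule), as are all-flat
    series.  Peaks at the window boundary are flagged.
    """
    series = np.atleast_2d(series)
    P, T = series.shape
    if parcel_ids is None:
        parcel_ids = np.arange(1, P + 1)
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError("window not covered by the series")
    sub = series[:, mask]
    tw = times[mask]
    if isinstance(expected_sign, str):
        signs = np.zeros(P, dtype=int)
    else:
        signs = np.broadcast_to(np.atleast_1d(expected_sign), (P,)).astype(int)

    lat = np.full(P, np.nan)
    amp = np.zeros(P)
    boundary = np.zeros(P, dtype=bool)
    for p in range(P):
        s = signs[p]
        if s > 0:
            i = int(np.argmax(sub[p]))
        elif s < 0:
            i = int(np.argmin(sub[p]))
        else:
            i = int(np.argmax(np.abs(sub[p])))
        lat[p] = tw[i]
        amp[p] = sub[p, i]
        boundary[p] = i in (0, sub.shape[1] - 1)

    peak_mag = np.abs(amp)
    max_peak = peak_mag.max()
    excluded = np.zeros(P, dtype=bool)
    reasons = [""] * P
    for p in range(P):
        if max_peak == 0 or peak_mag[p] == 0:
            excluded[p] = True
            reasons[p] = "flat series"
        elif peak_mag[p] < max_peak / exclusion_factor:
            excluded[p] = True
            reasons[p] = "sub-threshold peak"
    lat[excluded] = np.nan
    return LatencyResult(
        parcel_ids=np.asarray(parcel_ids), latency_s=lat, amplitude=amp,
        excluded=excluded, reasons=reasons, at_boundary=boundary,
    )


@dataclass
class RankSumResult:
    z: float
    rank_sum: float
    p_value: float
    n_a: int
    n_b: int


def compare_latencies(
    latencies_a: np.ndarray,
    modulation_a: np.ndarray,
    latencies_b: np.ndarray,
    modulation_b: np.ndarray,
    top_k: int = 300,
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum on top-modulation voxel latencies.

    Within each region the ``top_k`` voxels of largest |modulation| are
    selected; if a region has fewer finite-latency voxels, all are used
    (logged).
    """

    def _top(lat, mod):
        lat = np.asarray(lat, dtype=float)
        mod = np.asarray(mod, dtype=float)
        ok = np.isfinite(lat)
        lat, mod = lat[ok], mod[ok]
        if len(lat) < top_k:
            logger.info("compare_latencies: only %d voxels available (< %d)", len(lat), top_k)
            return lat
        idx = np.argsort(-np.abs(mod), kind="stable")[:top_k]
        return lat[idx]

    a = _top(latencies_a, modulation_a)
    b = _top(latencies_b, modulation_b)
    res = sstats.ranksums(a, b)
    ranks = sstats.rankdata(np.concatenate([a, b]))
    return RankSumResult(
        z=float(res.statistic),
        rank_sum=float(ranks[: len(a)].sum()),
        p_value=float(res.pvalue),
        n_a=len(a),
        n_b=len(b),
    )


def cross_correlation_groups(
    series: np.ndarray,
    times: np.ndarray,
    n_groups: int = 3,
    max_lag_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pairwise peak-lag matrix and single-linkage grouping by lag.

    Returns (lag_matrix_s, corr_at_peak, group_labels).  lag[i, j] > 0
    means series i leads series j.  Constant series are skipped (their
    rows are NaN and they get group 0).
    """
    series = np.atleast_2d(series)
    P, T = series.shape
    if P < 2:
        raise ValueError("need at least 2 parcel series")
    dt = float(np.median(np.diff(times)))
    max_shift = T - 1 if max_lag_s is None else int(round(max_lag_s / dt))
    sd = series.std(axis=1)
    ok = sd > 0
    z = series - series.mean(axis=1, keepdims=True)

    lag = np.full((P, P), np.nan)
    cc = np.full((P, P), np.nan)
    np.fill_diagonal(lag, 0.0)
    np.fill_diagonal(cc, 1.0)
    for i in range(P):
        for j in range(i + 1, P):
            if not (ok[i] and ok[j]):
                continue
            full = np.correlate(z[i], z[j], mode="full") / (T * sd[i] * sd[j])
            lags = np.arange(-(T - 1), T)
            keep = np.abs(lags) <= max_shift
            k = int(np.argmax(full[keep]))
            lag[i, j] = lags[keep][k] * dt
            lag[j, i] = -lag[i, j]
            cc[i, j] = cc[j, i] = full[keep][k]

    groups = np.zeros(P, dtype=int)
    idx = np.flatnonzero(ok)
    if len(idx) >= 2:
        d = np.abs(lag[np.ix_(idx, idx)])
        np.fill_diagonal(d, 0.0)
        Zl = linkage(squareform(d, checks=False), method="single")
        groups[idx] = fcluster(Zl, t=min(n_groups, len(idx)), criterion="maxclust")
    return lag, cc, groups


def one_way_anova(*groups: np.ndarray):
    """Textbook one-way F test (regional latency effect)."""
    return sstats.f_oneway(*groups)
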