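"""Raw-signal conditioning: log-ratio conversion, band-pass filtering,
spectroscopic artifact removal, trial segmentation with pretask
baselining, and regularized pretask noise-covariance estimation.

The processing order mirrors standard event-related fNIRS practice:
base-10 log-ratio -> zero-phase Butterworth high/low-pass -> projection
onto the hemoglobin extinction subspace -> segmentation into [-5, 20] s
trial windows with the pretask ([-5, 0] s) mean subtracted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)


@dataclass
class TrialSet:
    """Segmented per-trial log-ratio absorbance.

    ``trials`` has shape (n_trials, n_wavelengths, n_channels, n_samples)
    over the window [-5, 20] s relative to movement onset, pretask mean
    already subtracted.
    """

    trials: np.ndarray
    labels: list[str]
    times: np.ndarray  # seconds relative to onset
    wavelengths: tuple[float, ...]
    sampling_hz: float = 7.69
    pretask_window: tuple[float, float] = (-5.0, 0.0)

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def pretask_mask(self) -> np.ndarray:
        return (self.times >= self.pretask_window[0]) & (self.times < self.pretask_window[1])

    def task_mask(self, window: tuple[float, float] = (0.0, 10.0)) -> np.ndarray:
        return (self.times >= window[0]) & (self.times <= window[1])

    def by_hand(self, hand: str) -> np.ndarray:
        idx = [i for i, lab in enumerate(self.labels) if lab == hand]
        return self.trials[idx]

    def save(self, path: str) -> None:
        np.savez_compressed(
            path,
            trials=self.trials,
            times=self.times,
            labels=np.array(self.labels),
            wavelengths=np.array(self.wavelengths),
            sampling_hz=self.sampling_hz,
            pretask_window=np.array(self.pretask_window),
        )

    @classmethod
    def load(cls, path: str) -> "TrialSet":
        z = np.load(path, allow_pickle=False)
        return cls(
            trials=z["trials"],
            labels=[str(x) for x in z["labels"]],
            times=z["times"],
            wavelengths=tuple(float(w) for w in z["wavelengths"]),
            sampling_hz=float(z["sampling_hz"]),
            pretask_window=tuple(z["pretask_window"]),
        )


@dataclass
class NoiseModel:
    """Regularized pretask noise covariance, per wavelength.

    Sigma = Sigma_tilde + beta * s * I  with  s = trace(Sigma_tilde) / M.
    Diagonal mode zeroes the off-diagonal entries of Sigma_tilde before
    regularizing (ignoring interchannel noise correlation).
    """

    sigma_tilde: dict[float, np.ndarray]
    sigma: dict[float, np.ndarray]
    s: dict[float, float]
    beta: float
    mode: str  # "full" | "diagonal"

    def save(self, path: str) -> None:
        import json

        np.savez_compressed(
            str(path) + ".npz",
            **{f"sigma_{wl:g}": v for wl, v in self.sigma.items()},
            **{f"sigma_tilde_{wl:g}": v for wl, v in self.sigma_tilde.items()},
        )
        with open(path, "w") as fh:
            json.dump(
                {"beta": self.beta, "mode": self.mode,
                 "s": {str(k): v for k, v in self.s.items()}},
                fh, indent=2,
            )


def to_log_ratio(raw: np.ndarray, reference: np.ndarray | None = None) -> np.ndarray:
    """Base-10 log-ratio: -log10(raw / reference).

    ``reference`` defaults to the per-channel series mean.  Non-positive
    samples are rejected with the offending channel and index named.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw <= 0):
        bad = np.argwhere(raw <= 0)[0]
        raise ValueError(
            f"non-positive raw sample at channel {bad[0]}, index {tuple(bad[1:])}"
        )
    if reference is None:
        reference = raw.mean(axis=-1, keepdims=True)
    return -np.log10(raw / reference)


def bandpass(
    series: np.ndarray,
    sampling_hz: float = 7.69,
    low_cut_hz: float = 0.01,
    high_cut_hz: float = 0.7,
    low_order: int = 3,
    high_order: int = 7,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis.

    High-pass of order ``low_order`` at ``low_cut_hz`` plus low-pass of
    order ``high_order`` at ``high_cut_hz``, each applied
    forward-backward (``filtfilt``) so event latencies are undistorted.
    """
    if sampling_hz <= 2.0 * high_cut_hz:
        raise ValueError("sampling rate must exceed twice the low-pass cutoff")
    n = series.shape[-1]
    b_hp, a_hp = signal.butter(low_order, low_cut_hz, "highpass", fs=sampling_hz)
    b_lp, a_lp = signal.butter(high_order, high_cut_hz, "lowpass", fs=sampling_hz)
    padlen = 3 * max(len(a_hp), len(b_hp), len(a_lp), len(b_lp))
    if n <= padlen:
        raise ValueError(f"series too short for filter warm-up (need > {padlen} samples)")
    out = signal.filtfilt(b_hp, a_hp, series, axis=-1)
    return signal.filtfilt(b_lp, a_lp, out, axis=-1)


def remove_spectroscopic_artifacts(
    series: np.ndarray, extinction
) -> tuple[np.ndarray, np.ndarray]:
    """Project multiwavelength absorbance onto the hemoglobin subspace.

    ``series`` is (n_wavelengths, n_channels, n_samples).  At each
    (channel, time) the wavelength 3-vector is orthogonally projected
    onto span{eps_HbO, eps_HbR}; the removed orthogonal residual's
    magnitude is returned as the artifact trace (n_channels, n_samples).
    """
    E = np.asarray(extinction.matrix, dtype=float)
    if np.linalg.matrix_rank(E) < E.shape[1]:
        raise ValueError("rank-deficient extinction matrix")
    if series.shape[0] != E.shape[0]:
        raise ValueError("series wavelength axis does not match extinction matrix")
    P = E @ np.linalg.pinv(E)
    cleaned = np.einsum("lk,kct->lct", P, series)
    resid = series - cleaned
    artifact = np.sqrt(np.sum(resid**2, axis=0))
    return cleaned, artifact


def segment_and_baseline(
    series: np.ndarray,
    times: np.ndarray,
    onsets: np.ndarray,
    labels: list[str],
    wavelengths: tuple[float, ...],
    sampling_hz: float = 7.69,
    window_s: tuple[float, float] = (-5.0, 20.0),
    pretask_s: tuple[float, float] = (-5.0, 0.0),
) -> TrialSet:
    """Cut [-5, 20] s trial windows and zero the pretask mean.

    Trials whose window overlaps a recording edge are dropped and
    counted in the log.  ``series`` is (n_wavelengths, n_channels,
    n_samples).
    """
    dt = 1.0 / sampling_hz
    n_pre = int(round(-window_s[0] * sampling_hz))
    n_post = int(round(window_s[1] * sampling_hz))
    rel_times = np.arange(-n_pre, n_post + 1) * dt
    pre_mask = (rel_times >= pretask_s[0]) & (rel_times < pretask_s[1])

    trials, kept_labels, dropped = [], [], 0
    for onset, lab in zip(onsets, labels):
        i0 = int(round((onset - times[0]) * sampling_hz))
        lo, hi = i0 - n_pre, i0 + n_post + 1
        if lo < 0 or hi > series.shape[-1]:
            dropped += 1
            continue
        seg = series[..., lo:hi].copy()
        seg -= seg[..., pre_mask].mean(axis=-1, keepdims=True)
        trials.append(seg)
        kept_labels.append(lab)
    if dropped:
        logger.info("segment_and_baseline: dropped %d edge-overlapping trials", dropped)
    if not trials:
        raise ValueError("zero usable trials after edge trimming")
    return TrialSet(
        trials=np.array(trials),
        labels=kept_labels,
        times=rel_times,
        wavelengths=tuple(wavelengths),
        sampling_hz=sampling_hz,
        pretask_window=pretask_s,
    )


def estimate_noise_covariance(
    trialset: TrialSet, beta: float = 1.0, mode: str = "full"
) -> NoiseModel:
    """Empirical pretask covariance with trace-scaled ridge regularization.

    Sigma_tilde averages y y^T over all pretask (trial, time) pairs;
    s = trace(Sigma_tilde)/M;  Sigma = Sigma_tilde + beta*s*I.
    """
    if beta < 0:
        raise ValueError("beta must be non-negative")
    if mode not in ("full", "diagonal"):
        raise ValueError("mode must be 'full' or 'diagonal'")
    pre = trialset.trials[..., trialset.pretask_mask]
    if pre.shape[-1] < 2:
        raise ValueError("need at least 2 pretask time points")
    sigma_tilde, sigma, s_by_wl = {}, {}, {}
    M = trialset.trials.shape[2]
    for i, wl in enumerate(trialset.wavelengths):
        # (n_trials, M, T_pre) -> pooled samples
        y = pre[:, i].transpose(1, 0, 2).reshape(M, -1)
        st = y @ y.T / y.shape[1]
        if mode == "diagonal":
            st = np.diag(np.diag(st))
        s = float(np.trace(st) / M)
        sig = st + beta * s * np.eye(M)
        if beta == 0:
            if np.linalg.matrix_rank(sig) < M:
                raise ValueError(
                    "singular pretask covariance with beta=0; increase beta"
                )
        sigma_tilde[wl], sigma[wl], s_by_wl[wl] = st, sig, s
    return NoiseModel(sigma_tilde=sigma_tilde, sigma=sigma, s=s_by_wl, beta=beta, mode=mode)


def preprocess_session(session, extinction) -> TrialSet:
    """Full conditioning chain for a simulated session."""
    wls = tuple(sorted(session.raw))
    lr = np.array([to_log_ratio(session.raw[wl]) for wl in wls])
    filt = bandpass(lr, session.spec.sampling_hz)
    cleaned, _ = remove_spectroscopic_artifacts(filt, extinction)
    return segment_and_baseline(
        cleaned,
        session.times,
        session.onsets,
        session.labels,
        wls,
        session.spec.sampling_hz,
    )
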