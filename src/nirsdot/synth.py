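"""Synthetic fNIRS session generator with known voxel-level ground truth.

Emulates the alternating left/right-hand food-retrieval task: localized
cortical activation blobs with HbO-up / HbR-down coupling, gamma-shaped
hemodynamic response kernels with region-specific peak latencies,
correlated channel noise, slow drift, and sparse motion-like artifact
spikes whose three-wavelength signature lies outside the hemoglobin
extinction subspace (so a spectroscopic remover can null them exactly).

Raw output follows the optical convention ``raw = baseline *
10**(-(A x + noise))`` so the preprocessing log-ratio step inverts it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .forward import SensitivityMatrix

LEFT, RIGHT = "left", "right"


def gamma_hrf(t: np.ndarray, peak_s: float = 4.0, fwhm_s: float = 4.0) -> np.ndarray:
    """Unimodal gamma-density response kernel, unit peak at ``peak_s``.

    Zero for t < 0 (causal: pretask epochs stay activation-free).
    """
    t = np.asarray(t, dtype=float)
    # gamma density t^(k-1) exp(-t/theta): mode (k-1)*theta = peak
    # choose k from the width/peak ratio; FWHM of a gamma ~ 2.355*sd for
    # large k, sd = sqrt(k)*theta
    sd = fwhm_s / 2.355
    k = max(1.01, (peak_s / sd) ** 2 + 1.0)
    theta = peak_s / (k - 1.0)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]
    logh = (k - 1.0) * np.log(tp / peak_s) - (tp - peak_s) / theta
    out[pos] = np.exp(logh)
    return out


@dataclass
class Blob:
    """A localized cortical activation with anticorrelated HbO/HbR."""

    center_mm: np.ndarray  # 3D position (mm)
    radius_mm: float  # Gaussian sd of the spatial profile
    amp_hbo_mM: float
    amp_hbr_mM: float
    peak_latency_s: float
    hand: str  # which hand drives this blob
    fwhm_s: float = 4.0

    def __post_init__(self) -> None:
        self.center_mm = np.asarray(self.center_mm, dtype=float)
        if self.hand not in (LEFT, RIGHT):
            raise ValueError(f"hand must be 'left' or 'right', got {self.hand!r}")
        if self.amp_hbo_mM * self.amp_hbr_mM > 0:
            raise ValueError(
                "HbO and HbR amplitudes must have opposite signs (negative coupling)"
            )


@dataclass
class GroundTruth:
    """Voxel-resolved activation truth on the retained-voxel set."""

    blobs: list[Blob]
    sens: SensitivityMatrix
    region_labels: np.ndarray = field(default=None)  # per retained voxel
    profiles: np.ndarray = field(default=None)  # (n_blobs, n_voxels)

    def hb_fields(self, hand: str, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(HbO, HbR) voxel x time concentration changes for one trial."""
        n = self.sens.n_voxels
        hbo = np.zeros((n, len(t)))
        hbr = np.zeros((n, len(t)))
        for b, prof in zip(self.blobs, self.profiles):
            if b.hand != hand:
                continue
            h = gamma_hrf(t, b.peak_latency_s, b.fwhm_s)
            hbo += np.outer(prof * b.amp_hbo_mM, h)
            hbr += np.outer(prof * b.amp_hbr_mM, h)
        return hbo, hbr


def make_ground_truth(sens: SensitivityMatrix, blobs: list[Blob]) -> GroundTruth:
    """Rasterize blob profiles onto the retained voxels.

    Left-hand blobs belong in the right hemisphere and vice versa
    (contralateral organization); blob centers must fall within the
    retained gray-matter voxel set.
    """
    coords = sens.voxel_coords()
    vox_tol = 2.0 * sens.head.voxel_size_mm
    profiles = []
    labels = np.zeros(sens.n_voxels, dtype=int)
    for i, b in enumerate(blobs):
        d = np.linalg.norm(coords - b.center_mm, axis=1)
        if d.min() > vox_tol:
            raise ValueError(
                f"blob center {b.center_mm} is not within the retained voxel set"
            )
        prof = np.exp(-0.5 * (d / b.radius_mm) ** 2)
        prof[prof < 0.01] = 0.0
        profiles.append(prof)
        labels[prof > 0.5] = i + 1
    return GroundTruth(
        blobs=list(blobs), sens=sens, region_labels=labels,
        profiles=np.array(profiles) if profiles else np.zeros((0, sens.n_voxels)),
    )


def hb_to_absorption(
    hbo: np.ndarray, hbr: np.ndarray, extinction
) -> dict[float, np.ndarray]:
    """Beer-Lambert forward map: x_lambda = eps_HbO*HbO + eps_HbR*HbR."""
    if hbo.shape != hbr.shape:
        raise ValueError("HbO and HbR fields must have the same shape")
    out = {}
    for i, wl in enumerate(extinction.wavelengths):
        e_hbo, e_hbr = extinction.matrix[i]
        out[wl] = e_hbo * hbo + e_hbr * hbr
    return out


@dataclass
class SessionSpec:
    """Acquisition and noise parameters of one simulated daily session."""

    n_trials_per_hand: int = 75
    inter_trial_s: float = 20.0
    sampling_hz: float = 7.69
    n_days: int = 3
    noise_sd: float = 5e-5  # channel log-ratio noise sd
    noise_corr_length_mm: float = 15.0
    drift_amp: float = 1e-3
    artifact_rate_per_min: float = 1.0
    artifact_amp: float = 5e-3
    onset_jitter_s: float = 0.5
    baseline_voltage: float = 1.0
    seed: int | None = None

    @property
    def dt(self) -> float:
        return 1.0 / self.sampling_hz

    def channel_covariance(self, layout) -> np.ndarray:
        """Default noise covariance: exponential spatial decay across the
        channel grid with per-channel heteroscedastic scaling."""
        mid = layout.channel_midpoints()
        corr = np.exp(-cdist(mid, mid) / self.noise_corr_length_mm)
        rng = np.random.default_rng(12345)  # fixed channel gains, not per-session
        gains = self.noise_sd * (1.0 + 0.5 * rng.uniform(-1, 1, len(mid)))
        return corr * np.outer(gains, gains)


@dataclass
class Session:
    """Raw multiwavelength voltages plus event markers."""

    raw: dict[float, np.ndarray]  # wavelength -> (n_channels, n_samples)
    times: np.ndarray
    onsets: np.ndarray  # onset times (s)
    labels: list[str]  # hand per trial, alternating
    spec: SessionSpec
    clean_log_ratio: dict[float, np.ndarray] | None = None

    def to_files(self, tsv_path: str, events_path: str) -> None:
        cols = {"time_s": self.times}
        for wl, arr in self.raw.items():
            for ch in range(arr.shape[0]):
                cols[f"ch{ch:02d}_{wl:g}nm"] = arr[ch]
        pd.DataFrame(cols).to_csv(tsv_path, sep="\t", index=False)
        with open(events_path, "w") as fh:
            json.dump(
                {"onset_s": self.onsets.tolist(), "hand": list(self.labels)}, fh, indent=2
            )


def hb_null_vector(extinction) -> np.ndarray:
    """Unit wavelength-space vector orthogonal to both extinction columns."""
    from scipy.linalg import null_space

    E = np.asarray(extinction.matrix, dtype=float)
    ns = null_space(E.T)
    if ns.shape[1] == 0:
        raise ValueError("extinction matrix leaves no artifact subspace")
    return ns[:, 0]


def simulate_session(
    sens: SensitivityMatrix,
    truth: GroundTruth,
    spec: SessionSpec,
    extinction,
) -> Session:
    """Simulate one daily session of raw multiwavelength channel data.

    y(t) = A x_lambda(t) + correlated noise + drift + artifact spikes,
    exponentiated to voltage-like form.  Reproducible from ``spec.seed``
    (a missing seed is refused).
    """
    if spec.seed is None:
        raise ValueError("SessionSpec.seed is required for reproducibility")
    rng = np.random.default_rng(spec.seed)
    n_trials = 2 * spec.n_trials_per_hand
    lead_in, tail = 10.0, 26.0
    duration = lead_in + n_trials * spec.inter_trial_s + tail
    n_samp = int(round(duration * spec.sampling_hz))
    times = np.arange(n_samp) * spec.dt

    onsets = lead_in + np.arange(n_trials) * spec.inter_trial_s
    if spec.onset_jitter_s > 0:
        onsets = onsets + rng.uniform(-spec.onset_jitter_s, spec.onset_jitter_s, n_trials)
    labels = [LEFT if i % 2 == 0 else RIGHT for i in range(n_trials)]

    M = sens.layout.n_channels
    wls = sens.wavelengths

    # clean channel signal: per blob, spatial channel pattern x HRF train
    clean = {wl: np.zeros((M, n_samp)) for wl in wls}
    for b, prof in zip(truth.blobs, truth.profiles):
        trains = np.zeros(n_samp)
        for onset, lab in zip(onsets, labels):
            if lab != b.hand:
                continue
            trains += gamma_hrf(times - onset, b.peak_latency_s, b.fwhm_s)
        for i, wl in enumerate(wls):
            e_hbo, e_hbr = extinction.matrix[list(extinction.wavelengths).index(wl)]
            x_pattern = prof * (e_hbo * b.amp_hbo_mM + e_hbr * b.amp_hbr_mM)
            clean[wl] += np.outer(sens.values[wl] @ x_pattern, trains)

    # correlated Gaussian channel noise, independent across wavelengths
    cov = spec.channel_covariance(sens.layout)
    if np.trace(cov) > 0:
        jitter = 1e-12 * np.trace(cov) / M
        Lc = np.linalg.cholesky(cov + jitter * np.eye(M))
        noise = {wl: Lc @ rng.standard_normal((M, n_samp)) for wl in wls}
    else:
        noise = {wl: np.zeros((M, n_samp)) for wl in wls}

    # slow drift: random-phase low-frequency sinusoids, shared shape scale
    drift = {}
    for wl in wls:
        d = np.zeros((M, n_samp))
        for f in (0.002, 0.005, 0.008):
            phase = rng.uniform(0, 2 * np.pi, M)[:, None]
            d += np.sin(2 * np.pi * f * times[None, :] + phase)
        drift[wl] = spec.drift_amp / 3.0 * d
    # artifact spikes: out-of-Hb-subspace signature in wavelength space
    art = {wl: np.zeros((M, n_samp)) for wl in wls}
    v_art = hb_null_vector(extinction)
    n_art = rng.poisson(spec.artifact_rate_per_min * duration / 60.0)
    kernel = np.exp(-np.arange(8) / 2.0)
    for _ in range(n_art):
        ch = rng.integers(M)
        t0 = rng.integers(0, n_samp - len(kernel))
        amp = spec.artifact_amp * rng.uniform(0.5, 1.5) * rng.choice([-1, 1])
        for i, wl in enumerate(wls):
            art[wl][ch, t0:t0 + len(kernel)] += amp * v_art[i] * kernel

    raw = {}
    for wl in wls:
        total = clean[wl] + noise[wl] + drift[wl] + art[wl]
        raw[wl] = spec.baseline_voltage * 10.0 ** (-total)
    return Session(
        raw=raw, times=times, onsets=onsets, labels=labels, spec=spec,
        clean_log_ratio=clean,
    )


def default_blobs(
    sens: SensitivityMatrix,
    amp_hbo_mM: float = 0.02,
    latencies_s: tuple[float, float] = (3.8, 4.2),
    depth_mm: float | None = None,
    radius_mm: float = 2.0,
) -> list[Blob]:
    """Two contralateral blob pairs with staggered ('premotor' earlier
    than 'motor') peak latencies, placed at gray-matter depth under each
    hemisphere's optode patch."""
    coords = sens.voxel_coords()
    ext = sens.head.extent_mm
    if depth_mm is None:
        # superficial gray matter: where the optical sensitivity (and the
        # hemodynamic response of the cortical surface) is concentrated
        depth_mm = float(coords[:, 2].min())
    midx = ext[0] / 2.0
    blobs = []
    for hand, hemi_sign in ((LEFT, +1), (RIGHT, -1)):
        # contralateral: left-hand blobs in the right hemisphere (x > mid)
        hemi = coords[:, 0] * hemi_sign > midx * hemi_sign
        if not hemi.any():
            raise ValueError("no retained voxels in a hemisphere")
        sub = coords[hemi]
        for k, lat in enumerate(latencies_s):
            target = np.array([
                midx + hemi_sign * ext[0] / 5.0,
                ext[1] / 2.0 + (k - 0.5) * ext[1] / 6.0,
                depth_mm,
            ])
            center = sub[np.argmin(np.linalg.norm(sub - target, axis=1))]
            blobs.append(
                Blob(
                    center_mm=center,
                    radius_mm=radius_mm,
                    amp_hbo_mM=amp_hbo_mM,
                    amp_hbr_mM=-0.35 * amp_hbo_mM,
                    peak_latency_s=lat,
                    hand=hand,
                )
            )
    return blobs
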