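"""Shared fixtures: small phantoms and simulated sessions built once."""

from __future__ import annotations

import numpy as np
import pytest

from nirsdot import forward, preprocess, reconstruct, synth


@pytest.fixture(scope="session")
def extinction():
    return reconstruct.DEFAULT_EXTINCTION


@pytest.fixture(scope="session")
def sens_small(tmp_path_factory):
    """18-optode bilateral layout on a coarse (2 mm voxel) slab phantom."""
    head = forward.build_phantom(extent_mm=(78.0, 64.0, 14.0), voxel_size_mm=2.0, gray_mm=4.0)
    layout = forward.place_triangular_grid(head, 18, 15.0)
    return forward.compute_sensitivity(head, layout)


@pytest.fixture(scope="session")
def single_blob(sens_small):
    """One left-hand blob in the right hemisphere at superficial gray depth."""
    coords = sens_small.voxel_coords()
    target = np.array([78.0 * 0.7, 32.0, coords[:, 2].min()])
    center = coords[np.argmin(np.linalg.norm(coords - target, axis=1))]
    blob = synth.Blob(
        center_mm=center, radius_mm=2.0, amp_hbo_mM=0.02, amp_hbr_mM=-0.007,
        peak_latency_s=4.0, hand="left",
    )
    return synth.make_ground_truth(sens_small, [blob])


def _session_views(sens, truth, extinction, **spec_kwargs):
    from nirsdot.pipeline import _trial_channel_data

    spec = synth.SessionSpec(**spec_kwargs)
    sess = synth.simulate_session(sens, truth, spec, extinction)
    ts = preprocess.preprocess_session(sess, extinction)
    noise = preprocess.estimate_noise_covariance(ts, beta=1.0, mode="full")
    return sess, ts, noise, _trial_channel_data(ts)


@pytest.fixture(scope="session")
def noiseless_blob_session(sens_small, single_blob, extinction):
    """Noise-free single-blob session, preprocessed, with trial views."""
    # noise_sd 1e-8 is ~2000x below the signal scale: effectively
    # noise-free while keeping covariances in a sane numerical range
    return _session_views(
        sens_small, single_blob, extinction,
        n_trials_per_hand=8, seed=3, noise_sd=1e-8, drift_amp=0.0,
        artifact_rate_per_min=0.0, onset_jitter_s=0.0,
    )


@pytest.fixture(scope="session")
def mn_on_blob(sens_small, noiseless_blob_session):
    """MN solution of the noiseless blob fixture at 830 nm."""
    _, ts, noise, views = noiseless_blob_session
    wl = 830.0
    return reconstruct.mn_solve(
        views[wl]["trial_means"], sens_small.values[wl], noise.sigma[wl],
        y_evidence=views[wl]["task_pool"],
    )
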