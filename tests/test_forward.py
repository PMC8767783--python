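"""Forward model: phantom, optode grid, Green's function, sensitivity."""

import numpy as np
import pytest

from nirsdot import forward
from nirsdot.forward import (
    AIR,
    CSF,
    GRAY,
    SKULL,
    WHITE,
    FDForward,
    build_phantom,
    compute_sensitivity,
    extrapolated_boundary_depth,
    green_function_cw,
    place_triangular_grid,
    source_depth,
)


class TestPhantom:
    def test_layered_slab_has_expected_labels(self):
        head = build_phantom(extent_mm=(40, 40, 30), voxel_size_mm=0.6,
                             skull_mm=2, csf_mm=1, gray_mm=3)
        present = set(np.unique(head.tissue_label))
        assert present == {SKULL, CSF, GRAY, WHITE}
        assert head.gm_mask.sum() == (head.tissue_label == GRAY).sum()

    def test_scalp_incision_is_idempotent_without_scalp(self):
        a = build_phantom(extent_mm=(24, 24, 18), voxel_size_mm=1.2, scalp_mm=0.0)
        b = build_phantom(extent_mm=(24, 24, 18), voxel_size_mm=1.2, scalp_mm=0.0,
                          incision_patch=(0, 24, 0, 24))
        np.testing.assert_array_equal(a.tissue_label, b.tissue_label)

    def test_incision_replaces_scalp_with_air(self):
        head = build_phantom(extent_mm=(24, 24, 18), voxel_size_mm=1.2, scalp_mm=2.4,
                             incision_patch=(6, 18, 6, 18))
        assert (head.tissue_label == AIR).any()
        # outside the patch scalp remains
        assert head.tissue_label[0, 0, 0] == forward.SCALP

    @pytest.mark.parametrize("kwargs", [
        {"voxel_size_mm": 0.0},
        {"voxel_size_mm": -1.0},
        {"skull_mm": 50.0, "extent_mm": (20, 20, 10)},
    ])
    def test_invalid_geometry_rejected(self, kwargs):
        with pytest.raises(ValueError):
            build_phantom(**kwargs)


class TestOptodeGrid:
    @pytest.mark.parametrize("n,expected", [(18, 30), (3, 3), (1, 0)])
    def test_channel_counts(self, n, expected):
        head = build_phantom(extent_mm=(90, 80, 14), voxel_size_mm=2.0)
        layout = place_triangular_grid(head, n, 15.0)
        assert layout.n_channels == expected

    def test_channels_at_source_detector_distance(self):
        head = build_phantom(extent_mm=(90, 80, 14), voxel_size_mm=2.0)
        layout = place_triangular_grid(head, 18, 15.0)
        for s, d in layout.channels:
            dist = np.linalg.norm(layout.positions[s] - layout.positions[d])
            assert dist == pytest.approx(15.0, abs=2.0)

    def test_grid_must_fit_surface(self):
        head = build_phantom(extent_mm=(20, 20, 10), voxel_size_mm=1.0)
        with pytest.raises(ValueError):
            place_triangular_grid(head, 18, 15.0)


class TestGreenFunction:
    MUA, MUSP = 0.02, 1.0

    def test_zero_on_extrapolated_boundary(self):
        zb = extrapolated_boundary_depth(self.MUA, self.MUSP)
        src = np.array([0.0, 0.0, source_depth(self.MUSP)])
        obs = np.array([5.0, 3.0, zb])  # on the z = -zb plane
        obs[2] = zb
        phi = green_function_cw(src, np.array([5.0, 3.0, zb]), self.MUA, self.MUSP)
        # extrapolated plane sits at negative z
        phi_plane = green_function_cw(src, np.array([5.0, 3.0, -abs(zb)]), self.MUA, self.MUSP)
        assert abs(phi_plane) < 1e-12 * abs(
            green_function_cw(src, np.array([5.0, 3.0, 2.0]), self.MUA, self.MUSP)
        )

    def test_attenuation_monotone_in_mu_a(self):
        src = np.array([0.0, 0.0, 1.0])
        obs = np.array([8.0, 0.0, 3.0])
        phi1 = green_function_cw(src, obs, self.MUA, self.MUSP)
        phi2 = green_function_cw(src, obs, 2 * self.MUA, self.MUSP)
        assert phi2 < phi1

    def test_reciprocity_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            a = rng.uniform([0, 0, 0.5], [20, 20, 10])
            b = rng.uniform([0, 0, 0.5], [20, 20, 10])
            f = green_function_cw(a, b, self.MUA, self.MUSP)
            g = green_function_cw(b, a, self.MUA, self.MUSP)
            assert f == pytest.approx(g, rel=1e-10)

    def test_coincident_points_rejected(self):
        p = np.array([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            green_function_cw(p, p, self.MUA, self.MUSP)

    def test_nonpositive_optics_rejected(self):
        with pytest.raises(ValueError):
            green_function_cw(np.zeros(3), np.ones(3), -0.01, 1.0)


class TestSensitivity:
    def test_retained_voxels_above_threshold_and_gray(self, sens_small):
        assert (sens_small.normalized_sensitivity > sens_small.threshold).all()
        gm_flat = sens_small.head.gm_mask.ravel()
        assert gm_flat[sens_small.retained_voxels].all()

    def test_normalization_max_is_one(self, sens_small):
        assert sens_small.normalized_sensitivity.max() == pytest.approx(1.0)

    def test_values_finite_nonnegative(self, sens_small):
        for wl, A in sens_small.values.items():
            assert np.isfinite(A).all()
            assert (A >= 0).all()

    def test_threshold_monotonicity(self):
        head = build_phantom(extent_mm=(50, 40, 14), voxel_size_mm=2.0)
        layout = place_triangular_grid(head, 3, 15.0)
        counts = []
        for thr in (0.001, 0.01, 0.1):
            s = compute_sensitivity(head, layout, 830.0, threshold=thr)
            counts.append(s.n_voxels)
        assert counts[0] >= counts[1] >= counts[2]

    def test_channel_row_reciprocity(self):
        """Swapping source and detector leaves the channel row unchanged."""
        head = build_phantom(extent_mm=(50, 40, 14), voxel_size_mm=2.0)
        layout = place_triangular_grid(head, 3, 15.0)
        swapped = forward.OptodeLayout(
            positions=layout.positions,
            channels=[(d, s) for s, d in layout.channels],
        )
        a = compute_sensitivity(head, layout, 830.0)
        b = compute_sensitivity(head, swapped, 830.0)
        np.testing.assert_allclose(a.values[830.0], b.values[830.0], rtol=1e-10)

    def test_banana_shape_depth_profile(self):
        """Midplane sensitivity is larger at 2 mm than at 15 mm depth."""
        head = build_phantom(extent_mm=(60, 40, 24), voxel_size_mm=1.0,
                             skull_mm=1.0, csf_mm=0.5, gray_mm=20.0)
        layout = place_triangular_grid(head, 3, 15.0)
        s = compute_sensitivity(head, layout, 830.0, threshold=1e-9)
        coords = s.voxel_coords()
        mid = layout.channel_midpoints()[0]
        near = np.linalg.norm(coords[:, :2] - mid[:2], axis=1) < 1.0
        A = s.values[830.0][0]
        shallow = A[near & (np.abs(coords[:, 2] - 2.0) < 1.0)]
        deep = A[near & (np.abs(coords[:, 2] - 15.0) < 1.0)]
        assert shallow.size and deep.size
        assert shallow.mean() > deep.mean()

    def test_rytov_linearity_against_fd_forward(self):
        """A x matches differenced full finite-difference forward solves
        within 10% for small absorption perturbations."""
        head = build_phantom(extent_mm=(36, 24, 16), voxel_size_mm=2.0,
                             skull_mm=2.0, csf_mm=0.0, gray_mm=10.0)
        layout = place_triangular_grid(head, 3, 15.0)
        sens = compute_sensitivity(head, layout, 830.0, threshold=1e-4, mode="fd")
        wl = 830.0
        mu_a = head.mu_a_volume(wl)
        mu_sp = head.mu_sp_volume(wl)
        # perturb a small cluster of retained voxels
        rng = np.random.default_rng(0)
        x = np.zeros(sens.n_voxels)
        pick = rng.choice(sens.n_voxels, size=12, replace=False)
        x[pick] = 1e-4
        y_lin = sens.values[wl] @ x

        mu_pert = mu_a.copy().ravel()
        mu_pert[sens.retained_voxels[pick]] += 1e-4
        mu_pert = mu_pert.reshape(head.grid_shape)
        base = FDForward(mu_a, mu_sp, head.voxel_size_mm)
        pert = FDForward(mu_pert, mu_sp, head.voxel_size_mm)
        musp_gray = head.bulk_optics(wl)[1]
        z0 = source_depth(musp_gray)
        pts = layout.positions.copy()
        pts[:, 2] = z0
        phi0 = [base.solve_point_source(p) for p in pts]
        phi1 = [pert.solve_point_source(p) for p in pts]

        def _at(field, p):
            ijk = np.clip(np.floor(p / head.voxel_size_mm).astype(int), 0,
                          np.array(head.grid_shape) - 1)
            return field[tuple(ijk)]

        L = sens.mean_path_length_mm[wl]
        y_full = np.empty(layout.n_channels)
        for m, (s, d) in enumerate(layout.channels):
            lr0 = np.log(_at(phi0[s], pts[d]))
            lr1 = np.log(_at(phi1[s], pts[d]))
            y_full[m] = (lr0 - lr1) / np.log(10.0) / L[m]
        assert np.linalg.norm(y_lin - y_full) / np.linalg.norm(y_full) < 0.10

    def test_fd_green_function_symmetric(self):
        head = build_phantom(extent_mm=(30, 20, 14), voxel_size_mm=2.0)
        solver = FDForward(head.mu_a_volume(830.0), head.mu_sp_volume(830.0), 2.0)
        pa = np.array([8.0, 10.0, 3.0])
        pb = np.array([20.0, 10.0, 5.0])
        fa = solver.solve_point_source(pa)
        fb = solver.solve_point_source(pb)

        def _at(field, p):
            return field[tuple((p / 2.0).astype(int))]

        assert _at(fa, pb) == pytest.approx(_at(fb, pa), rel=1e-8)


class TestVolumeIO:
    def test_nifti_round_trip_of_sensitivity_volume(self, sens_small, tmp_path):
        import nibabel as nib

        from nirsdot.forward import save_voxel_volume

        path = tmp_path / "nsens.nii.gz"
        save_voxel_volume(sens_small.head, sens_small.retained_voxels,
                          sens_small.normalized_sensitivity, str(path))
        img = nib.load(path)
        assert img.shape == sens_small.head.grid_shape
        back = np.asarray(img.dataobj).ravel()[sens_small.retained_voxels]
        np.testing.assert_allclose(back, sens_small.normalized_sensitivity,
                                   rtol=1e-6)
        assert img.header.get_zooms()[0] == pytest.approx(
            sens_small.head.voxel_size_mm
        )

    def test_layout_and_matrix_files(self, sens_small, tmp_path):
        import pandas as pd

        sens_small.layout.to_tsv(tmp_path / "optodes.tsv", tmp_path / "channels.tsv")
        ch = pd.read_csv(tmp_path / "channels.tsv", sep="\t")
        assert len(ch) == sens_small.layout.n_channels
        sens_small.save(str(tmp_path / "A.npz"))
        z = np.load(tmp_path / "A.npz")
        np.testing.assert_array_equal(z["retained_voxels"], sens_small.retained_voxels)
        import json
        meta = json.loads((tmp_path / "A.npz.json").read_text())
        assert meta["threshold"] == sens_small.threshold
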