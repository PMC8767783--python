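"""Forward model for continuous-wave diffuse optical tomography.

Builds a voxelized layered head phantom, places a triangular bidirectional
optode grid on its measurement surface, and computes the channel x voxel
sensitivity matrix ``A`` of the linearized (Rytov) observation model
``y = A x`` under the diffusion approximation to photon transport.

Two forward engines are available:

* ``analytic`` (default): the continuous-wave Green's function of a
  semi-infinite homogeneous medium with an extrapolated-boundary
  condition, evaluated with the gray-matter bulk optics.  Deterministic,
  mesh-free, and fast enough to run on full 0.6 mm grids.
* ``fd``: a finite-difference diffusion solve on the voxel grid honoring
  per-tissue optical coefficients, used mainly to validate the linear
  model against full (non-linearized) forward evaluations.

Coordinate convention: 0-based voxel indices, voxel centers at
``(i + 0.5) * voxel_size``, z increasing with depth from the measurement
surface (z = 0 plane).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

logger = logging.getLogger(__name__)

# Tissue codes for the six optical layers.
TISSUES = ("air", "scalp", "skull", "csf", "gray", "white")
AIR, SCALP, SKULL, CSF, GRAY, WHITE = range(6)

#: Default tissue optical coefficients (mu_a, mu_s') in mm^-1 per
#: (tissue, wavelength nm).  Literature-style values for near-infrared
#: wavelengths; configurable -- any table with positive entries works.
DEFAULT_OPTICS: dict[tuple[str, float], tuple[float, float]] = {}
for _wl, _sc in ((780.0, 0.95), (805.0, 1.0), (830.0, 1.05)):
    DEFAULT_OPTICS[("scalp", _wl)] = (0.018 * _sc, 0.8)
    DEFAULT_OPTICS[("skull", _wl)] = (0.02 * _sc, 1.0)
    DEFAULT_OPTICS[("csf", _wl)] = (0.004 * _sc, 0.3)
    DEFAULT_OPTICS[("gray", _wl)] = (0.02 * _sc, 1.0)
    DEFAULT_OPTICS[("white", _wl)] = (0.01 * _sc, 1.2)

REFRACTIVE_INDEX = 1.40


@dataclass
class HeadModel:
    """Voxelized head phantom with per-voxel tissue labels.

    Attributes
    ----------
    voxel_size_mm : edge length of the cubic voxels (default 0.6 mm).
    grid_shape : (nx, ny, nz); z is depth from the measurement surface.
    tissue_label : integer tissue code per voxel (see :data:`TISSUES`).
    optical_props : map (tissue name, wavelength) -> (mu_a, mu_s') in mm^-1.
    refractive_index : common refractive index of all tissue layers (1.40).
    gm_mask : boolean mask of gray-matter voxels eligible for reconstruction.
    """

    voxel_size_mm: float
    grid_shape: tuple[int, int, int]
    tissue_label: np.ndarray
    optical_props: dict[tuple[str, float], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OPTICS)
    )
    refractive_index: float = REFRACTIVE_INDEX
    gm_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tissue_label = np.asarray(self.tissue_label)
        if self.tissue_label.shape != tuple(self.grid_shape):
            raise ValueError("tissue_label shape does not match grid_shape")
        if self.gm_mask is None:
            self.gm_mask = self.tissue_label == GRAY
        self.gm_mask = np.asarray(self.gm_mask, dtype=bool)
        if np.any(self.gm_mask & (self.tissue_label != GRAY)):
            raise ValueError("gm_mask must be a subset of gray-labelled voxels")
        for (tis, _wl), (mua, musp) in self.optical_props.items():
            if tis != "air" and (mua <= 0 or musp <= 0):
                raise ValueError(f"non-positive optical coefficients for {tis}")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.array(self.grid_shape) * self.voxel_size_mm

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Coordinates (mm) of voxel centers, optionally restricted to a mask."""
        nx, ny, nz = self.grid_shape
        if mask is None:
            idx = np.indices(self.grid_shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return (idx + 0.5) * self.voxel_size_mm

    def bulk_optics(self, wavelength: float, tissue: str = "gray") -> tuple[float, float]:
        try:
            return self.optical_props[(tissue, float(wavelength))]
        except KeyError as exc:
            raise KeyError(
                f"optical properties undefined for ({tissue}, {wavelength} nm)"
            ) from exc

    def mu_a_volume(self, wavelength: float) -> np.ndarray:
        """Per-voxel absorption coefficient at a wavelength (air -> 0)."""
        out = np.zeros(self.grid_shape)
        for code, name in enumerate(TISSUES):
            m = self.tissue_label == code
            if name != "air" and m.any():
                out[m] = self.optical_props[(name, float(wavelength))][0]
        return out

    def mu_sp_volume(self, wavelength: float) -> np.ndarray:
        out = np.zeros(self.grid_shape)
        for code, name in enumerate(TISSUES):
            m = self.tissue_label == code
            if name != "air" and m.any():
                out[m] = self.optical_props[(name, float(wavelength))][1]
        return out

    def to_nifti(self, path: str) -> None:
        import nibabel as nib

        affine = np.diag([self.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.tissue_label.astype(np.int16), affine), path)


def save_voxel_volume(
    head: HeadModel, retained_voxels: np.ndarray, values: np.ndarray, path: str
) -> None:
    """Write per-retained-voxel values (e.g. normalized sensitivity or a
    t-image) as a NIfTI-1 volume on the head grid, zero elsewhere."""
    import nibabel as nib

    vol = np.zeros(head.grid_shape, dtype=np.float32)
    vol.ravel()[retained_voxels] = values
    affine = np.diag([head.voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(vol, affine), path)


@dataclass
class OptodeLayout:
    """Bidirectional optode grid with nearest-neighbor channels.

    Every optode acts as both source and detector; the two measurement
    directions of a pair are averaged, so a channel is the unordered pair
    ``(source_index, detector_index)``.
    """

    positions: np.ndarray  # (n_optodes, 3) mm, on the measurement surface
    channels: list[tuple[int, int]]
    source_detector_distance_mm: float = 15.0
    channel_spacing_mm: float = 7.5
    bidirectional: bool = True

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def channel_midpoints(self) -> np.ndarray:
        p = self.positions
        return np.array([(p[s] + p[d]) / 2.0 for s, d in self.channels])

    def to_tsv(self, optode_path: str, channel_path: str) -> None:
        pd.DataFrame(
            {
                "optode": np.arange(len(self.positions)),
                "x_mm": self.positions[:, 0],
                "y_mm": self.positions[:, 1],
                "z_mm": self.positions[:, 2],
            }
        ).to_csv(optode_path, sep="\t", index=False)
        pd.DataFrame(
            {
                "channel": np.arange(self.n_channels),
                "source": [s for s, _ in self.channels],
                "detector": [d for _, d in self.channels],
            }
        ).to_csv(channel_path, sep="\t", index=False)


@dataclass
class SensitivityMatrix:
    """Channel x retained-voxel sensitivity of the Rytov linear model.

    ``values[wl]`` maps voxel absorption changes (mm^-1) to base-10
    log-ratio absorbance changes, after per-channel normalization by the
    mean optical path length.  ``retained_voxels`` indexes the flat voxel
    grid; only gray-matter voxels whose summed (path-length) sensitivity
    exceeds ``threshold`` after normalization are retained.
    """

    values: dict[float, np.ndarray]
    retained_voxels: np.ndarray  # flat indices into the head grid
    normalized_sensitivity: np.ndarray  # per retained voxel, in (threshold, 1]
    threshold: float
    head: HeadModel
    layout: OptodeLayout
    mean_path_length_mm: dict[float, np.ndarray] = field(default_factory=dict)

    @property
    def n_voxels(self) -> int:
        return len(self.retained_voxels)

    @property
    def wavelengths(self) -> tuple[float, ...]:
        return tuple(sorted(self.values))

    def voxel_coords(self) -> np.ndarray:
        """Centers (mm) of the retained voxels."""
        idx = np.array(np.unravel_index(self.retained_voxels, self.head.grid_shape)).T
        return (idx + 0.5) * self.head.voxel_size_mm

    def save(self, path: str) -> None:
        """Compressed matrix file with a JSON sidecar."""
        arrays = {f"A_{wl:g}": v for wl, v in self.values.items()}
        np.savez_compressed(
            path,
            retained_voxels=self.retained_voxels,
            normalized_sensitivity=self.normalized_sensitivity,
            **arrays,
        )
        meta = {
            "wavelengths": list(self.wavelengths),
            "threshold": self.threshold,
            "n_channels": self.layout.n_channels,
            "voxel_size_mm": self.head.voxel_size_mm,
        }
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh, indent=2)


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------

def build_phantom(
    extent_mm: tuple[float, float, float] = (40.0, 40.0, 30.0),
    voxel_size_mm: float = 0.6,
    scalp_mm: float = 0.0,
    skull_mm: float = 2.0,
    csf_mm: float = 1.0,
    gray_mm: float = 3.0,
    incision_patch: tuple[float, float, float, float] | None = None,
    optics: dict | None = None,
) -> HeadModel:
    """Layered slab phantom: scalp / skull / CSF / gray / white along depth.

    ``incision_patch = (x0, x1, y0, y1)`` replaces scalp with air over a
    rectangular surface region, mirroring a scalp-incised preparation.
    The default scalp thickness is 0 (scalp-free preparation).
    """
    if voxel_size_mm <= 0:
        raise ValueError("voxel size must be positive")
    for name, t in (("scalp", scalp_mm), ("skull", skull_mm), ("csf", csf_mm), ("gray", gray_mm)):
        if t < 0:
            raise ValueError(f"{name} thickness must be non-negative")
    total = scalp_mm + skull_mm + csf_mm + gray_mm
    if total >= extent_mm[2]:
        raise ValueError("layer thicknesses exceed the grid depth")
    shape = tuple(int(round(e / voxel_size_mm)) for e in extent_mm)
    if min(shape) < 1:
        raise ValueError("grid too small for the requested extent")

    z = (np.arange(shape[2]) + 0.5) * voxel_size_mm
    label_col = np.full(shape[2], WHITE, dtype=np.int16)
    bounds = np.cumsum([scalp_mm, skull_mm, csf_mm, gray_mm])
    label_col[z < bounds[3]] = GRAY
    label_col[z < bounds[2]] = CSF
    label_col[z < bounds[1]] = SKULL
    label_col[z < bounds[0]] = SCALP
    labels = np.broadcast_to(label_col, shape).copy()

    if incision_patch is not None and scalp_mm > 0:
        x0, x1, y0, y1 = incision_patch
        xc = (np.arange(shape[0]) + 0.5) * voxel_size_mm
        yc = (np.arange(shape[1]) + 0.5) * voxel_size_mm
        inx = (xc >= x0) & (xc <= x1)
        iny = (yc >= y0) & (yc <= y1)
        patch = np.ix_(np.where(inx)[0], np.where(iny)[0], np.where(labels[0, 0] == SCALP)[0])
        labels[patch] = AIR

    return HeadModel(
        voxel_size_mm=voxel_size_mm,
        grid_shape=shape,
        tissue_label=labels,
        optical_props=dict(optics) if optics else dict(DEFAULT_OPTICS),
    )


def _triangular_patch(rows: list[int], spacing: float) -> np.ndarray:
    """Points of a triangular lattice patch with the given row sizes.

    Odd rows are offset by half a spacing so all nearest-neighbor
    distances (within and between rows) equal ``spacing``.
    """
    pts = []
    dy = spacing * np.sqrt(3.0) / 2.0
    for i, n in enumerate(rows):
        for j in range(n):
            pts.append(((j - 0.5 * (i % 2)) * spacing, i * dy))
    pts = np.array(pts, dtype=float)
    return pts - pts.mean(axis=0)


#: Row layouts for the replica optode counts.  18 optodes form two
#: triangular ladders (one per hemisphere, 8 + 10 optodes) yielding
#: exactly 30 nearest-neighbor channels (the 30-channel arrangement).
_KNOWN_ROWS: dict[int, list[list[int]]] = {
    1: [[1]],
    3: [[1, 2]],
    9: [[2, 2, 2, 3]],
    18: [[2, 2, 2, 2], [2, 2, 2, 2, 2]],
}


def place_triangular_grid(
    head: HeadModel,
    n_optodes: int = 18,
    spacing_mm: float = 15.0,
    rows: list[list[int]] | None = None,
) -> OptodeLayout:
    """Place a bidirectional triangular optode grid on the top surface.

    Channels are all optode pairs at nearest-neighbor distance
    ``spacing_mm`` (the fixed source-detector separation); adjacent
    channel midpoints are then ``spacing_mm / 2`` apart.
    """
    if rows is None:
        if n_optodes not in _KNOWN_ROWS:
            # generic near-square patch
            ncol = max(1, int(round(np.sqrt(n_optodes))))
            full, rem = divmod(n_optodes, ncol)
            rows = [[ncol] * full + ([rem] if rem else [])]
        else:
            rows = _KNOWN_ROWS[n_optodes]
    patches = []
    n_patches = len(rows)
    for k, patch_rows in enumerate(rows):
        pts = _triangular_patch(patch_rows, spacing_mm)
        # separate patches along x (one per hemisphere), far enough apart
        # that no cross-patch pair sits at the channel distance
        if n_patches > 1:
            shift = (k - (n_patches - 1) / 2.0) * 3.0 * spacing_mm
            pts = pts + np.array([shift, 0.0])
        patches.append(pts)
    pts2d = np.vstack(patches)
    if len(pts2d) != n_optodes:
        raise ValueError("row specification does not match n_optodes")
    center = head.extent_mm[:2] / 2.0
    pts2d = pts2d - pts2d.mean(axis=0) + center
    margin = spacing_mm * 0.01
    if (pts2d < -margin).any() or (pts2d > head.extent_mm[:2] + margin).any():
        raise ValueError("optode grid does not fit on the phantom surface")
    positions = np.column_stack([pts2d, np.zeros(len(pts2d))])

    tol = max(head.voxel_size_mm, 1e-6)
    channels = []
    for i in range(n_optodes):
        for j in range(i + 1, n_optodes):
            d = np.linalg.norm(positions[i] - positions[j])
            if abs(d - spacing_mm) <= tol:
                channels.append((i, j))
    return OptodeLayout(
        positions=positions,
        channels=channels,
        source_detector_distance_mm=spacing_mm,
        channel_spacing_mm=spacing_mm / 2.0,
    )


# ---------------------------------------------------------------------------
# Analytic Green's function (semi-infinite medium, extrapolated boundary)
# ---------------------------------------------------------------------------

def _boundary_params(mu_a: float, mu_sp: float, n: float = REFRACTIVE_INDEX):
    """Diffusion coefficient, effective attenuation, and extrapolation length."""
    D = 1.0 / (3.0 * (mu_a + mu_sp))
    mu_eff = np.sqrt(3.0 * mu_a * (mu_a + mu_sp))
    # internal-reflection parameter for refractive-index mismatch
    r_d = -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n
    A = (1.0 + r_d) / (1.0 - r_d)
    z_b = 2.0 * A * D
    return D, mu_eff, z_b


def source_depth(mu_sp: float) -> float:
    """Effective isotropic-source depth: one transport mean free path."""
    return 1.0 / mu_sp


def green_function_cw(
    r_src: np.ndarray,
    r_obs: np.ndarray,
    mu_a: float,
    mu_s_prime: float,
    n: float = REFRACTIVE_INDEX,
) -> np.ndarray:
    """CW fluence Green's function of the semi-infinite homogeneous medium.

    Both points are taken as given (the caller shifts surface optodes to
    the effective source depth ``1/mu_s'``); the image source across the
    extrapolated boundary plane z = -z_b enforces zero fluence there.
    Symmetric in its two arguments (reciprocity).
    """
    if mu_a <= 0 or mu_s_prime <= 0:
        raise ValueError("optical coefficients must be positive")
    r_src = np.atleast_2d(np.asarray(r_src, dtype=float))
    r_obs = np.atleast_2d(np.asarray(r_obs, dtype=float))
    D, mu_eff, z_b = _boundary_params(mu_a, mu_s_prime, n)
    dxy = r_src[:, None, :2] - r_obs[None, :, :2]
    rho2 = np.sum(dxy**2, axis=-1)
    dz = r_src[:, None, 2] - r_obs[None, :, 2]
    d1 = np.sqrt(rho2 + dz**2)
    zs_img = -2.0 * z_b - r_src[:, 2]
    dz2 = zs_img[:, None] - r_obs[None, :, 2]
    d2 = np.sqrt(rho2 + dz2**2)
    if np.any(d1 == 0):
        raise ValueError("coincident source and observation points")
    phi = (np.exp(-mu_eff * d1) / d1 - np.exp(-mu_eff * d2) / d2) / (4.0 * np.pi * D)
    return phi[0, 0] if phi.size == 1 else np.squeeze(phi)


def extrapolated_boundary_depth(mu_a: float, mu_sp: float, n: float = REFRACTIVE_INDEX) -> float:
    """z-coordinate (negative) of the extrapolated zero-fluence plane."""
    return -_boundary_params(mu_a, mu_sp, n)[2]


# ---------------------------------------------------------------------------
# Finite-difference diffusion solver (per-tissue optics)
# ---------------------------------------------------------------------------

class FDForward:
    """7-point finite-difference diffusion solver on the voxel grid.

    Solves ``-div(D grad phi) + mu_a phi = q`` with zero-fluence Dirichlet
    conditions on the grid boundary, using harmonic-mean face diffusivity
    so the operator (and hence the Green's function) is symmetric.
    Air voxels are excluded from the computational domain.
    """

    def __init__(self, mu_a: np.ndarray, mu_sp: np.ndarray, voxel_size_mm: float):
        self.shape = mu_a.shape
        self.h = voxel_size_mm
        medium = mu_sp > 0
        self.medium = medium
        self.index = -np.ones(self.shape, dtype=np.int64)
        self.index[medium] = np.arange(medium.sum())
        n = medium.sum()
        D = np.zeros(self.shape)
        D[medium] = 1.0 / (3.0 * (mu_a[medium] + mu_sp[medium]))
        h2 = self.h**2
        rows, cols, vals = [], [], []
        diag = mu_a[medium].astype(float).copy()
        flat_idx = self.index
        for axis in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[axis] = slice(None, -1)
            sl_hi[axis] = slice(1, None)
            m_lo = medium[tuple(sl_lo)] & medium[tuple(sl_hi)]
            Dlo, Dhi = D[tuple(sl_lo)][m_lo], D[tuple(sl_hi)][m_lo]
            Dface = 2.0 * Dlo * Dhi / (Dlo + Dhi)
            i_lo = flat_idx[tuple(sl_lo)][m_lo]
            i_hi = flat_idx[tuple(sl_hi)][m_lo]
            w = Dface / h2
            rows.extend([i_lo, i_hi])
            cols.extend([i_hi, i_lo])
            vals.extend([-w, -w])
            np.add.at(diag, i_lo, w)
            np.add.at(diag, i_hi, w)
            # Dirichlet zero outside the medium: boundary faces add to diag
            for sl_in, sl_out in ((sl_lo, sl_hi), (sl_hi, sl_lo)):
                m_b = medium[tuple(sl_in)] & ~medium[tuple(sl_out)]
                ib = flat_idx[tuple(sl_in)][m_b]
                np.add.at(diag, ib, 2.0 * D[tuple(sl_in)][m_b] / h2)
        # outer grid faces
        for axis in range(3):
            for side in (0, -1):
                sl = [slice(None)] * 3
                sl[axis] = side
                m_b = medium[tuple(sl)]
                ib = flat_idx[tuple(sl)][m_b]
                np.add.at(diag, ib, 2.0 * D[tuple(sl)][m_b] / h2)
        rows.append(np.arange(n))
        cols.append(np.arange(n))
        vals.append(diag)
        A = sparse.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(n, n),
        )
        self._lu = splu(A)

    def solve_point_source(self, point_mm: np.ndarray) -> np.ndarray:
        """Fluence volume for a unit point source at the given position."""
        ijk = np.clip(
            np.floor(np.asarray(point_mm) / self.h).astype(int),
            0,
            np.array(self.shape) - 1,
        )
        if not self.medium[tuple(ijk)]:
            # snap to the nearest medium voxel along depth
            col = self.medium[ijk[0], ijk[1]]
            if not col.any():
                raise ValueError("source position is outside the medium")
            ijk[2] = np.argmax(col)
        q = np.zeros(self.medium.sum())
        q[self.index[tuple(ijk)]] = 1.0 / self.h**3
        phi = np.zeros(self.shape)
        phi[self.medium] = self._lu.solve(q)
        return phi


# ---------------------------------------------------------------------------
# Sensitivity matrix
# ---------------------------------------------------------------------------

def compute_sensitivity(
    head: HeadModel,
    layout: OptodeLayout,
    wavelengths: float | tuple[float, ...] = (780.0, 805.0, 830.0),
    threshold: float = 0.001,
    mode: str = "analytic",
) -> SensitivityMatrix:
    """Compute the normalized, thresholded sensitivity matrix ``A``.

    Per channel m = (s, d) the raw Rytov kernel (photon measurement
    density function) is ``a_m(v) = G(r_s, r_v) G(r_v, r_d) / G(r_s, r_d)
    * voxel_volume`` -- a partial path length (mm) in voxel v.  Each
    channel row is normalized by its mean optical path length
    ``<L>_m = sum_v a_m(v)`` and converted to base-10 log-ratio units, so
    ``A`` maps absorption changes (mm^-1) to absorbance log-ratios.

    The per-voxel normalized sensitivity is ``sum_m a_m(v)`` divided by
    its maximum over gray-matter voxels; voxels at or below ``threshold``
    are dropped, and the retained set is intersected with the gray-matter
    mask.
    """
    wls = (wavelengths,) if np.isscalar(wavelengths) else tuple(wavelengths)
    medium = head.tissue_label != AIR
    centers = head.voxel_centers(medium)
    vvol = head.voxel_size_mm**3
    flat_medium = np.flatnonzero(medium.ravel())
    gm_flat = head.gm_mask.ravel()[flat_medium]

    values: dict[float, np.ndarray] = {}
    mpl: dict[float, np.ndarray] = {}
    norm_sens_accum = None
    retained = None

    for wl in wls:
        mua, musp = head.bulk_optics(wl, "gray")
        if mode == "analytic":
            z0 = source_depth(musp)
            opt_pts = layout.positions.copy()
            opt_pts[:, 2] = z0
            G_opt_vox = green_function_cw(opt_pts, centers, mua, musp, head.refractive_index)
            G_opt_vox = np.atleast_2d(G_opt_vox)
            G_pair = np.zeros((len(opt_pts), len(opt_pts)))
            for s, d in layout.channels:
                g = green_function_cw(opt_pts[s], opt_pts[d], mua, musp, head.refractive_index)
                G_pair[s, d] = G_pair[d, s] = float(g)
        elif mode == "fd":
            solver = FDForward(head.mu_a_volume(wl), head.mu_sp_volume(wl), head.voxel_size_mm)
            z0 = source_depth(musp)
            opt_pts = layout.positions.copy()
            opt_pts[:, 2] = z0
            fields = [solver.solve_point_source(p) for p in opt_pts]
            G_opt_vox = np.array([f[medium] for f in fields])
            G_pair = np.empty((len(opt_pts), len(opt_pts)))
            for i, f in enumerate(fields):
                for j, p in enumerate(opt_pts):
                    ijk = np.clip(np.floor(p / head.voxel_size_mm).astype(int), 0,
                                  np.array(head.grid_shape) - 1)
                    G_pair[i, j] = f[tuple(ijk)]
        else:
            raise ValueError(f"unknown forward mode {mode!r}")

        kern = np.empty((layout.n_channels, len(centers)))
        for m, (s, d) in enumerate(layout.channels):
            if G_pair[s, d] <= 0:
                raise ValueError(f"non-positive pair Green's function for channel {m}")
            kern[m] = G_opt_vox[s] * G_opt_vox[d] / G_pair[s, d] * vvol
        if not np.all(np.isfinite(kern)) or kern.max() <= 0:
            raise ValueError("degenerate (all-zero or non-finite) sensitivity kernel")
        kern = np.clip(kern, 0.0, None)

        sens_sum = kern.sum(axis=0)
        if not gm_flat.any():
            raise ValueError("phantom has no gray-matter voxels")
        norm_sens = sens_sum / sens_sum[gm_flat].max()
        norm_sens_accum = norm_sens if norm_sens_accum is None else norm_sens_accum + norm_sens

        L = kern.sum(axis=1)  # mean optical path length per channel (mm)
        values[wl] = kern / L[:, None] / np.log(10.0)
        mpl[wl] = L

    norm_sens_mean = norm_sens_accum / len(wls)
    keep = (norm_sens_mean > threshold) & gm_flat
    if not keep.any():
        raise ValueError("no voxels retained; threshold too high or layout off-grid")
    retained = flat_medium[keep]
    values = {wl: v[:, keep] for wl, v in values.items()}
    return SensitivityMatrix(
        values=values,
        retained_voxels=retained,
        normalized_sensitivity=norm_sens_mean[keep],
        threshold=threshold,
        head=head,
        layout=layout,
        mean_path_length_mm=mpl,
    )
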