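"""Synthetic PET/CT phantoms and simulated multi-observer contour sets.

No imaging data accompany the delineation study this package models, so
every analysis stage is exercised on phantoms with known ground truth:

* ``make_phantom`` builds a hot lesion (sphere, ellipsoid, or lobulated
  ellipsoid) on a uniform lower background, convolves it with an
  isotropic Gaussian point-spread function and adds scaled-Poisson
  noise — a post-reconstruction approximation of PET image statistics.
  A matching two-level CT channel is produced for display/fusion tests;
  no anatomical realism is claimed for it.

* ``simulate_observers`` emulates the delineation design of the study
  (four radiation oncologists, two sessions per modality): each
  observer's contour deviates from truth by a smooth angular radial
  displacement field with a per-observer (inter-observer) component, a
  per-session (intra-observer) component and a global bias, all in mm.

* ``bundled_table_fixtures`` exposes the per-patient GTV volumes and
  overlap fractions printed in the source study's cohort tables, so the
  published summary statistics can be recomputed without any download.

All generators are pure functions of their spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .voxel_core import BinaryMask, StructureSet, VoxelGrid

__all__ = [
    "PhantomSpec",
    "ObserverModel",
    "make_phantom",
    "simulate_observers",
    "bundled_table_fixtures",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and activity of one synthetic PET/CT lesion phantom.

    Defaults describe a desk-scale pelvic lesion: a 15 mm-radius hot
    sphere at signal-to-background ratio 8 (typical FDG-avid recurrence
    on quiet soft-tissue background), 6 mm PSF (whole-body PET spatial
    resolution) on a 2 mm isotropic grid.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    lesion_center_mm: tuple[float, float, float] | None = None  # None → grid center
    lesion_shape: Literal["sphere", "ellipsoid", "lobulated"] = "sphere"
    lesion_radii_mm: tuple[float, float, float] = (15.0, 15.0, 15.0)
    activity_lesion: float = 8.0  # kBq/mL
    activity_background: float = 1.0  # kBq/mL
    psf_fwhm_mm: float = 6.0
    noise_scale: float = 0.0  # 0 = noise-free; variance = noise_scale × mean
    lobulation_amplitude: float = 0.15  # relative radius modulation (lobulated only)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.activity_lesion > self.activity_background > 0):
            raise ValueError("need activity_lesion > activity_background > 0")
        if self.psf_fwhm_mm < 0 or self.noise_scale < 0:
            raise ValueError("psf_fwhm_mm and noise_scale must be ≥ 0")
        if self.lesion_shape not in ("sphere", "ellipsoid", "lobulated"):
            raise ValueError(f"unknown lesion shape {self.lesion_shape!r}")

    @property
    def center_mm(self) -> np.ndarray:
        if self.lesion_center_mm is not None:
            return np.asarray(self.lesion_center_mm, dtype=float)
        return (np.asarray(self.shape, dtype=float) - 1.0) / 2.0 * np.asarray(self.spacing)


@dataclass(frozen=True)
class ObserverModel:
    """Multi-observer, two-session contouring noise model.

    ``sigma_inter_mm`` sets the scale of each observer's systematic
    boundary displacement (their personal "style", shared by both of
    their sessions); ``sigma_intra_mm`` the additional per-session
    scatter; ``bias_mm`` a global over- (+) or under- (−) contouring
    offset.  ``smoothness`` is the angular correlation length of the
    boundary noise field in radians — larger values give broader, more
    coherent deviations.  Defaults mirror the study design: 4 observers
    × 2 sessions.
    """

    n_observers: int = 4
    n_sessions: int = 2
    sigma_inter_mm: float = 2.0
    sigma_intra_mm: float = 1.0
    bias_mm: float = 0.0
    smoothness: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ValueError("need at least one observer")
        if self.sigma_inter_mm < 0 or self.sigma_intra_mm < 0:
            raise ValueError("noise magnitudes must be ≥ 0")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be positive")


# ---------------------------------------------------------------------------
# Lesion geometry: every generator shape is star-shaped about its center,
# defined by a directional radius function r(u) on the unit sphere.
# ---------------------------------------------------------------------------


def _directional_radius(spec: PhantomSpec, units: np.ndarray) -> np.ndarray:
    """Lesion radius (mm) along unit directions, shape (n, 3) → (n,)."""
    a, b, c = spec.lesion_radii_mm
    if spec.lesion_shape == "sphere":
        r = np.full(units.shape[0], float(a))
    else:
        denom = np.sqrt(
            (units[:, 0] / a) ** 2 + (units[:, 1] / b) ** 2 + (units[:, 2] / c) ** 2
        )
        r = 1.0 / np.maximum(denom, 1e-12)
    if spec.lesion_shape == "lobulated":
        rng = np.random.default_rng(spec.seed + 777)
        bumps = _sphere_bump_field(rng, n_bumps=6, concentration=6.0)
        r = r * (1.0 + spec.lobulation_amplitude * bumps(units))
    return r


def _sphere_bump_field(rng: np.random.Generator, n_bumps: int, concentration: float):
    """A smooth random scalar field on the unit sphere, unit RMS.

    Sum of ``n_bumps`` von-Mises–Fisher-shaped bumps at random poles with
    standard-normal amplitudes, normalized to unit standard deviation
    over a fixed quasi-uniform direction sample.  Smooth, closed and
    cheap to evaluate — adequate for low-order organ-contour wobble.
    """
    poles = rng.normal(size=(n_bumps, 3))
    poles /= np.linalg.norm(poles, axis=1, keepdims=True)
    amps = rng.normal(size=n_bumps)

    def raw(units: np.ndarray) -> np.ndarray:
        cosang = units @ poles.T  # (n, n_bumps)
        vals = np.exp(concentration * (cosang - 1.0)) @ amps
        return vals

    # normalize on a Fibonacci direction sample (deterministic)
    k = np.arange(512)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / 512)
    theta = np.pi * (1.0 + 5**0.5) * k
    sample = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    ref = raw(sample)
    scale = ref.std()
    if scale < 1e-12:
        return lambda units: np.zeros(units.shape[0])
    mean = ref.mean()
    return lambda units: (raw(units) - mean) / scale


def _voxel_center_world(shape, spacing) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*ax, indexing="ij")


def _digitize_lesion(spec: PhantomSpec) -> np.ndarray:
    """Boolean truth: voxel centers whose radius ≤ r(direction)."""
    xs, ys, zs = _voxel_center_world(spec.shape, spec.spacing)
    center = spec.center_mm
    dx, dy, dz = xs - center[0], ys - center[1], zs - center[2]
    dist = np.sqrt(dx * dx + dy * dy + dz * dz)
    flat = np.column_stack([dx.ravel(), dy.ravel(), dz.ravel()])
    norms = np.maximum(dist.ravel(), 1e-12)
    units = flat / norms[:, None]
    radial = _directional_radius(spec, units).reshape(spec.shape)
    return dist <= radial


def make_phantom(spec: PhantomSpec) -> tuple[VoxelGrid, VoxelGrid, BinaryMask]:
    """Generate (pet, ct, truth) for one lesion phantom.

    The PET channel is the two-level activity image convolved with an
    isotropic Gaussian of FWHM ``psf_fwhm_mm``, then degraded with
    scaled-Poisson noise: ``noisy = noise_scale × Poisson(mean /
    noise_scale)``, giving variance proportional to the local mean.
    With ``noise_scale=0`` and ``psf_fwhm_mm=0`` the PET image is
    exactly two-valued and the supra-background set equals the truth
    mask.  Deterministic given ``spec.seed``.
    """
    truth_arr = _digitize_lesion(spec)
    if not truth_arr.any():
        raise ValueError("lesion lies outside the grid (no truth voxel)")
    # lesion must fit inside the grid with ≥ psf_fwhm margin
    margin_vox = np.ceil(spec.psf_fwhm_mm / np.asarray(spec.spacing)).astype(int)
    idx = np.argwhere(truth_arr)
    lo, hi = idx.min(axis=0), idx.max(axis=0)
    if np.any(lo < margin_vox) or np.any(hi >= np.asarray(spec.shape) - margin_vox):
        raise ValueError(
            "lesion does not fit inside the grid with a margin of one PSF FWHM"
        )

    pet = np.where(truth_arr, spec.activity_lesion, spec.activity_background).astype(float)
    if spec.psf_fwhm_mm > 0:
        sigma_vox = spec.psf_fwhm_mm * _FWHM_TO_SIGMA / np.asarray(spec.spacing)
        pet = ndimage.gaussian_filter(pet, sigma=sigma_vox, mode="nearest")
    if spec.noise_scale > 0:
        rng = np.random.default_rng(spec.seed)
        pet = spec.noise_scale * rng.poisson(pet / spec.noise_scale).astype(float)

    # two-level structural channel: soft tissue 40 HU, lesion 55 HU
    ct = np.where(truth_arr, 55.0, 40.0)

    pet_grid = VoxelGrid(pet, spec.spacing)
    ct_grid = VoxelGrid(ct, spec.spacing)
    truth = BinaryMask(truth_arr, spec.spacing)
    return pet_grid, ct_grid, truth


# ---------------------------------------------------------------------------
# Observer simulation: radial boundary perturbation about the truth centroid.
# ---------------------------------------------------------------------------


class _RadialPerturber:
    """Shared geometry for radially displacing one truth mask's boundary.

    A voxel at radius r along unit direction u (about the truth
    centroid) belongs to the perturbed structure iff
    r ≤ r_truth(u) + d(u), i.e. iff the point at radius r − d(u) along u
    lies inside truth (all generator shapes are star-shaped about their
    centroid).  Truth is sampled at the pulled-back radius by trilinear
    interpolation with a 0.5 cut, which keeps the half-voxel
    digitization bias small.  The computation is restricted to the
    truth bounding box padded by ``max_disp_mm`` (displacements are
    clipped to that magnitude), and the new radius is clipped to ≥ one
    voxel so the structure never vanishes.
    """

    def __init__(self, truth: BinaryMask, max_disp_mm: float) -> None:
        self.truth = truth
        self.max_disp = float(max_disp_mm)
        spacing = np.asarray(truth.spacing)
        self.spacing = spacing
        idx = np.argwhere(truth.values)
        self.centroid_vox = idx.mean(axis=0)
        pad = np.ceil(max_disp_mm / spacing).astype(int) + 1
        self.lo = np.maximum(idx.min(axis=0) - pad, 0)
        self.hi = np.minimum(idx.max(axis=0) + pad + 1, np.asarray(truth.shape))
        sub_axes = [np.arange(l, h) for l, h in zip(self.lo, self.hi)]
        ix, iy, iz = np.meshgrid(*sub_axes, indexing="ij")
        self.sub_shape = ix.shape
        coords = np.column_stack([ix.ravel(), iy.ravel(), iz.ravel()]).astype(float)
        delta_mm = (coords - self.centroid_vox) * spacing
        self.r = np.linalg.norm(delta_mm, axis=1)
        self.units = delta_mm / np.maximum(self.r, 1e-12)[:, None]
        self.truth_f = truth.values.astype(np.float32)

    def __call__(self, displacement) -> BinaryMask:
        d = np.clip(displacement(self.units), -self.max_disp, self.max_disp)
        min_r = float(self.spacing.min())
        r_sample = np.clip(self.r - d, 0.0, None)
        r_sample = np.where(self.r <= min_r, 0.0, r_sample)  # centre voxel kept
        sample_vox = (self.units * r_sample[:, None] / self.spacing + self.centroid_vox).T
        inside = ndimage.map_coordinates(
            self.truth_f, sample_vox, order=1, mode="constant", cval=0.0
        )
        arr = np.zeros(self.truth.shape, dtype=bool)
        arr[self.lo[0]:self.hi[0], self.lo[1]:self.hi[1], self.lo[2]:self.hi[2]] = (
            inside.reshape(self.sub_shape) >= 0.5
        )
        return BinaryMask(arr, self.truth.spacing, self.truth.origin)


def simulate_observers(
    truth: BinaryMask,
    model: ObserverModel,
    patient_id: str = "1",
    modality: str = "CT",
) -> StructureSet:
    """Simulate multi-observer, multi-session contours of one lesion.

    For observer *o*, a smooth angular displacement field with scale
    ``sigma_inter_mm`` is drawn once; each session *s* adds an
    independent field with scale ``sigma_intra_mm`` plus the global
    ``bias_mm``.  With all magnitudes zero every mask equals truth.
    Deterministic given ``model.seed``.
    """
    if truth.n_voxels < 10:
        raise ValueError("degenerate truth mask (< 10 voxels)")
    rng = np.random.default_rng(model.seed)
    noiseless = (
        model.sigma_inter_mm == 0 and model.sigma_intra_mm == 0 and model.bias_mm == 0
    )
    max_disp = abs(model.bias_mm) + 4.0 * (model.sigma_inter_mm + model.sigma_intra_mm)
    perturb = None if noiseless else _RadialPerturber(truth, max_disp)

    sset = StructureSet()
    concentration = 1.0 / model.smoothness**2
    for o in range(1, model.n_observers + 1):
        inter_field = _sphere_bump_field(rng, n_bumps=12, concentration=concentration)
        for s in range(1, model.n_sessions + 1):
            intra_field = _sphere_bump_field(rng, n_bumps=12, concentration=concentration)

            def disp(units, _fi=inter_field, _fs=intra_field):
                return (
                    model.bias_mm
                    + model.sigma_inter_mm * _fi(units)
                    + model.sigma_intra_mm * _fs(units)
                )

            if noiseless:
                mask = BinaryMask(truth.values.copy(), truth.spacing, truth.origin)
            else:
                mask = perturb(disp)
            sset.add(patient_id, modality, str(o), s, mask)
    return sset


# ---------------------------------------------------------------------------
# Bundled reference tables from the source delineation study (10 patients).
# ---------------------------------------------------------------------------


def bundled_table_fixtures() -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-patient cohort tables transcribed from the source study.

    Returns
    -------
    volumes : DataFrame
        One row per patient (n=10): manually contoured GTV volumes on CT
        (two sessions) and fused PET/CT (two sessions), each averaged
        over the four observers, plus the SBR auto-contour volume — all
        in cm³.
    overlaps : DataFrame
        One row per patient: composite and common volume (cm³) of the
        CT- and PET/CT-based GTVs and the three overlap fractions
        (OF_CT1, OF_PET/CT1, OF_SBR).

    Notes
    -----
    These are transcribed printed values, not recomputable from images
    (the study deposited no imaging data).  Two printed inconsistencies
    are preserved as-is and flagged by the reporting layer: one row
    lists a common volume larger than its composite volume, and the
    printed cohort means of the composite/common columns do not match
    the column means.
    """
    data_dir = resources.files("petgtv") / "data"
    volumes = pd.read_csv(str(data_dir / "reference_gtv_volumes.csv"))
    overlaps = pd.read_csv(str(data_dir / "reference_overlap_fractions.csv"))
    return volumes, overlaps
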