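"""Image/mask data model, mask algebra, volumes and overlap fractions.

The two in-memory containers are deliberately minimal:

``VoxelGrid``
    a 3D scalar image (PET activity in kBq/mL, SUV, or CT Hounsfield
    units) with physical voxel spacing in mm.  Axis order is (x, y, z)
    with the third axis indexing transversal (axial) slices; voxel
    indices are 0-based and world coordinates refer to voxel centers.

``BinaryMask``
    a boolean structure (one delineated gross tumor volume, GTV) living
    on exactly the same geometry as its reference grid.

All overlap statistics in this package reduce to set algebra on masks
that share a geometry.  Masks with mismatched geometry are rejected
rather than resampled: silent resampling corrupts overlap statistics,
and resampling is an explicit separate step outside this package.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "GeometryError",
    "EmptyReferenceError",
    "VoxelGrid",
    "BinaryMask",
    "StructureSet",
    "OverlapReport",
    "volume",
    "intersect",
    "unite",
    "overlap_fraction",
    "composite_and_common",
    "read_grid",
    "write_grid",
    "read_mask",
    "write_mask",
]

_GEOM_ATOL_MM = 1e-6

MODALITIES = ("CT", "PETCT", "SBR")


class GeometryError(ValueError):
    """Two structures do not share shape, spacing and origin."""


class EmptyReferenceError(ValueError):
    """An overlap fraction was requested against an empty reference."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Scalar per voxel; must be finite.
    spacing : tuple of float
        Voxel edge lengths (sx, sy, sz) in mm, strictly positive.
    origin : tuple of float
        World coordinates (mm) of the center of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("grid values must all be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive finite mm values, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_geometry(self, other: "VoxelGrid | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=_GEOM_ATOL_MM)
            and np.allclose(self.origin, other.origin, atol=_GEOM_ATOL_MM)
        )


@dataclass(frozen=True)
class BinaryMask:
    """A boolean structure on the same geometry as its reference grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={values.ndim}")
        if values.dtype != bool:
            uniq = np.unique(values)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError(f"mask values must be 0/1, found {uniq[:10]}")
            values = values.astype(bool)
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive finite mm values, got {self.spacing}")
        origin = tuple(float(o) for o in self.origin)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.values))

    def same_geometry(self, other: "VoxelGrid | BinaryMask") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=_GEOM_ATOL_MM)
            and np.allclose(self.origin, other.origin, atol=_GEOM_ATOL_MM)
        )

    def is_empty(self) -> bool:
        return not bool(self.values.any())


def _check_geometry(a: BinaryMask, b: BinaryMask) -> None:
    if not a.same_geometry(b):
        raise GeometryError(
            f"geometry mismatch: shape {a.shape} vs {b.shape}, "
            f"spacing {a.spacing} vs {b.spacing}, origin {a.origin} vs {b.origin}"
        )


def volume(mask: BinaryMask) -> float:
    """Volume of a mask in cm³: (set voxels) × voxel volume / 1000."""
    return mask.n_voxels * mask.voxel_volume_mm3 / 1000.0


def intersect(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise AND of two masks sharing a geometry (the *common* volume)."""
    _check_geometry(a, b)
    return BinaryMask(a.values & b.values, a.spacing, a.origin)


def unite(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Voxelwise OR of two masks sharing a geometry (the *composite* volume)."""
    _check_geometry(a, b)
    return BinaryMask(a.values | b.values, a.spacing, a.origin)


def overlap_fraction(a: BinaryMask, reference: BinaryMask) -> float:
    """Overlap fraction OF = volume(a ∩ reference) / volume(reference).

    The reference mask defines the denominator: OF_CT uses the CT-based
    GTV as reference, OF_PET/CT the PET/CT-based GTV, OF_SBR the
    SBR-based GTV.  Always in [0, 1].

    Raises
    ------
    EmptyReferenceError
        If the reference mask is empty (the fraction is undefined).
    """
    _check_geometry(a, reference)
    n_ref = reference.n_voxels
    if n_ref == 0:
        raise EmptyReferenceError("overlap fraction undefined for an empty reference mask")
    n_common = int(np.count_nonzero(a.values & reference.values))
    return n_common / n_ref


def composite_and_common(masks: Sequence[BinaryMask]) -> tuple[BinaryMask, BinaryMask]:
    """Union and intersection of ≥2 masks (multi-observer composite/common)."""
    if len(masks) < 2:
        raise ValueError(f"need at least 2 masks, got {len(masks)}")
    first = masks[0]
    union = first.values.copy()
    inter = first.values.copy()
    for m in masks[1:]:
        _check_geometry(first, m)
        union |= m.values
        inter &= m.values
    return (
        BinaryMask(union, first.spacing, first.origin),
        BinaryMask(inter, first.spacing, first.origin),
    )


# ---------------------------------------------------------------------------
# NIfTI I/O.  The affine is a pure scaling + translation built from spacing
# and origin; round trips preserve shape, spacing (to 1e-6 mm) and every
# voxel value for lossless dtypes.
# ---------------------------------------------------------------------------


def _affine(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    aff[:3, 3] = origin
    return aff


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D NIfTI volume, got ndim={data.ndim}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(t) for t in img.affine[:3, 3])
    return data, spacing, origin


def read_grid(path: str | Path) -> VoxelGrid:
    """Read a 3D NIfTI volume as a :class:`VoxelGrid`."""
    data, spacing, origin = _load_nifti(path)
    return VoxelGrid(np.asarray(data, dtype=float), spacing, origin)


def write_grid(grid: VoxelGrid, path: str | Path) -> None:
    """Write a grid as NIfTI-1 (float64, lossless)."""
    img = nib.Nifti1Image(grid.values.astype(np.float64), _affine(grid.spacing, grid.origin))
    img.header.set_zooms(grid.spacing)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> BinaryMask:
    """Read a 0/1 NIfTI volume as a :class:`BinaryMask`.

    Values other than 0 and 1 are an error — a labelled multi-structure
    volume must be split before it can be treated as one GTV.
    """
    data, spacing, origin = _load_nifti(path)
    uniq = np.unique(data)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError(f"{path}: mask file contains non-binary values {uniq[:10]}")
    return BinaryMask(data.astype(bool), spacing, origin)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as a 0/1 uint8 NIfTI-1 volume."""
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine(mask.spacing, mask.origin)
    )
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# StructureSet: the delineation design — masks keyed by
# (patient, modality, observer, session).
# ---------------------------------------------------------------------------


@dataclass
class StructureSet:
    """A labelled collection of masks keyed by (patient, modality, observer, session).

    Mirrors a multi-observer delineation study: each patient is contoured
    by several observers, in several sessions, on several modalities
    (CT, fused PET/CT, or the SBR auto-contour).  Keys are unique and all
    masks of one patient share one geometry.
    """

    _entries: dict[tuple[str, str, str, int], BinaryMask] = field(default_factory=dict)

    def add(
        self,
        patient_id: str,
        modality: str,
        observer_id: str,
        session: int,
        mask: BinaryMask,
    ) -> None:
        if modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}, got {modality!r}")
        if session not in (1, 2):
            raise ValueError(f"session must be 1 or 2, got {session}")
        key = (str(patient_id), modality, str(observer_id), int(session))
        if key in self._entries:
            raise ValueError(f"duplicate structure key {key}")
        for (pat, *_), existing in self._entries.items():
            if pat == key[0] and not existing.same_geometry(mask):
                raise GeometryError(f"mask geometry differs from other masks of patient {pat}")
        self._entries[key] = mask

    def get(self, patient_id: str, modality: str, observer_id: str, session: int) -> BinaryMask:
        return self._entries[(str(patient_id), modality, str(observer_id), int(session))]

    def select(
        self,
        patient_id: str | None = None,
        modality: str | None = None,
        observer_id: str | None = None,
        session: int | None = None,
    ) -> list[tuple[tuple[str, str, str, int], BinaryMask]]:
        out = []
        for key, mask in sorted(self._entries.items()):
            pat, mod, obs, ses = key
            if patient_id is not None and pat != str(patient_id):
                continue
            if modality is not None and mod != modality:
                continue
            if observer_id is not None and obs != str(observer_id):
                continue
            if session is not None and ses != int(session):
                continue
            out.append((key, mask))
        return out

    def patients(self) -> list[str]:
        return sorted({k[0] for k in self._entries})

    def observers(self) -> list[str]:
        return sorted({k[2] for k in self._entries})

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[tuple[tuple[str, str, str, int], BinaryMask]]:
        return iter(sorted(self._entries.items()))

    # -- persistence: NIfTI mask files plus a JSON sidecar ------------------

    def save(self, directory: str | Path) -> Path:
        """Write all masks as NIfTI files plus a ``structureset.json`` sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        records = []
        for (pat, mod, obs, ses), mask in sorted(self._entries.items()):
            fname = f"mask_p{pat}_{mod}_o{obs}_s{ses}.nii.gz"
            write_mask(mask, directory / fname)
            records.append(
                {"patient": pat, "modality": mod, "observer": obs, "session": ses, "path": fname}
            )
        sidecar = directory / "structureset.json"
        sidecar.write_text(json.dumps(records, indent=2) + "\n")
        return sidecar

    @classmethod
    def load(cls, sidecar: str | Path) -> "StructureSet":
        sidecar = Path(sidecar)
        records = json.loads(sidecar.read_text())
        out = cls()
        for rec in records:
            mask = read_mask(sidecar.parent / rec["path"])
            out.add(rec["patient"], rec["modality"], rec["observer"], int(rec["session"]), mask)
        return out


@dataclass
class OverlapReport:
    """Per-patient composite/common volumes and overlap fractions.

    One row per (patient, observer): composite and common volume (cm³) of
    the CT and PET/CT GTVs, and the three overlap fractions.  Cohort
    statistics (mean, sample SD) are computed over per-patient means.
    """

    rows: "list[dict]" = field(default_factory=list)

    def add_row(
        self,
        patient_id: str,
        observer_id: str,
        composite_volume: float,
        common_volume: float,
        of_ct: float,
        of_petct: float,
        of_sbr: float,
    ) -> None:
        if common_volume > composite_volume + 1e-9:
            raise ValueError("common volume cannot exceed composite volume")
        for name, of in (("of_ct", of_ct), ("of_petct", of_petct), ("of_sbr", of_sbr)):
            if not 0.0 <= of <= 1.0 + 1e-12:
                raise ValueError(f"{name}={of} outside [0, 1]")
        self.rows.append(
            {
                "patient": str(patient_id),
                "observer": str(observer_id),
                "composite_volume_cm3": float(composite_volume),
                "common_volume_cm3": float(common_volume),
                "of_ct": float(of_ct),
                "of_petct": float(of_petct),
                "of_sbr": float(of_sbr),
            }
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.rows,
            columns=[
                "patient",
                "observer",
                "composite_volume_cm3",
                "common_volume_cm3",
                "of_ct",
                "of_petct",
                "of_sbr",
            ],
        )

    def per_patient_means(self):
        df = self.to_frame()
        return df.groupby("patient", sort=True).mean(numeric_only=True)

    def cohort_summary(self) -> dict:
        """Mean and sample SD of each column over per-patient means."""
        means = self.per_patient_means()
        out = {}
        for col in means.columns:
            vals = means[col].to_numpy(dtype=float)
            out[col] = {
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "n": int(len(vals)),
            }
        return out
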