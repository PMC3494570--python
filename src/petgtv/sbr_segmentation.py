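"""Signal-to-background ratio (SBR) adaptive-threshold PET auto-delineation.

The method estimates the lesion *signal* as the mean activity of the
hottest voxel and its eight in-plane neighbours (a 3×3 neighbourhood in
the transversal slice), the *background* as the mean activity of a
manually drawn ROI far from the lesion, and places the segmentation
threshold adaptively as a function of the signal-to-background ratio

    q(SBR) = a + b / SBR,        T = q · signal            (fraction_of_signal)
                                 T = bg + q · (signal - bg) (background_subtracted)

This inverse-linear calibration is the standard published family of SBR
threshold rules; the coefficients (a, b) are scanner- and
reconstruction-specific, so they are plain parameters with defaults
a = 0.30, b = 0.70 and a site's own phantom calibration can be
substituted.  The segmented GTV is the connected component of the
supra-threshold set that contains the hottest voxel.  Auto-contours are
flagged as needing a visual check before clinical approval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .voxel_core import BinaryMask, GeometryError, VoxelGrid, volume

__all__ = [
    "BackgroundROI",
    "SBREstimate",
    "ThresholdModel",
    "SUVParams",
    "SegmentationResult",
    "find_hottest_voxel",
    "estimate_signal",
    "estimate_background",
    "threshold_value",
    "segment_sbr",
    "to_suv",
    "suv_max",
]


@dataclass(frozen=True)
class BackgroundROI:
    """A mask designating background tissue, away from the lesion."""

    region: BinaryMask

    def __post_init__(self) -> None:
        if self.region.is_empty():
            raise ValueError("background ROI must be non-empty")

    def check_disjoint(self, search: BinaryMask) -> None:
        if (self.region.values & search.values).any():
            raise ValueError("background ROI intersects the lesion search region")


@dataclass(frozen=True)
class SBREstimate:
    """Tumor signal, background activity and their ratio.

    ``signal`` is the mean of the hottest voxel and its 8 in-plane
    neighbours; ``background`` the mean over the background ROI; both in
    the units of the input grid (the mask produced downstream does not
    depend on the unit because the threshold scales with the signal).
    """

    signal: float
    background: float
    hottest_voxel: tuple[int, int, int]

    def __post_init__(self) -> None:
        if not self.signal > 0:
            raise ValueError(f"signal must be positive, got {self.signal}")
        if not self.background > 0:
            raise ValueError(f"background must be positive, got {self.background}")

    @property
    def sbr(self) -> float:
        return self.signal / self.background


@dataclass(frozen=True)
class ThresholdModel:
    """Adaptive threshold rule q(SBR) = a + b/SBR.

    ``a`` is the high-contrast asymptote of the threshold fraction;
    ``b`` scales the background-driven correction.  ``mode`` selects
    whether the fraction multiplies the signal directly or only the
    background-subtracted signal excess.
    """

    a: float = 0.30
    b: float = 0.70
    mode: Literal["fraction_of_signal", "background_subtracted"] = "fraction_of_signal"

    def __post_init__(self) -> None:
        if self.mode not in ("fraction_of_signal", "background_subtracted"):
            raise ValueError(f"unknown threshold mode {self.mode!r}")

    def fraction(self, sbr: float) -> float:
        """Threshold fraction q at a given SBR; must lie in (0, 1)."""
        if not sbr > 1.0:
            raise ValueError(
                f"SBR must exceed 1 (lesion hotter than background), got {sbr:.4g}"
            )
        q = self.a + self.b / sbr
        if not 0.0 < q < 1.0:
            raise ValueError(
                f"threshold fraction q={q:.4g} outside (0, 1) at SBR={sbr:.4g} "
                f"(a={self.a}, b={self.b})"
            )
        return q


@dataclass(frozen=True)
class SUVParams:
    """Injected dose (MBq) and body weight (kg) for SUV normalization."""

    injected_dose_mbq: float
    body_weight_kg: float
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        if not self.injected_dose_mbq > 0:
            raise ValueError("injected dose must be positive")
        if not self.body_weight_kg > 0:
            raise ValueError("body weight must be positive")


@dataclass(frozen=True)
class SegmentationResult:
    """An SBR auto-contour plus the estimate and threshold that produced it."""

    mask: BinaryMask
    estimate: SBREstimate
    threshold: float
    needs_visual_check: bool = True

    def report(self) -> dict:
        return {
            "signal": self.estimate.signal,
            "background": self.estimate.background,
            "sbr": self.estimate.sbr,
            "threshold": self.threshold,
            "volume_cm3": volume(self.mask),
            "hottest_voxel": list(self.estimate.hottest_voxel),
            "needs_visual_check": self.needs_visual_check,
        }


def find_hottest_voxel(grid: VoxelGrid, search: BinaryMask) -> tuple[int, int, int]:
    """Index of the maximum-valued voxel within the search region.

    Ties are broken by the lexicographically smallest (x, y, z) index so
    the result is deterministic.
    """
    if not grid.same_geometry(search):
        raise GeometryError("search mask geometry does not match the grid")
    if search.is_empty():
        raise ValueError("search region is empty")
    masked = np.where(search.values, grid.values, -np.inf)
    peak = masked.max()
    # argwhere yields indices in C order == lexicographic (x, y, z)
    idx = np.argwhere(masked == peak)[0]
    return (int(idx[0]), int(idx[1]), int(idx[2]))


def estimate_signal(grid: VoxelGrid, hottest: tuple[int, int, int]) -> float:
    """Mean activity of the hottest voxel and its 8 in-plane neighbours.

    The neighbourhood is the 3×3 patch in the transversal (same-z)
    slice.  A hottest voxel on an in-plane border has no complete
    neighbourhood; that is an error (a silent partial mean would bias
    the signal estimate) — pad or enlarge the field of view instead.
    """
    x, y, z = hottest
    nx, ny, nz = grid.shape
    if not (0 <= x < nx and 0 <= y < ny and 0 <= z < nz):
        raise IndexError(f"hottest voxel {hottest} outside grid of shape {grid.shape}")
    if x < 1 or y < 1 or x > nx - 2 or y > ny - 2:
        raise ValueError(
            f"hottest voxel {hottest} lies on an in-plane border; the 3×3 "
            "transversal neighbourhood is incomplete — pad the grid or "
            "enlarge the field of view"
        )
    patch = grid.values[x - 1 : x + 2, y - 1 : y + 2, z]
    return float(patch.mean())


def estimate_background(grid: VoxelGrid, roi: BackgroundROI) -> float:
    """Mean activity over the background ROI."""
    if not grid.same_geometry(roi.region):
        raise GeometryError("background ROI geometry does not match the grid")
    return float(grid.values[roi.region.values].mean())


def threshold_value(model: ThresholdModel, est: SBREstimate) -> float:
    """Absolute activity threshold from the adaptive rule and an estimate."""
    q = model.fraction(est.sbr)
    if model.mode == "fraction_of_signal":
        return q * est.signal
    return est.background + q * (est.signal - est.background)


_CONNECTIVITY_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def segment_sbr(
    grid: VoxelGrid,
    model: ThresholdModel,
    roi: BackgroundROI,
    search: BinaryMask,
    connectivity: int = 26,
) -> SegmentationResult:
    """Delineate the lesion by SBR adaptive thresholding.

    Pipeline: find the hottest voxel inside ``search``; estimate signal
    (3×3 in-plane mean) and background (ROI mean); compute the adaptive
    threshold; keep the connected component of the supra-threshold set
    (``grid ≥ T``) containing the hottest voxel.

    The returned result carries ``needs_visual_check=True``: adaptive
    auto-contours are reviewed visually before approval in clinical use.
    """
    if connectivity not in _CONNECTIVITY_STRUCTS:
        raise ValueError(f"connectivity must be one of {sorted(_CONNECTIVITY_STRUCTS)}")
    roi.check_disjoint(search)
    hottest = find_hottest_voxel(grid, search)
    signal = estimate_signal(grid, hottest)
    background = estimate_background(grid, roi)
    est = SBREstimate(signal=signal, background=background, hottest_voxel=hottest)
    threshold = threshold_value(model, est)

    supra = grid.values >= threshold
    if not supra.any():
        raise ValueError(f"no voxel reaches the threshold {threshold:.4g}")
    labels, _ = ndimage.label(supra, structure=_CONNECTIVITY_STRUCTS[connectivity])
    lesion_label = labels[hottest]
    if lesion_label == 0:
        # the hottest voxel itself is supra-threshold whenever q < 1 and
        # signal ≥ voxel max is violated only on pathological inputs
        raise ValueError("hottest voxel is below the threshold; no lesion component")
    mask = BinaryMask(labels == lesion_label, grid.spacing, grid.origin)
    return SegmentationResult(mask=mask, estimate=est, threshold=float(threshold))


def to_suv(grid: VoxelGrid, params: SUVParams) -> VoxelGrid:
    """Convert an activity grid (kBq/mL) to body-weight-normalized SUV.

    SUV = activity [kBq/mL] × body weight [kg] / injected dose [MBq],
    the usual body-weight normalization with tissue density taken as
    1 g/mL.  Decay correction is assumed already applied by the scanner
    when ``decay_corrected`` is set.
    """
    factor = params.body_weight_kg / params.injected_dose_mbq
    return VoxelGrid(grid.values * factor, grid.spacing, grid.origin)


def suv_max(grid: VoxelGrid, mask: BinaryMask) -> float:
    """Maximum value of an (SUV) grid within a mask."""
    if not grid.same_geometry(mask):
        raise GeometryError("mask geometry does not match the grid")
    if mask.is_empty():
        raise ValueError("mask is empty")
    return float(grid.values[mask.values].max())
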