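"""Vessel segmentation and CT image-quality metrics.

The segmentation chain mirrors a slice-based radiology workflow: seeded
region growing inside an intensity window, followed by per-slice
morphological hole filling.  Image quality is quantified with ROI-based
metrics: noise (SD of two background ROIs), brightness-to-noise index
BI = object mean / noise, and contrast-to-noise ratio
CNR = (object mean - background mean) / noise, evaluated per slice and then
averaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.segmentation import flood

__all__ = [
    "ImageVolume",
    "SegmentationMask",
    "ImageQualityReport",
    "RoiSpec",
    "region_grow",
    "fill_holes",
    "image_quality",
    "compare_masks",
    "default_rois",
    "robust_seed_point",
    "window_level",
]


@dataclass(frozen=True)
class ImageVolume:
    """3-D scalar image with voxel spacing in mm per axis."""

    voxels: np.ndarray
    spacing: tuple

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3-D volume, got ndim={vox.ndim}")
        if not np.all(np.isfinite(vox)):
            raise ValueError("volume intensities must be finite")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self):
        return self.voxels.shape

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class SegmentationMask:
    """Boolean voxel mask sharing the geometry of its source volume."""

    voxels: np.ndarray
    spacing: tuple

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=bool)
        if vox.ndim != 3:
            raise ValueError(f"expected a 3-D mask, got ndim={vox.ndim}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self):
        return self.voxels.shape

    def volume_mm3(self) -> float:
        return float(np.count_nonzero(self.voxels)) * float(np.prod(self.spacing))


def window_level(volume: ImageVolume, window: float, level: float) -> ImageVolume:
    """Linear brightness adjustment: map [level-w/2, level+w/2] to [0, 255].

    Deterministic replacement for interactive brightness tuning; the
    (window, level) pair should be logged with any result derived from it.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    lo = level - 0.5 * window
    out = np.clip((volume.voxels - lo) / window, 0.0, 1.0) * 255.0
    return ImageVolume(out, volume.spacing)


def region_grow(volume: ImageVolume, seed_point, tolerance: float) -> SegmentationMask:
    """Seeded region growing with 6-connectivity.

    Returns the connected component, containing ``seed_point``, of voxels
    whose intensity lies within ``[I(seed)-tolerance, I(seed)+tolerance]``.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    seed_point = tuple(int(i) for i in seed_point)
    shape = volume.shape
    if len(seed_point) != 3 or any(
        not 0 <= i < n for i, n in zip(seed_point, shape)
    ):
        raise IndexError(f"seed point {seed_point} outside grid of shape {shape}")
    grown = flood(volume.voxels, seed_point, tolerance=tolerance, connectivity=1)
    return SegmentationMask(grown, volume.spacing)


def robust_seed_point(volume: ImageVolume, center=None, half_width: int = 2):
    """Pick a seed voxel whose intensity is closest to the local median.

    Looks at a ``(2*half_width+1)^3`` neighbourhood around ``center``
    (defaults to the grid centre) and returns the voxel index whose value is
    nearest the neighbourhood median — a seed-selection protocol that is
    robust to single-voxel noise.
    """
    shape = volume.shape
    if center is None:
        center = tuple(n // 2 for n in shape)
    sl = tuple(
        slice(max(0, c - half_width), min(n, c + half_width + 1))
        for c, n in zip(center, shape)
    )
    patch = volume.voxels[sl]
    med = np.median(patch)
    off = np.unravel_index(np.argmin(np.abs(patch - med)), patch.shape)
    return tuple(s.start + o for s, o in zip(sl, off))


def fill_holes(mask: SegmentationMask) -> SegmentationMask:
    """Per-slice morphological hole filling (2-D, 4-connectivity).

    Background components not connected to the slice border become
    foreground; output is a superset of the input and the operation is
    idempotent.
    """
    structure = ndimage.generate_binary_structure(2, 1)  # 4-connectivity
    out = np.empty_like(mask.voxels)
    for k in range(mask.shape[2]):
        out[:, :, k] = ndimage.binary_fill_holes(mask.voxels[:, :, k], structure)
    return SegmentationMask(out, mask.spacing)


@dataclass(frozen=True)
class RoiSpec:
    """Axis-aligned square ROI in mm: centre (x, y) and area in mm^2."""

    center_mm: tuple
    area_mm2: float

    def slices(self, spacing) -> tuple:
        side = np.sqrt(self.area_mm2)
        sx, sy = spacing[0], spacing[1]
        x0 = int(round((self.center_mm[0] - 0.5 * side) / sx))
        x1 = int(round((self.center_mm[0] + 0.5 * side) / sx))
        y0 = int(round((self.center_mm[1] - 0.5 * side) / sy))
        y1 = int(round((self.center_mm[1] + 0.5 * side) / sy))
        return slice(x0, max(x1, x0 + 1)), slice(y0, max(y1, y0 + 1))


@dataclass(frozen=True)
class ImageQualityReport:
    """Slice-averaged ROI image-quality metrics.

    ``noise`` is the mean over the two background ROIs of the intensity SD;
    ``bi`` and ``cnr`` are NaN (flagged ``undefined``) when noise is zero.
    """

    noise: float
    bi: float
    cnr: float
    object_roi_area: float
    background_roi_area: float
    per_slice: "np.ndarray" = field(repr=False, default=None)

    @property
    def undefined(self) -> bool:
        return not (np.isfinite(self.bi) and np.isfinite(self.cnr))


#: default object ROI area (mm^2) — centre of the vessel cross-section
OBJECT_ROI_AREA = 94.0
#: default background ROI area (mm^2), one region left and one right
BACKGROUND_ROI_AREA = 100.0


def default_rois(volume: ImageVolume, object_area: float = OBJECT_ROI_AREA,
                 background_area: float = BACKGROUND_ROI_AREA):
    """Object ROI at the grid centre, background ROIs near left/right edges."""
    nx, ny = volume.shape[0], volume.shape[1]
    sx, sy = volume.spacing[0], volume.spacing[1]
    cx, cy = 0.5 * nx * sx, 0.5 * ny * sy
    side = np.sqrt(background_area)
    margin = 0.6 * side
    obj = RoiSpec((cx, cy), object_area)
    left = RoiSpec((margin, cy), background_area)
    right = RoiSpec((nx * sx - margin, cy), background_area)
    return obj, (left, right)


def image_quality(
    volume: ImageVolume,
    object_roi: RoiSpec | None = None,
    background_rois: Sequence[RoiSpec] | None = None,
) -> ImageQualityReport:
    """Noise, BI and CNR from ROI statistics, per slice then averaged."""
    if object_roi is None or background_rois is None:
        obj_default, bg_default = default_rois(volume)
        object_roi = object_roi or obj_default
        background_rois = background_rois or bg_default
    if len(background_rois) != 2:
        raise ValueError("exactly two background ROIs (left and right) are expected")

    ox, oy = object_roi.slices(volume.spacing)
    bg_slices = [roi.slices(volume.spacing) for roi in background_rois]
    nx, ny, nz = volume.shape
    for sx_, sy_ in [(ox, oy)] + bg_slices:
        if sx_.start < 0 or sy_.start < 0 or sx_.stop > nx or sy_.stop > ny:
            raise ValueError("ROI extends outside the image grid")

    rows = np.empty((nz, 3))
    for k in range(nz):
        obj_mean = volume.voxels[ox, oy, k].mean()
        bg_patches = [volume.voxels[bx, by, k] for bx, by in bg_slices]
        noise_k = float(np.mean([p.std(ddof=1) for p in bg_patches]))
        bg_mean = float(np.mean([p.mean() for p in bg_patches]))
        rows[k] = (noise_k, obj_mean, bg_mean)

    noise = float(rows[:, 0].mean())
    obj_mean = float(rows[:, 1].mean())
    bg_mean = float(rows[:, 2].mean())
    if noise > 0:
        bi = obj_mean / noise
        cnr = (obj_mean - bg_mean) / noise
    else:
        bi = cnr = float("nan")
    return ImageQualityReport(
        noise=noise,
        bi=bi,
        cnr=cnr,
        object_roi_area=object_roi.area_mm2,
        background_roi_area=background_rois[0].area_mm2,
        per_slice=rows,
    )


def compare_masks(estimated: SegmentationMask, truth: SegmentationMask):
    """(relative volume error %, Dice coefficient) of two masks."""
    if estimated.shape != truth.shape:
        raise ValueError("masks must share a shape")
    if estimated.spacing != truth.spacing:
        raise ValueError("masks must share voxel spacing")
    n_true = int(np.count_nonzero(truth.voxels))
    if n_true == 0:
        raise ValueError("truth mask is empty")
    n_est = int(np.count_nonzero(estimated.voxels))
    n_both = int(np.count_nonzero(estimated.voxels & truth.voxels))
    rel_err = abs(n_est - n_true) / n_true * 100.0
    dice = 2.0 * n_both / (n_est + n_true) if (n_est + n_true) else 1.0
    return rel_err, dice
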