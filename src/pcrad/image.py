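"""3D image containers, I/O and the preprocessing chain used before feature extraction.

Volumes are plain numpy arrays in (z, y, x) index order with a physical voxel
spacing in mm.  The preprocessing chain applied before radiomic feature
extraction is: voxelwise subtraction (post - pre contrast), whole-volume
intensity normalization to mean 0 / sd 100, isotropic resampling to 0.90 mm
cubes (cubic b-spline for the image, nearest-neighbour for the mask) and
fixed-bin-count discretization of the masked intensities into Ng = 8 gray
levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "ImageVolume",
    "BinaryMask",
    "DiscretizedROI",
    "read_volume",
    "write_volume",
    "subtract_images",
    "normalize_intensity",
    "resample_isotropic",
    "discretize_fixed_bin_count",
]


@dataclass(frozen=True)
class ImageVolume:
    """A 3D scalar grid with physical voxel spacing (mm) and origin (mm)."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("volume contains non-finite values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryMask:
    """A boolean lesion mask aligned to an :class:`ImageVolume` grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={values.ndim}")
        object.__setattr__(self, "values", values.astype(bool))
        spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in spacing):
            raise ValueError("spacing must be positive")
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def n_voxels(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class DiscretizedROI:
    """Masked voxels mapped to integer gray levels 1..n_bins.

    ``levels`` is a full 3D integer array with 0 outside the mask so that
    spatial texture matrices can be computed directly; ``degenerate`` flags a
    constant ROI (all voxels assigned level 1).
    """

    levels: np.ndarray
    mask: np.ndarray
    n_bins: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        levels = np.asarray(self.levels, dtype=np.int64)
        mask = np.asarray(self.mask, dtype=bool)
        if levels.shape != mask.shape:
            raise ValueError("levels and mask shapes differ")
        if not mask.any():
            raise ValueError("empty ROI")
        inside = levels[mask]
        if inside.min() < 1 or inside.max() > self.n_bins:
            raise ValueError("levels outside [1, n_bins]")
        object.__setattr__(self, "levels", levels)
        object.__setattr__(self, "mask", mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    @property
    def voxel_coordinates(self) -> np.ndarray:
        return np.argwhere(self.mask)


def _sitk_from_volume(values: np.ndarray, spacing, origin):
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(values))
    # SimpleITK orders spacing/origin (x, y, z); arrays are (z, y, x)
    img.SetSpacing(tuple(spacing[::-1]))
    img.SetOrigin(tuple(origin[::-1]))
    return img


def read_volume(path: str | Path, as_mask: bool = False) -> ImageVolume | BinaryMask:
    """Read a NIfTI or NRRD volume into an :class:`ImageVolume` / :class:`BinaryMask`."""
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    values = sitk.GetArrayFromImage(img)
    spacing = tuple(img.GetSpacing())[::-1]
    origin = tuple(img.GetOrigin())[::-1]
    if as_mask:
        return BinaryMask(values > 0.5, spacing, origin)
    return ImageVolume(values.astype(float), spacing, origin)


def write_volume(vol: ImageVolume | BinaryMask, path: str | Path) -> None:
    """Write a volume or mask as NIfTI/NRRD (format chosen by extension)."""
    import SimpleITK as sitk

    values = vol.values.astype(np.uint8) if isinstance(vol, BinaryMask) else vol.values
    sitk.WriteImage(_sitk_from_volume(values, vol.spacing, vol.origin), str(path))


def _check_aligned(a, b, what: str) -> None:
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    if not np.allclose(a.spacing, b.spacing):
        raise ValueError(f"{what}: spacing mismatch {a.spacing} vs {b.spacing}")


def subtract_images(pre: ImageVolume, post: ImageVolume) -> ImageVolume:
    """Voxelwise post-contrast minus pre-contrast image."""
    _check_aligned(pre, post, "subtract_images")
    return ImageVolume(post.values - pre.values, post.spacing, post.origin)


def normalize_intensity(
    vol: ImageVolume,
    scale: float = 100.0,
    mask: BinaryMask | None = None,
) -> ImageVolume:
    """Force the intensity mean to 0 and standard deviation to ``scale``.

    Statistics are computed over the whole volume by default; pass ``mask`` to
    use ROI-only statistics instead.
    """
    region = vol.values[mask.values] if mask is not None else vol.values
    mu = float(region.mean())
    sd = float(region.std())
    if sd == 0:
        raise ValueError("constant volume: normalization undefined")
    return ImageVolume((vol.values - mu) / sd * scale, vol.spacing, vol.origin)


def resample_isotropic(
    vol: ImageVolume, mask: BinaryMask, target: float = 0.90
) -> tuple[ImageVolume, BinaryMask]:
    """Resample volume and mask to isotropic cubes of side ``target`` mm.

    The image is interpolated with cubic b-splines, the mask with nearest
    neighbour (so it stays binary).
    """
    import SimpleITK as sitk

    if target <= 0:
        raise ValueError("target spacing must be positive")
    _check_aligned(vol, mask, "resample_isotropic")

    img = _sitk_from_volume(vol.values, vol.spacing, vol.origin)
    msk = _sitk_from_volume(mask.values.astype(np.uint8), mask.spacing, mask.origin)
    old_size = np.array(img.GetSize(), dtype=float)  # (x, y, z)
    old_spacing = np.array(img.GetSpacing(), dtype=float)
    new_size = np.maximum(1, np.round(old_size * old_spacing / target)).astype(int)

    def _resample(src, interp):
        rs = sitk.ResampleImageFilter()
        rs.SetOutputSpacing((target, target, target))
        rs.SetSize([int(s) for s in new_size])
        rs.SetOutputOrigin(src.GetOrigin())
        rs.SetOutputDirection(src.GetDirection())
        rs.SetInterpolator(interp)
        rs.SetDefaultPixelValue(0)
        return rs.Execute(src)

    out_img = sitk.GetArrayFromImage(_resample(img, sitk.sitkBSpline))
    out_msk = sitk.GetArrayFromImage(_resample(msk, sitk.sitkNearestNeighbor)) > 0.5
    if not out_msk.any():
        raise ValueError("mask is empty after resampling")
    spacing = (target, target, target)
    return (
        ImageVolume(out_img, spacing, vol.origin),
        BinaryMask(out_msk, spacing, mask.origin),
    )


def discretize_fixed_bin_count(
    vol: ImageVolume, mask: BinaryMask, n_bins: int = 8
) -> DiscretizedROI:
    """Map masked intensities to levels 1..n_bins with equal-width bins.

    Bins span [min, max] of the masked intensities; the maximum maps to level
    ``n_bins``.  A constant ROI is assigned level 1 everywhere and flagged
    degenerate.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    _check_aligned(vol, mask, "discretize_fixed_bin_count")
    if not mask.values.any():
        raise ValueError("empty mask")

    inside = vol.values[mask.values]
    lo, hi = float(inside.min()), float(inside.max())
    levels = np.zeros(vol.shape, dtype=np.int64)
    if hi == lo:
        levels[mask.values] = 1
        warnings.warn("constant ROI: all voxels assigned level 1", stacklevel=2)
        return DiscretizedROI(levels, mask.values, n_bins, degenerate=True)
    width = (hi - lo) / n_bins
    lv = np.floor((inside - lo) / width).astype(np.int64) + 1
    levels[mask.values] = np.minimum(lv, n_bins)
    return DiscretizedROI(levels, mask.values, n_bins)
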