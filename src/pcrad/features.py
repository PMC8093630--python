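"""The five radiomic features retained after feature reduction.

F1  sphericity                          — shape, from the triangulated mask surface
F2  kurtosis (Pearson, non-excess)      — first order, on continuous intensities
F3  GLDM dependence variance            — texture (gray level dependence matrix)
F4  GLRLM long-run high-gray-level emphasis — texture (run length matrix)
F5  GLSZM high-gray-level zone emphasis — texture (size zone matrix)

Texture features operate on a :class:`~pcrad.image.DiscretizedROI` (gray
levels 1..Ng inside the lesion mask).  GLDM and GLSZM use the 26-voxel
(Chebyshev distance 1) neighbourhood; GLRLM scans maximal runs along the 13
unique 3D directions and averages the per-direction statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import BinaryMask, DiscretizedROI, ImageVolume
from .image import discretize_fixed_bin_count, normalize_intensity, resample_isotropic

__all__ = [
    "RadiomicVector",
    "ExtractionParams",
    "sphericity",
    "kurtosis",
    "gldm_dependence_variance",
    "glrlm_lrhgle",
    "glszm_hglze",
    "extract_features",
    "DIRECTIONS_13",
]

# 13 unique 3D directions (one per axis pair up to sign), (dz, dy, dx)
DIRECTIONS_13: tuple[tuple[int, int, int], ...] = tuple(
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
)

_OFFSETS_26 = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) != (0, 0, 0)
]


@dataclass(frozen=True)
class RadiomicVector:
    """The five selected features for one lesion."""

    F1: float  # sphericity, in (0, ~1]
    F2: float  # kurtosis, >= 1
    F3: float  # GLDM dependence variance, >= 0
    F4: float  # GLRLM long run high gray level emphasis, >= 0
    F5: float  # GLSZM high gray level zone emphasis, >= 0

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in ("F1", "F2", "F3", "F4", "F5")}


@dataclass(frozen=True)
class ExtractionParams:
    """Preprocessing parameters for feature extraction.

    Defaults follow the extraction protocol: whole-volume normalization to
    mean 0 / sd 100, isotropic resampling to 0.90 mm, fixed bin count 8.
    """

    target_spacing: float = 0.90
    n_bins: int = 8
    normalization_scale: float = 100.0
    normalize_roi_only: bool = False
    gldm_alpha: int = 0
    gldm_count_center: bool = True


def _shift(arr: np.ndarray, offset: tuple[int, int, int], fill) -> np.ndarray:
    """Return arr translated by -offset so out[v] = arr[v + offset]."""
    out = np.full_like(arr, fill)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(offset):
        n = arr.shape[ax]
        if abs(d) >= n:
            return out
        if d > 0:
            src[ax], dst[ax] = slice(d, n), slice(0, n - d)
        elif d < 0:
            src[ax], dst[ax] = slice(0, n + d), slice(-d, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _mesh_volume_area(verts: np.ndarray, faces: np.ndarray) -> tuple[float, float]:
    from skimage import measure

    tri = verts[faces]  # (n_faces, 3, 3)
    volume = abs(np.einsum("ij,ij->", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])) / 6.0)
    return float(volume), float(measure.mesh_surface_area(verts, faces))


def sphericity(mask: BinaryMask, spacing: tuple[float, float, float] | None = None) -> float:
    """Mesh-based sphericity (36 pi V^2)^(1/3) / A.

    V and A are the volume and surface area of the triangle mesh obtained by
    marching cubes on the 0.5 iso-level of the (zero-padded) mask.  The raw
    marching-cubes surface of a voxelized shape carries staircase artifacts
    that inflate A (a digital ball plateaus near 0.92 instead of 1), so the
    mesh is regularized with Taubin smoothing; when smoothing would collapse
    a thin structure (mesh volume loss above 50%), the raw mesh is used
    instead.  Equals 1 for a perfect sphere and decreases for irregular
    shapes; dimensionless, hence invariant to uniform spacing rescaling.
    """
    import trimesh
    from skimage import measure

    if not mask.values.any():
        raise ValueError("empty mask")
    spacing = tuple(spacing) if spacing is not None else mask.spacing
    padded = np.pad(mask.values.astype(float), 1)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    volume, area = _mesh_volume_area(verts, faces)

    smooth = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    trimesh.smoothing.filter_taubin(smooth, lamb=0.5, nu=-0.53, iterations=20)
    vol_s, area_s = _mesh_volume_area(np.asarray(smooth.vertices), np.asarray(smooth.faces))
    if vol_s >= 0.5 * volume:
        volume, area = vol_s, area_s
    return float((36.0 * np.pi * volume**2) ** (1.0 / 3.0) / area)


def kurtosis(vol: ImageVolume, mask: BinaryMask) -> float:
    """Pearson (non-excess) kurtosis m4 / m2^2 of the masked intensities.

    Population central moments, no bias correction; a Gaussian gives 3.
    """
    x = vol.values[mask.values]
    if x.size < 4:
        raise ValueError("kurtosis needs at least 4 masked voxels")
    d = x - x.mean()
    m2 = np.mean(d**2)
    if m2 == 0:
        raise ValueError("zero variance in ROI")
    return float(np.mean(d**4) / m2**2)


def gldm_dependence_variance(
    roi: DiscretizedROI, alpha: int = 0, count_center: bool = True
) -> float:
    """Dependence variance of the gray level dependence matrix.

    A voxel's dependence is (1 if ``count_center`` else 0) plus the number of
    in-mask 26-neighbours whose level differs from the centre's by at most
    ``alpha``.  The feature is the variance of the dependence size j under the
    normalized GLDM p(i, j), which equals the population variance of the
    per-voxel dependences.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    levels, mask = roi.levels, roi.mask
    dep = np.zeros(levels.shape, dtype=np.int64)
    for off in _OFFSETS_26:
        nb_mask = _shift(mask, off, False)
        nb_level = _shift(levels, off, 0)
        dep += (nb_mask & (np.abs(nb_level - levels) <= alpha)) & mask
    d = dep[mask] + (1 if count_center else 0)
    return float(np.mean((d - d.mean()) ** 2))


def _runs_along(levels: np.ndarray, mask: np.ndarray, direction) -> tuple[np.ndarray, np.ndarray]:
    """Maximal runs of equal level along one direction: (level, length) arrays.

    A run breaks at the mask/grid boundary or at a level change; voxels outside
    the mask never belong to a run.
    """
    prev_mask = _shift(mask, tuple(-d for d in direction), False)
    prev_level = _shift(levels, tuple(-d for d in direction), 0)
    starts = mask & (~prev_mask | (prev_level != levels))
    coords = np.argwhere(starts)
    run_levels = levels[starts]
    lengths = np.ones(len(coords), dtype=np.int64)
    cur = coords
    active = np.arange(len(coords))
    shape = np.array(levels.shape)
    d = np.array(direction)
    while active.size:
        nxt = cur + d
        inb = np.all((nxt >= 0) & (nxt < shape), axis=1)
        cont = np.zeros(len(cur), dtype=bool)
        if inb.any():
            idx = tuple(nxt[inb].T)
            cont[inb] = mask[idx] & (levels[idx] == run_levels[active[inb]])
        lengths[active[cont]] += 1
        active, cur = active[cont], nxt[cont]
    return run_levels, lengths


def glrlm_lrhgle(roi: DiscretizedROI) -> float:
    """GLRLM long run high gray level emphasis, averaged over 13 directions.

    Per direction: (1/Nr) sum over runs of level^2 * length^2 where Nr is the
    total run count for that direction.
    """
    vals = []
    for direction in DIRECTIONS_13:
        lv, ln = _runs_along(roi.levels, roi.mask, direction)
        vals.append(np.mean((lv.astype(float) ** 2) * (ln.astype(float) ** 2)))
    return float(np.mean(vals))


def glszm_hglze(roi: DiscretizedROI) -> float:
    """GLSZM high gray level zone emphasis.

    Zones are 26-connected components of equal level within the mask; the
    feature is (1/Nz) sum over zones of level^2.
    """
    structure = np.ones((3, 3, 3), dtype=bool)
    total = 0.0
    n_zones = 0
    for level in np.unique(roi.levels[roi.mask]):
        _, k = ndimage.label(roi.levels == level, structure=structure)
        total += k * float(level) ** 2
        n_zones += k
    return total / n_zones


def extract_features(
    dynamic: ImageVolume,
    subtracted: ImageVolume,
    mask: BinaryMask,
    params: ExtractionParams = ExtractionParams(),
) -> RadiomicVector:
    """Run the full preprocessing chain and compute F1..F5.

    F2 (kurtosis), F4 (GLRLM LRHGLE) and F5 (GLSZM HGLZE) are computed on the
    dynamic post-contrast channel; F1 (sphericity) and F3 (GLDM dependence
    variance) on the subtracted channel.  Each channel is normalized,
    resampled isotropically and (for texture) discretized independently.
    """

    def _prep(vol: ImageVolume):
        norm = normalize_intensity(
            vol,
            scale=params.normalization_scale,
            mask=mask if params.normalize_roi_only else None,
        )
        return resample_isotropic(norm, mask, params.target_spacing)

    dyn_vol, dyn_mask = _prep(dynamic)
    sub_vol, sub_mask = _prep(subtracted)

    dyn_roi = discretize_fixed_bin_count(dyn_vol, dyn_mask, params.n_bins)
    sub_roi = discretize_fixed_bin_count(sub_vol, sub_mask, params.n_bins)

    return RadiomicVector(
        F1=sphericity(sub_mask),
        F2=kurtosis(dyn_vol, dyn_mask),
        F3=gldm_dependence_variance(
            sub_roi, alpha=params.gldm_alpha, count_center=params.gldm_count_center
        ),
        F4=glrlm_lrhgle(dyn_roi),
        F5=glszm_hglze(dyn_roi),
    )
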