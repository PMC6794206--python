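"""Volume I/O, isotropic resampling and myocardial segmentation.

Volumes are stored as ``ImageVolume``: a 3D scalar array indexed ``[x, y, z]``
with per-axis voxel spacing in micrometres. ``z`` is the stack axis (slice
index in a multi-page TIFF); by convention the ventricular base sits at low
``z`` and the apex at high ``z``. Physical position of a voxel centre is
``origin_um + index * spacing_um``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import tifffile
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import ball

log = logging.getLogger(__name__)

__all__ = [
    "ImageVolume",
    "MyocardialMask",
    "load_volume",
    "save_volume",
    "save_mask",
    "resample_isotropic",
    "segment_myocardium",
]


@dataclass
class ImageVolume:
    """3D scalar field with voxel spacing metadata (micrometres)."""

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected 3D data, got ndim={self.data.ndim}")
        if min(self.data.shape) < 3:
            raise ValueError(f"each axis needs >= 3 voxels, got shape {self.data.shape}")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError(f"spacings must be positive, got {self.spacing_um}")
        self.origin_um = tuple(float(o) for o in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_isotropic(self) -> bool:
        s = self.spacing_um
        return abs(s[0] - s[1]) < 1e-9 and abs(s[0] - s[2]) < 1e-9

    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))


@dataclass
class MyocardialMask:
    """Binary myocardium mask aligned to an ImageVolume."""

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_meta: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise ValueError("mask is empty")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def n_voxels(self) -> int:
        return int(self.data.sum())


def _affine_from_spacing(spacing_um, origin_um) -> np.ndarray:
    aff = np.diag([spacing_um[0], spacing_um[1], spacing_um[2], 1.0])
    aff[:3, 3] = origin_um
    return aff


def load_volume(path, spacing_override=None) -> ImageVolume:
    """Read a multi-page TIFF stack or a NIfTI file into an ImageVolume.

    TIFF pages become z-slices, so a stack of N pages of shape (rows, cols)
    loads as an (cols, rows, N) array in ``[x, y, z]`` index order. TIFF
    carries no physical spacing here, so ``spacing_override`` (μm per axis,
    or a scalar for isotropic) is required for TIFF input. NIfTI spacing is
    taken from the header zooms unless overridden.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        pages = tifffile.imread(str(path))  # (z, rows, cols) for a stack
        if pages.ndim == 2:
            pages = pages[None]
        data = np.ascontiguousarray(np.transpose(pages, (2, 1, 0)))
        if spacing_override is None:
            raise ValueError(
                f"{path.name}: TIFF carries no voxel spacing; pass spacing_override"
            )
        spacing = _as_spacing(spacing_override)
        vol = ImageVolume(data, spacing)
    elif suffixes.endswith((".nii", ".nii.gz")):
        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj)
        zooms = img.header.get_zooms()[:3]
        spacing = _as_spacing(spacing_override) if spacing_override is not None else tuple(
            float(z) for z in zooms
        )
        if any(s <= 0 for s in spacing):
            raise ValueError(f"{path.name}: non-positive spacing {spacing} and no override")
        vol = ImageVolume(data, spacing)
    else:
        raise ValueError(f"unsupported volume format: {path.name}")
    log.info("loaded %s shape=%s spacing_um=%s", path.name, vol.shape, vol.spacing_um)
    return vol


def _as_spacing(value) -> tuple[float, float, float]:
    if np.isscalar(value):
        return (float(value),) * 3
    value = tuple(float(v) for v in value)
    if len(value) != 3:
        raise ValueError("spacing needs 3 entries (x, y, z)")
    return value


def save_volume(vol: ImageVolume, path) -> None:
    """Write as multi-page 16-bit TIFF (.tif) or NIfTI (.nii/.nii.gz)."""
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".tif", ".tiff")):
        data = vol.data
        if data.dtype != np.uint16:
            lo, hi = float(data.min()), float(data.max())
            scale = 65535.0 / (hi - lo) if hi > lo else 1.0
            data = ((data - lo) * scale).astype(np.uint16)
        tifffile.imwrite(str(path), np.transpose(data, (2, 1, 0)), photometric="minisblack")
    elif suffixes.endswith((".nii", ".nii.gz")):
        img = nib.Nifti1Image(
            np.asarray(vol.data, dtype=np.float32),
            _affine_from_spacing(vol.spacing_um, vol.origin_um),
        )
        img.header.set_zooms(vol.spacing_um)
        nib.save(img, str(path))
    else:
        raise ValueError(f"unsupported output format: {path.name}")


def save_mask(mask: MyocardialMask, path) -> None:
    """Write a mask as 8-bit NIfTI."""
    img = nib.Nifti1Image(
        mask.data.astype(np.uint8), _affine_from_spacing(mask.spacing_um, mask.origin_um)
    )
    img.header.set_zooms(mask.spacing_um)
    nib.save(img, str(path))


def load_mask(path, spacing_override=None) -> MyocardialMask:
    vol = load_volume(path, spacing_override=spacing_override)
    return MyocardialMask(vol.data > 0, vol.spacing_um, vol.origin_um)


def resample_isotropic(vol: ImageVolume, target_um: float | None = None) -> ImageVolume:
    """Trilinear resampling onto an isotropic grid.

    Default target edge is the in-plane pixel edge (x spacing), so a stack
    with coarse or fine z-sectioning is resampled along z to match the image
    plane — e.g. 30.03 μm² pixels give a 5.48 μm cubic voxel of volume
    30.03^1.5 = 164.57 μm³.
    """
    if target_um is None:
        target_um = vol.spacing_um[0]
    target_um = float(target_um)
    if target_um <= 0:
        raise ValueError("target_um must be positive")
    if vol.is_isotropic and abs(vol.spacing_um[0] - target_um) < 1e-12:
        return ImageVolume(vol.data.copy(), vol.spacing_um, vol.origin_um)
    zoom = [s / target_um for s in vol.spacing_um]
    data = ndimage.zoom(vol.data.astype(np.float64), zoom, order=1, mode="nearest")
    out = ImageVolume(data, (target_um,) * 3, vol.origin_um)
    log.info(
        "resampled %s @ %s um -> %s @ %.4g um", vol.shape, vol.spacing_um, out.shape, target_um
    )
    return out


def segment_myocardium(vol: ImageVolume, min_component_voxels: int = 64) -> MyocardialMask:
    """Automatic myocardium segmentation.

    Otsu threshold, keep the largest connected foreground component (and any
    others above ``min_component_voxels``), 1-voxel-radius morphological
    closing, then 3D hole filling. The ventricular cavity reaches the volume
    border through the open base, so 3D filling closes intramural holes
    without swallowing the cavity.
    """
    if not vol.is_isotropic:
        raise ValueError("segment an isotropic volume (run resample_isotropic first)")
    data = np.asarray(vol.data, dtype=np.float64)
    if np.ptp(data) == 0:
        raise ValueError("constant-valued volume: no foreground to segment")
    thr = threshold_otsu(data)
    fg = data > thr
    if not fg.any():
        raise ValueError("empty foreground after Otsu thresholding")
    labels, n = ndimage.label(fg)
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.flatnonzero((sizes >= min_component_voxels) | (sizes == sizes.max())) + 1
    mask = np.isin(labels, keep)
    # edge-pad so the closing does not erode structures that touch the volume
    # border (an open base reaches the boundary by construction)
    padded = np.pad(mask, 1, mode="edge")
    padded = ndimage.binary_closing(padded, structure=ball(1))
    mask = padded[1:-1, 1:-1, 1:-1]
    mask = ndimage.binary_fill_holes(mask)
    meta = f"otsu={thr:.4g};min_component={min_component_voxels};closing=ball(1);fill=3d"
    return MyocardialMask(mask, vol.spacing_um, vol.origin_um, label_meta=meta)
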