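"""Structure-tensor orientation estimation and helical/intrusion angle maps.

The structure tensor at a voxel is the window average of the outer product of
Gaussian-derivative image gradients, J = ⟨∇I ∇Iᵀ⟩. Its eigenvector with the
smallest eigenvalue (v3) points along the direction of least intensity
variation — the myocyte long axis, defined only up to sign. Angles are then
measured in the local wall frame:

* helical angle  α_H = arcsin(v3·g2): elevation of the fibre out of the local
  circumferential plane (g1, g3); positive = right-handed helix at the
  endocardium;
* intrusion angle α_I = arcsin(v3·g1): elevation out of the epicardial
  tangential plane (g2, g3); positive = intruding toward the epicardium.

Raw helical angle lives in [−90°, +90°] and wraps at ±90° where fibres pass
through the longitudinal direction (papillary insertions); per-ray unwrapping
expands the dynamic range to [−90°, +150°) so transmural profiles stay
continuous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .geometry import LocalFrameField, SegmentModel
from .io import ImageVolume, MyocardialMask

log = logging.getLogger(__name__)

__all__ = [
    "StructureTensorField",
    "AngleMaps",
    "TransmuralProfile",
    "structure_tensor",
    "orientation_from_vectors",
    "helical_angle",
    "intrusion_angle",
    "unwrap_profile",
    "unwrap_helical",
    "transmural_profiles",
    "circumferential_fraction",
    "angle_histograms",
    "ks_two_sample",
]

HA_MIN, HA_MAX = -90.0, 150.0


@dataclass
class StructureTensorField:
    """Per-voxel eigen-decomposition of the structure tensor (λ1 ≥ λ2 ≥ λ3)."""

    eigvals: np.ndarray  # (X, Y, Z, 3), descending
    v1: np.ndarray  # (X, Y, Z, 3)
    v2: np.ndarray
    v3: np.ndarray  # smallest-eigenvalue eigenvector: the fibre axis (±)
    valid: np.ndarray  # (X, Y, Z) bool


@dataclass
class AngleMaps:
    """Helical (unwrapped, [−90, +150)) and intrusion ([−90, +90]) angle maps."""

    ha_deg: np.ndarray
    ia_deg: np.ndarray


@dataclass
class TransmuralProfile:
    """Depth-binned helical angle in one segment with its linear fit."""

    segment_id: int
    level: int
    sector: int
    depth_samples: np.ndarray  # bin centres, normalised depth
    x_um: np.ndarray  # bin centres, physical wall depth
    ha_deg_samples: np.ndarray
    beta1: float  # °/μm
    beta0: float
    r2: float
    insufficient: bool = False


def structure_tensor(
    vol: ImageVolume,
    mask: MyocardialMask | None = None,
    window_voxels: int = 3,
    gradient_sigma_um: float | None = None,
    noise_floor_rel: float = 1e-6,
) -> StructureTensorField:
    """Compute per-voxel structure tensors and their eigen-decomposition.

    Gradients are Gaussian derivatives at scale ``gradient_sigma_um`` (default
    one voxel edge); outer products are averaged over a cubic window of
    ``window_voxels`` per side (default 3: the voxel and its 26 neighbours).
    Voxels whose largest eigenvalue falls below ``noise_floor_rel`` times the
    volume maximum carry no orientation signal and are flagged invalid.
    """
    if not vol.is_isotropic:
        raise ValueError("anisotropic volume: resample_isotropic before structure_tensor")
    if window_voxels < 3 or window_voxels % 2 == 0:
        raise ValueError("window_voxels must be an odd count >= 3")
    spacing = vol.spacing_um[0]
    sigma_vox = (gradient_sigma_um or spacing) / spacing
    data = np.asarray(vol.data, dtype=np.float64)
    grads = [ndimage.gaussian_filter(data, sigma_vox, order=tuple(int(i == ax) for i in range(3)))
             for ax in range(3)]
    J = np.empty(data.shape + (3, 3), dtype=np.float64)
    for i in range(3):
        for j in range(i, 3):
            Jij = ndimage.uniform_filter(grads[i] * grads[j], size=window_voxels)
            J[..., i, j] = Jij
            J[..., j, i] = Jij

    sel = mask.data if mask is not None else np.ones(data.shape, dtype=bool)
    w, v = np.linalg.eigh(J[sel])  # ascending eigenvalues, eigenvectors in columns
    shape = data.shape
    eigvals = np.zeros(shape + (3,), dtype=np.float32)
    v1 = np.zeros(shape + (3,), dtype=np.float32)
    v2 = np.zeros(shape + (3,), dtype=np.float32)
    v3 = np.zeros(shape + (3,), dtype=np.float32)
    eigvals[sel] = w[:, ::-1]
    v1[sel] = v[..., 2]
    v2[sel] = v[..., 1]
    v3[sel] = v[..., 0]
    lam1 = eigvals[..., 0]
    floor = noise_floor_rel * float(lam1.max()) if lam1.max() > 0 else np.inf
    valid = sel & (lam1 > floor)
    log.info("structure tensor: %d/%d voxels valid", int(valid.sum()), int(sel.sum()))
    return StructureTensorField(eigvals, v1, v2, v3, valid)


def orientation_from_vectors(vectors: np.ndarray, valid: np.ndarray) -> StructureTensorField:
    """Wrap a known unit-vector field (e.g. phantom ground truth) as an
    orientation field, bypassing the image pipeline."""
    vectors = np.asarray(vectors, dtype=np.float32)
    eigvals = np.zeros(vectors.shape[:3] + (3,), dtype=np.float32)
    eigvals[valid] = (1.0, 1.0, 0.0)
    zeros = np.zeros_like(vectors)
    return StructureTensorField(eigvals, zeros, zeros, vectors, np.asarray(valid, bool))


def _signed_v3(orient: StructureTensorField, frames: LocalFrameField) -> np.ndarray:
    """Resolve the ± ambiguity of v3: point it along +g3 (or +g2 when it is
    orthogonal to g3), so angle signs follow the frame conventions."""
    v3 = orient.v3.astype(np.float64)
    d3 = np.sum(v3 * frames.g3, axis=-1)
    d2 = np.sum(v3 * frames.g2, axis=-1)
    sign = np.where(np.abs(d3) > 1e-6, np.sign(d3), np.sign(d2))
    sign = np.where(sign == 0, 1.0, sign)
    return v3 * sign[..., None]


def helical_angle(orient: StructureTensorField, frames: LocalFrameField) -> np.ndarray:
    """Raw helical angle map in degrees, range [−90, +90]; NaN where invalid."""
    v3 = _signed_v3(orient, frames)
    ha = np.degrees(np.arcsin(np.clip(np.sum(v3 * frames.g2, axis=-1), -1.0, 1.0)))
    ha[~(orient.valid & frames.valid)] = np.nan
    return ha.astype(np.float32)


def intrusion_angle(orient: StructureTensorField, frames: LocalFrameField) -> np.ndarray:
    """Intrusion angle map in degrees, range [−90, +90]; NaN where invalid."""
    v3 = _signed_v3(orient, frames)
    ia = np.degrees(np.arcsin(np.clip(np.sum(v3 * frames.g1, axis=-1), -1.0, 1.0)))
    ia[~(orient.valid & frames.valid)] = np.nan
    return ia.astype(np.float32)


def unwrap_profile(samples: np.ndarray) -> np.ndarray:
    """Unwrap one endo→epi sequence of helical angles.

    Wherever consecutive finite samples jump by more than 90° the later
    samples are shifted by ±180° to restore continuity. The continuous ray is
    then re-anchored: the first sample fixes only the profile's shape, and if
    it was itself wrapped (raw values next to the +90° pole are the least
    reliable) the whole ray sits a multiple of 180° off, so the global
    180°-offset that brings the most samples into the [−90, +150) dynamic
    range is applied before clipping to that range.
    """
    out = np.asarray(samples, dtype=np.float64).copy()
    offset = 0.0
    prev = None
    for i, val in enumerate(out):
        if not np.isfinite(val):
            continue
        cur = val + offset
        if prev is not None:
            jump = cur - prev
            if jump > 90.0:
                offset -= 180.0
                cur -= 180.0
            elif jump < -90.0:
                offset += 180.0
                cur += 180.0
        out[i] = cur
        prev = cur
    finite = np.isfinite(out)
    if finite.any():
        best_k, best_score = 0, -1
        for k in (0, 1, -1, 2, -2):
            vals = out[finite] + 180.0 * k
            score = int(np.sum((vals >= HA_MIN) & (vals < HA_MAX)))
            if score > best_score:
                best_k, best_score = k, score
        out = out + 180.0 * best_k
    return np.clip(out, HA_MIN, np.nextafter(HA_MAX, -np.inf))


def unwrap_helical(
    ha_raw: np.ndarray,
    frames: LocalFrameField,
    mask: MyocardialMask,
    theta_bin_deg: float = 3.0,
) -> np.ndarray:
    """Unwrap the raw helical angle map along transmural rays.

    Voxels are grouped into thin rays by circumferential angle and long-axis
    position, ordered endo→epi by depth, and each ray is unwrapped with
    :func:`unwrap_profile`, expanding the dynamic range to [−90°, +150°).
    """
    axis = frames.axis
    spacing = np.asarray(mask.spacing_um)
    idx = np.argwhere(mask.data & np.isfinite(ha_raw))
    pos = idx * spacing + np.asarray(mask.origin_um)
    d = pos - axis.base_point_um
    ell = d @ axis.unit_axis
    e_u, e_v = axis.transverse_basis()
    theta = np.degrees(np.arctan2(d @ e_v, d @ e_u))
    t_bin = np.floor((theta + 180.0) / theta_bin_deg).astype(int)
    l_bin = np.floor(ell / (2.0 * spacing.min())).astype(int)
    depth = frames.depth[tuple(idx.T)]
    values = ha_raw[tuple(idx.T)].astype(np.float64)

    out = np.full(ha_raw.shape, np.nan, dtype=np.float32)
    order = np.lexsort((depth, l_bin, t_bin))
    keys = t_bin[order] * 100_000 + l_bin[order]
    starts = np.flatnonzero(np.r_[True, np.diff(keys) != 0])
    bounds = np.r_[starts, len(keys)]
    for s, e in zip(bounds[:-1], bounds[1:]):
        ray = order[s:e]
        out[tuple(idx[ray].T)] = unwrap_profile(values[ray])
    return out


def transmural_profiles(
    ha_deg: np.ndarray,
    frames: LocalFrameField,
    segments: SegmentModel,
    n_bins: int = 20,
    min_bins: int = 5,
) -> list[TransmuralProfile]:
    """Per-segment depth-binned helical angle profiles with OLS linear fits.

    The profile is the mean unwrapped helical angle in ``n_bins`` equal depth
    bins; depth is converted to physical micrometres through the segment's
    mean wall thickness so the slope β1 is reported in °/μm. R² is set to 0
    for a zero-variance response. Segments with fewer than ``min_bins``
    populated bins are flagged insufficient.
    """
    profiles = []
    finite = np.isfinite(ha_deg)
    for seg_id, level, sector in segments.segment_ids():
        sel = segments.segment_mask(level, sector) & finite
        if not sel.any():
            profiles.append(
                TransmuralProfile(seg_id, level, sector, np.array([]), np.array([]),
                                  np.array([]), np.nan, np.nan, np.nan, insufficient=True)
            )
            continue
        depth = frames.depth[sel].astype(np.float64)
        vals = ha_deg[sel].astype(np.float64)
        wall = float(np.mean(frames.wall_um[sel]))
        which = np.clip((depth * n_bins).astype(int), 0, n_bins - 1)
        sums = np.bincount(which, weights=vals, minlength=n_bins)
        cnts = np.bincount(which, minlength=n_bins)
        pop = cnts > 0
        centres = (np.arange(n_bins) + 0.5) / n_bins
        ha_bins = np.full(n_bins, np.nan)
        ha_bins[pop] = sums[pop] / cnts[pop]
        x_um = centres * wall
        n_pop = int(pop.sum())
        if n_pop < min_bins:
            profiles.append(
                TransmuralProfile(seg_id, level, sector, centres[pop], x_um[pop],
                                  ha_bins[pop], np.nan, np.nan, np.nan, insufficient=True)
            )
            continue
        x, y = x_um[pop], ha_bins[pop]
        beta1, beta0 = np.polyfit(x, y, 1)
        resid = y - (beta1 * x + beta0)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        r2 = 0.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
        profiles.append(
            TransmuralProfile(seg_id, level, sector, centres[pop], x, y,
                              float(beta1), float(beta0), float(np.clip(r2, 0.0, 1.0)))
        )
    return profiles


def circumferential_fraction(ha_deg: np.ndarray, region: np.ndarray) -> float:
    """Percentage of valid voxels in ``region`` with −10° < HA < +10° (strict)."""
    vals = ha_deg[region]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("empty region: no valid helical-angle voxels")
    return 100.0 * float(np.sum((vals > -10.0) & (vals < 10.0))) / vals.size


def angle_histograms(
    values_deg: np.ndarray,
    regions: dict[str, np.ndarray],
    bin_deg: float = 5.0,
    range_deg: tuple[float, float] = (HA_MIN, HA_MAX),
) -> dict[str, dict]:
    """Normalised per-region angle histograms (default 5° bins).

    Returns, per region, the bin edges, raw counts and the probability mass
    per bin (summing to 1).
    """
    edges = np.arange(range_deg[0], range_deg[1] + bin_deg / 2, bin_deg)
    out = {}
    for name, region in regions.items():
        vals = values_deg[region]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise ValueError(f"region {name!r} has no valid voxels")
        counts, _ = np.histogram(vals, bins=edges)
        out[name] = {
            "edges": edges,
            "counts": counts,
            "mass": counts / counts.sum(),
            "samples": vals,
        }
    return out


def ks_two_sample(a: np.ndarray, b: np.ndarray):
    """Two-sample Kolmogorov–Smirnov test between two angle samples."""
    a = np.asarray(a)[np.isfinite(a)]
    b = np.asarray(b)[np.isfinite(b)]
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
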