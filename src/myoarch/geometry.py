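"""LV long axis, prolate-spheroidal local frames, segment models, wall thickness.

The left ventricle is modelled as a half prolate spheroid. Every in-mask voxel
receives an orthonormal local triad

* ``g1`` — transmural, pointing outward (endocardium → epicardium),
* ``g2`` — longitudinal, pointing apex → base,
* ``g3`` — circumferential, ``g3 = g1 × g2`` (right-handed triad),

derived from prolate spheroidal coordinates (λ, μ, θ) with semi-foci distance
``f``, or from cylindrical coordinates for tubular test geometries where those
are exact. Normalised transmural depth (0 = endocardium, 1 = epicardium) is
computed geometrically from Euclidean distance to the cavity and exterior
surfaces, which keeps it in [0, 1] even where the spheroid fit is imperfect.

Conventions: the stack axis is ``z`` with the base at low ``z``; voxel indices
are 0-based; physical position = origin + index·spacing (voxel centres); all
lengths in micrometres.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import MyocardialMask

log = logging.getLogger(__name__)

__all__ = [
    "LVAxis",
    "LocalFrameField",
    "SegmentModel",
    "WallThicknessTable",
    "fit_axis",
    "build_frames",
    "assign_segments",
    "wall_thickness",
    "AHA16",
    "GRID45",
]

AHA16 = "AHA16"
GRID45 = "GRID45"

#: sectors per level, basal level first
_SCHEME_SECTORS = {AHA16: (6, 6, 4), GRID45: (9, 9, 9, 9, 9)}

LAYER_NAMES = ("inner", "mid-inner", "mid-outer", "outer")


@dataclass
class LVAxis:
    """LV long axis: base and apex points (μm) and the base→apex unit vector."""

    base_point_um: np.ndarray
    apex_point_um: np.ndarray

    def __post_init__(self) -> None:
        self.base_point_um = np.asarray(self.base_point_um, dtype=float)
        self.apex_point_um = np.asarray(self.apex_point_um, dtype=float)
        if self.lv_length_um <= 0:
            raise ValueError("base and apex coincide")

    @property
    def lv_length_um(self) -> float:
        return float(np.linalg.norm(self.apex_point_um - self.base_point_um))

    @property
    def unit_axis(self) -> np.ndarray:
        return (self.apex_point_um - self.base_point_um) / self.lv_length_um

    def transverse_basis(self) -> tuple[np.ndarray, np.ndarray]:
        """Fixed in-plane unit vectors (e_u, e_v) with (e_u, e_v, axis) right-handed.

        θ = atan2(d·e_v, d·e_u) defines the circumferential angle; sector 1 is
        centred on θ = sector0 (anterior by convention, configurable).
        """
        a = self.unit_axis
        ref = np.array([1.0, 0.0, 0.0])
        if abs(a @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e_u = ref - (ref @ a) * a
        e_u /= np.linalg.norm(e_u)
        e_v = np.cross(a, e_u)
        return e_u, e_v


@dataclass
class LocalFrameField:
    """Per-voxel orthonormal triads, transmural depth and validity."""

    g1: np.ndarray  # (X, Y, Z, 3) transmural outward
    g2: np.ndarray  # (X, Y, Z, 3) longitudinal apex→base
    g3: np.ndarray  # (X, Y, Z, 3) circumferential
    depth: np.ndarray  # (X, Y, Z) in [0, 1], 0 = endocardium
    wall_um: np.ndarray  # (X, Y, Z) local wall thickness (endo+epi distance sum)
    valid: np.ndarray  # (X, Y, Z) bool
    focus_um: float
    axis: LVAxis
    spacing_um: tuple[float, float, float]
    geometry: str = "prolate"
    cavity: np.ndarray | None = None  # background component forming the LV cavity


@dataclass
class SegmentModel:
    """Level/sector(/layer) labels. 0 marks unassigned voxels; labels are 1-based."""

    scheme: str
    level_of: np.ndarray
    sector_of: np.ndarray
    layer_of: np.ndarray | None  # GRID45 only: 1..4 from endocardium
    axis: LVAxis
    sector0_deg: float = 0.0

    @property
    def n_levels(self) -> int:
        return len(_SCHEME_SECTORS[self.scheme])

    def sectors_at(self, level: int) -> int:
        return _SCHEME_SECTORS[self.scheme][level - 1]

    def segment_ids(self):
        """Yield (segment_id, level, sector); ids are 1-based and contiguous."""
        seg = 1
        for level in range(1, self.n_levels + 1):
            for sector in range(1, self.sectors_at(level) + 1):
                yield seg, level, sector
                seg += 1

    @property
    def n_segments(self) -> int:
        return sum(_SCHEME_SECTORS[self.scheme])

    def segment_mask(self, level: int, sector: int) -> np.ndarray:
        return (self.level_of == level) & (self.sector_of == sector)

    def nonempty_segments(self) -> int:
        return sum(
            bool(self.segment_mask(level, sector).any())
            for _, level, sector in self.segment_ids()
        )


def fit_axis(mask: MyocardialMask, landmarks=None) -> LVAxis:
    """Fit the LV long axis from landmarks or the mask's principal axis.

    ``landmarks`` is a (base_point_um, apex_point_um) pair and is used verbatim
    when given. Otherwise the principal axis of the mask voxel cloud is taken,
    oriented base→apex using the base-at-low-z convention, with base/apex points
    set from the extreme mask slices along it.
    """
    if landmarks is not None:
        base, apex = landmarks
        return LVAxis(np.asarray(base, float), np.asarray(apex, float))
    spacing = np.asarray(mask.spacing_um)
    idx = np.argwhere(mask.data)
    pos = idx * spacing + np.asarray(mask.origin_um)
    centred = pos - pos.mean(axis=0)
    # planar masks have a near-zero extent along one principal direction
    cov = centred.T @ centred / len(centred)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < (0.75 * spacing.min()) ** 2:
        raise ValueError("degenerate (planar) mask: cannot fit a long axis")
    a = evecs[:, -1]
    if a[2] < 0:
        a = -a  # base at low z -> axis (base→apex) has positive z-component
    proj = centred @ a
    lo, hi = proj.min(), proj.max()
    voxel = spacing.min()
    base_pt = pos[proj <= lo + 0.5 * voxel].mean(axis=0)
    apex_pt = pos[proj >= hi - 0.5 * voxel].mean(axis=0)
    # place the points on the fitted axis line
    centre = pos.mean(axis=0)
    base_pt = centre + ((base_pt - centre) @ a) * a
    apex_pt = centre + ((apex_pt - centre) @ a) * a
    return LVAxis(base_pt, apex_pt)


def _voxel_positions(shape, spacing_um, origin_um):
    grids = np.meshgrid(
        *(np.arange(n) * s + o for n, s, o in zip(shape, spacing_um, origin_um)),
        indexing="ij",
    )
    return np.stack(grids, axis=-1)  # (X, Y, Z, 3)


def _find_cavity(mask_data: np.ndarray, axis: LVAxis, spacing_um, origin_um):
    """Label the background component holding the LV cavity.

    Seeded from points on the long axis between 20% and 70% of LV length; the
    remaining background is the exterior.
    """
    bg_labels, _ = ndimage.label(~mask_data)
    spacing = np.asarray(spacing_um)
    cav_label = 0
    for frac in np.linspace(0.2, 0.7, 11):
        p = axis.base_point_um + frac * axis.lv_length_um * axis.unit_axis
        ijk = np.round((p - np.asarray(origin_um)) / spacing).astype(int)
        if np.all(ijk >= 0) and np.all(ijk < mask_data.shape):
            lbl = bg_labels[tuple(ijk)]
            if lbl > 0:
                cav_label = lbl
                break
    if cav_label == 0:
        raise ValueError("could not locate the LV cavity from the long axis")
    cavity = bg_labels == cav_label
    exterior = ~mask_data & ~cavity
    return cavity, exterior


def _estimate_focus(axis: LVAxis, rho, ell, in_mask) -> float:
    """Semi-foci distance f = sqrt(L² − R²) of the prolate spheroid through the
    apex (on-axis at distance L from base) and the basal epicardial radius R."""
    L = axis.lv_length_um
    basal = in_mask & (ell < 0.15 * L)
    r_epi = np.percentile(rho[basal], 99) if basal.any() else np.percentile(rho[in_mask], 99)
    if r_epi >= L:
        raise ValueError("epicardial radius exceeds LV length: not a prolate geometry")
    return float(np.sqrt(L * L - r_epi * r_epi))


def build_frames(
    mask: MyocardialMask,
    axis: LVAxis,
    geometry: str = "prolate",
    focus_um: float | None = None,
) -> LocalFrameField:
    """Construct per-voxel local frames (g1, g2, g3) and transmural depth.

    ``geometry="prolate"`` uses prolate spheroidal coordinates aligned with the
    axis, centred on the base plane, with semi-foci distance ``focus_um``
    (estimated from LV length and basal epicardial radius when not given).
    ``geometry="cylindrical"`` uses exact cylindrical frames — appropriate for
    annular test phantoms. Voxels on the axis (circumferential direction
    undefined) are flagged invalid.
    """
    if geometry not in ("prolate", "cylindrical"):
        raise ValueError(f"unknown geometry {geometry!r}")
    md = mask.data
    pos = _voxel_positions(md.shape, mask.spacing_um, mask.origin_um)
    a = axis.unit_axis
    d = pos - axis.base_point_um
    ell = d @ a  # long-axis coordinate, 0 at base, L at apex
    radial = d - ell[..., None] * a
    rho = np.linalg.norm(radial, axis=-1)
    valid = md & (rho > 1e-9)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho_hat = radial / np.where(rho[..., None] > 1e-9, rho[..., None], 1.0)

    if geometry == "cylindrical":
        f = 0.0
        g1 = rho_hat.copy()
        g2 = np.broadcast_to(-a, g1.shape).copy()
    else:
        if focus_um is None:
            focus_um = _estimate_focus(axis, rho, ell, md)
        f = float(focus_um)
        # prolate coordinates about the base-plane centre; apex at xi = L
        xi = ell
        r1 = np.sqrt((xi + f) ** 2 + rho**2)
        r2 = np.sqrt((xi - f) ** 2 + rho**2)
        cosh_l = np.clip((r1 + r2) / (2 * f), 1.0, None)
        cos_m = np.clip((r1 - r2) / (2 * f), -1.0, 1.0)
        sinh_l = np.sqrt(cosh_l**2 - 1.0)
        sin_m = np.sqrt(1.0 - cos_m**2)
        # e_lambda = sinhλ cosμ a + coshλ sinμ ρ̂ ; e_mu = −coshλ sinμ a + sinhλ cosμ ρ̂
        ca = (sinh_l * cos_m)[..., None]
        cr = (cosh_l * sin_m)[..., None]
        g1 = ca * a + cr * rho_hat
        g2 = -cr * a + ca * rho_hat
        n1 = np.linalg.norm(g1, axis=-1, keepdims=True)
        n2 = np.linalg.norm(g2, axis=-1, keepdims=True)
        degen = (n1[..., 0] < 1e-9) | (n2[..., 0] < 1e-9)
        valid &= ~degen
        g1 = g1 / np.where(n1 > 1e-9, n1, 1.0)
        g2 = g2 / np.where(n2 > 1e-9, n2, 1.0)
    g3 = np.cross(g1, g2)

    cavity, exterior = _find_cavity(md, axis, mask.spacing_um, mask.origin_um)
    sampling = mask.spacing_um
    d_cav = ndimage.distance_transform_edt(~cavity, sampling=sampling)
    d_ext = ndimage.distance_transform_edt(~exterior, sampling=sampling)
    wall = d_cav + d_ext
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = d_cav / wall
    depth = np.clip(np.nan_to_num(depth, nan=0.5), 0.0, 1.0)

    return LocalFrameField(
        g1=g1.astype(np.float32),
        g2=g2.astype(np.float32),
        g3=g3.astype(np.float32),
        depth=depth.astype(np.float32),
        wall_um=wall.astype(np.float32),
        valid=valid,
        focus_um=f,
        axis=axis,
        spacing_um=mask.spacing_um,
        geometry=geometry,
        cavity=cavity,
    )


def assign_segments(
    mask: MyocardialMask,
    axis: LVAxis,
    scheme: str = GRID45,
    frames: LocalFrameField | None = None,
    sector0_deg: float = 0.0,
    truncate_frac: float = 0.0,
) -> SegmentModel:
    """Label every in-mask voxel with (level, sector[, layer]).

    Levels split the long-axis span between base and apex into equal bands
    (AHA16: basal/mid/apical thirds with 6/6/4 sectors, the apical-cap segment
    is not analysed; GRID45: five levels of nine sectors). Sector 1 is centred
    on ``sector0_deg`` (anterior by convention). GRID45 voxels additionally get
    a transmural layer from depth quartiles (inner, mid-inner, mid-outer,
    outer), which requires ``frames``. ``truncate_frac`` optionally leaves the
    basal-most and apical-most fraction of the span unassigned (label 0).
    """
    if scheme not in _SCHEME_SECTORS:
        raise ValueError(f"unknown scheme {scheme!r}")
    md = mask.data
    pos = _voxel_positions(md.shape, mask.spacing_um, mask.origin_um)
    a = axis.unit_axis
    d = pos - axis.base_point_um
    ell = d @ a
    ell_in = ell[md]
    lo, hi = float(ell_in.min()), float(ell_in.max())
    span = hi - lo
    lo_t, hi_t = lo + truncate_frac * span, hi - truncate_frac * span
    n_levels = len(_SCHEME_SECTORS[scheme])
    with np.errstate(invalid="ignore"):
        level = np.floor((ell - lo_t) / max(hi_t - lo_t, 1e-12) * n_levels).astype(int) + 1
    level = np.clip(level, 0, n_levels + 1)
    level[(level == n_levels + 1) & (ell <= hi_t)] = n_levels  # voxel exactly at hi_t
    inside = md & (level >= 1) & (level <= n_levels) & (ell >= lo_t) & (ell <= hi_t)
    level_of = np.where(inside, level, 0)

    e_u, e_v = axis.transverse_basis()
    theta = np.degrees(np.arctan2(d @ e_v, d @ e_u))
    sector_of = np.zeros_like(level_of)
    for lv in range(1, n_levels + 1):
        nsec = _SCHEME_SECTORS[scheme][lv - 1]
        width = 360.0 / nsec
        rel = np.mod(theta - sector0_deg + width / 2.0, 360.0)
        sec = np.floor(rel / width).astype(int) + 1
        sel = level_of == lv
        sector_of[sel] = sec[sel]

    layer_of = None
    if scheme == GRID45:
        if frames is None:
            raise ValueError("GRID45 layers need a LocalFrameField (depth)")
        # four equal layers per segment: quartiles of the segment's depth
        # distribution, so each layer holds a quarter of the segment's voxels
        layer_of = np.zeros_like(level_of)
        for lv in range(1, n_levels + 1):
            for sec in range(1, _SCHEME_SECTORS[scheme][lv - 1] + 1):
                sel = (level_of == lv) & (sector_of == sec)
                if not sel.any():
                    continue
                depths = frames.depth[sel]
                qs = np.quantile(depths, [0.25, 0.5, 0.75])
                layer_of[sel] = 1 + np.searchsorted(qs, depths, side="left")

    model = SegmentModel(scheme, level_of, sector_of, layer_of, axis, sector0_deg)
    for seg, lv, sec in model.segment_ids():
        if not model.segment_mask(lv, sec).any():
            warnings.warn(f"segment {seg} (level {lv}, sector {sec}) is empty", stacklevel=2)
    return model


@dataclass
class WallThicknessTable:
    """Radial caliper wall thickness: nine spokes at each of five levels."""

    table: pd.DataFrame  # columns: level, spoke, thickness_um, normalized
    lv_length_um: float

    def thickness(self, level: int, spoke: int) -> float:
        row = self.table[(self.table.level == level) & (self.table.spoke == spoke)]
        return float(row.thickness_um.iloc[0]) if len(row) else float("nan")


def wall_thickness(
    mask: MyocardialMask,
    axis: LVAxis,
    n_levels: int = 5,
    n_spokes: int = 9,
    sector0_deg: float = 0.0,
    frames: LocalFrameField | None = None,
) -> WallThicknessTable:
    """Nine radial caliper spoke measurements at each of five levels.

    At the mid-plane of each level, rays are cast from the cavity centroid at
    the sector-centre angles; thickness is the distance between the endocardial
    and epicardial crossings along the ray, also reported normalised to LV
    base-to-apex length. Rays that miss the myocardium give NaN entries.
    """
    md = mask.data
    spacing = np.asarray(mask.spacing_um)
    origin = np.asarray(mask.origin_um)
    a = axis.unit_axis
    e_u, e_v = axis.transverse_basis()
    if frames is not None and frames.cavity is not None:
        cavity = frames.cavity
    else:
        cavity, _ = _find_cavity(md, axis, mask.spacing_um, mask.origin_um)

    pos = _voxel_positions(md.shape, mask.spacing_um, mask.origin_um)
    ell = (pos - axis.base_point_um) @ a
    ell_in = ell[md]
    lo, hi = float(ell_in.min()), float(ell_in.max())
    L = hi - lo
    step = float(spacing.min()) * 0.25
    max_t = float(np.linalg.norm(np.asarray(md.shape) * spacing))
    ts = np.arange(0.0, max_t, step)

    rows = []
    for level in range(1, n_levels + 1):
        mid = lo + (level - 0.5) * L / n_levels
        slab = np.abs(ell - mid) <= max(L / (2 * n_levels), spacing.min())
        cav_slab = cavity & slab
        if cav_slab.any():
            centre = (np.argwhere(cav_slab) * spacing + origin).mean(axis=0)
        else:  # thin apex: fall back to the axis point
            centre = axis.base_point_um + mid * a
        centre = centre - ((centre - axis.base_point_um) @ a - mid) * a  # keep on mid-plane
        for spoke in range(1, n_spokes + 1):
            phi = np.radians(sector0_deg + (spoke - 1) * 360.0 / n_spokes)
            u = np.cos(phi) * e_u + np.sin(phi) * e_v
            pts = centre + ts[:, None] * u
            ijk = np.round((pts - origin) / spacing).astype(int)
            ok = np.all((ijk >= 0) & (ijk < np.asarray(md.shape)), axis=1)
            hit = np.zeros(len(ts), dtype=bool)
            hit[ok] = md[ijk[ok, 0], ijk[ok, 1], ijk[ok, 2]]
            if not hit.any():
                rows.append((level, spoke, np.nan, np.nan))
                continue
            t_in = ts[hit][0]
            after = hit[ts >= t_in]
            leave = np.flatnonzero(~after)
            t_out = t_in + (leave[0] if len(leave) else len(after)) * step
            th = t_out - t_in
            rows.append((level, spoke, th, th / axis.lv_length_um))
    table = pd.DataFrame(rows, columns=["level", "spoke", "thickness_um", "normalized"])
    n_missing = int(table.thickness_um.isna().sum())
    if n_missing:
        log.warning("%d wall-thickness spokes missed the myocardium", n_missing)
    return WallThicknessTable(table, axis.lv_length_um)
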