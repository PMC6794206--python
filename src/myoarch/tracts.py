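"""Fibre tractography: RK2 streamlines through the tertiary-eigenvector field.

The fibre axis field is axial (v3 ≡ −v3), so integration carries a running
direction: at every evaluation the sampled vector is flipped to keep the angle
with the incoming direction ≤ 90°, and trilinear interpolation aligns the
eight cell-corner vectors to the incoming direction before blending. Stepping
uses the midpoint (2nd-order Runge–Kutta) rule; each seed is integrated in
both directions and the halves joined into one track.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import MyocardialMask
from .orientation import StructureTensorField

log = logging.getLogger(__name__)

__all__ = ["Track", "track_fibers", "export_tracks", "read_vtk_polylines", "grid_seeds", "integrate_streamline"]


@dataclass
class Track:
    """One streamline: ordered points in μm plus bookkeeping."""

    points: np.ndarray  # (n, 3)
    step_um: float
    seed_point: np.ndarray
    termination: str  # left_mask | max_length | low_validity

    @property
    def length_um(self) -> float:
        if len(self.points) < 2:
            return 0.0
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


class _FieldSampler:
    """Trilinear, sign-coherent sampling of an axial unit-vector field."""

    def __init__(self, vectors: np.ndarray, valid: np.ndarray, spacing_um, origin_um):
        self.vec = np.where(valid[..., None], vectors, 0.0).astype(np.float64)
        self.valid = valid
        self.spacing = np.asarray(spacing_um, dtype=float)
        self.origin = np.asarray(origin_um, dtype=float)
        self.shape = np.asarray(valid.shape)

    def __call__(self, p_um: np.ndarray, ref_dir: np.ndarray):
        """Return (unit direction aligned with ref_dir, ok flag) at p_um."""
        g = (p_um - self.origin) / self.spacing
        if np.any(g < 0) or np.any(g > self.shape - 1):
            return None, False
        i0 = np.floor(g).astype(int)
        i0 = np.minimum(i0, self.shape - 2)
        f = g - i0
        acc = np.zeros(3)
        wtot = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    w = (
                        (f[0] if dx else 1 - f[0])
                        * (f[1] if dy else 1 - f[1])
                        * (f[2] if dz else 1 - f[2])
                    )
                    if w == 0.0:
                        continue
                    ijk = (i0[0] + dx, i0[1] + dy, i0[2] + dz)
                    if not self.valid[ijk]:
                        continue
                    v = self.vec[ijk]
                    if v @ ref_dir < 0:
                        v = -v
                    acc += w * v
                    wtot += w
        if wtot < 0.5:  # mostly invalid corners
            return None, False
        n = np.linalg.norm(acc)
        if n < 1e-9:
            return None, False
        return acc / n, True

    def in_mask(self, p_um: np.ndarray, mask: np.ndarray) -> bool:
        g = np.round((p_um - self.origin) / self.spacing).astype(int)
        if np.any(g < 0) or np.any(g >= self.shape):
            return False
        return bool(mask[tuple(g)])


def integrate_streamline(sampler, mask_data, p0, d0, step_um, max_steps):
    """Midpoint (RK2) streamline integration.

    ``sampler(p, ref_dir) -> (unit_dir, ok)`` supplies the sign-aligned
    direction field and ``sampler.in_mask(p, mask_data)`` the stopping domain;
    any object with those two methods works (grid samplers, analytic fields).
    """
    pts = [p0.copy()]
    d = d0.copy()
    termination = "max_length"
    p = p0.copy()
    for _ in range(max_steps):
        d1, ok = sampler(p, d)
        if not ok:
            termination = "low_validity"
            break
        mid = p + 0.5 * step_um * d1
        d2, ok = sampler(mid, d1)
        if not ok:
            termination = "low_validity"
            break
        p_next = p + step_um * d2
        if not sampler.in_mask(p_next, mask_data):
            termination = "left_mask"
            break
        pts.append(p_next.copy())
        d = d2
        p = p_next
    return np.asarray(pts), termination


def grid_seeds(mask: MyocardialMask, every_voxels: int = 5) -> np.ndarray:
    """Regular grid of in-mask seed points (μm), one every ``every_voxels``."""
    md = mask.data
    sub = np.zeros_like(md)
    sub[::every_voxels, ::every_voxels, ::every_voxels] = True
    idx = np.argwhere(md & sub)
    return idx * np.asarray(mask.spacing_um) + np.asarray(mask.origin_um)


def track_fibers(
    orient: StructureTensorField,
    mask: MyocardialMask,
    seeds: np.ndarray,
    step_um: float | None = None,
    max_steps: int | None = None,
) -> list[Track]:
    """Integrate bidirectional RK2 streamlines through the v3 field.

    Default step is half a voxel edge; default track length cap corresponds to
    twice the volume diagonal. Tracks terminate on mask exit, on invalid
    voxels, or at the step cap.
    """
    spacing = np.asarray(mask.spacing_um)
    if step_um is None:
        step_um = 0.5 * float(spacing.min())
    if max_steps is None:
        diag = float(np.linalg.norm(np.asarray(mask.shape) * spacing))
        max_steps = int(2 * diag / step_um)
    sampler = _FieldSampler(orient.v3, orient.valid & mask.data, mask.spacing_um, mask.origin_um)
    tracks: list[Track] = []
    for seed in np.atleast_2d(np.asarray(seeds, dtype=float)):
        if not sampler.in_mask(seed, mask.data):
            raise ValueError(f"seed {seed} lies outside the mask")
        d0, ok = sampler(seed, np.array([0.0, 0.0, 1.0]))
        if not ok:
            tracks.append(Track(seed[None], step_um, seed, "low_validity"))
            continue
        fwd, term_f = integrate_streamline(sampler, mask.data, seed, d0, step_um, max_steps)
        bwd, term_b = integrate_streamline(sampler, mask.data, seed, -d0, step_um, max_steps)
        pts = np.vstack([bwd[::-1], fwd[1:]]) if len(bwd) > 1 else fwd
        tracks.append(Track(pts, step_um, seed, term_f if len(fwd) >= len(bwd) else term_b))
    log.info("traced %d tracks (step %.3g um)", len(tracks), step_um)
    return tracks


def _track_scalars(track: Track, orient, mask, color_by: str) -> np.ndarray:
    sampler = _FieldSampler(orient.v3, orient.valid & mask.data, mask.spacing_um, mask.origin_um)
    vals = np.zeros(len(track.points))
    ref = np.array([0.0, 0.0, 1.0])
    for i, p in enumerate(track.points):
        d, ok = sampler(p, ref)
        vals[i] = d[2] if ok else 0.0
    return vals


def export_tracks(
    tracks: list[Track],
    path,
    orient: StructureTensorField | None = None,
    mask: MyocardialMask | None = None,
    color_by: str = "z_component",
    scalars: list[np.ndarray] | None = None,
) -> None:
    """Write tracks as a legacy ASCII VTK polydata file with per-point scalars.

    ``color_by="z_component"`` samples the stored fibre field's z-component at
    every point (requires ``orient`` and ``mask``); alternatively pass
    precomputed per-point ``scalars`` (e.g. helical angle) directly.
    Single-point tracks are skipped with a warning.
    """
    keep, attr = [], []
    for i, t in enumerate(tracks):
        if len(t.points) < 2:
            warnings.warn(f"track {i} has a single point; skipped", stacklevel=2)
            continue
        keep.append(t)
        if scalars is not None:
            attr.append(np.asarray(scalars[i], dtype=float))
        elif color_by == "z_component" and orient is not None and mask is not None:
            attr.append(_track_scalars(t, orient, mask, color_by))
        else:
            attr.append(np.zeros(len(t.points)))
    if not keep:
        raise ValueError("no tracks with >= 2 points to export")
    n_pts = sum(len(t.points) for t in keep)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nmyoarch fibre tracks\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {n_pts} float\n")
        for t in keep:
            for p in t.points:
                fh.write(f"{p[0]:.4f} {p[1]:.4f} {p[2]:.4f}\n")
        fh.write(f"LINES {len(keep)} {len(keep) + n_pts}\n")
        offset = 0
        for t in keep:
            ids = " ".join(str(offset + k) for k in range(len(t.points)))
            fh.write(f"{len(t.points)} {ids}\n")
            offset += len(t.points)
        fh.write(f"POINT_DATA {n_pts}\nSCALARS {color_by} float 1\nLOOKUP_TABLE default\n")
        for vals in attr:
            for v in vals:
                fh.write(f"{v:.6f}\n")


def read_vtk_polylines(path):
    """Read back a legacy ASCII VTK polyline file (points, lines, scalars)."""
    with open(path) as fh:
        tokens = fh.read().split()
    i = tokens.index("POINTS")
    n = int(tokens[i + 1])
    pts = np.asarray(tokens[i + 3 : i + 3 + 3 * n], dtype=float).reshape(n, 3)
    j = tokens.index("LINES")
    n_lines = int(tokens[j + 1])
    k = j + 3
    lines = []
    for _ in range(n_lines):
        m = int(tokens[k])
        lines.append(np.asarray(tokens[k + 1 : k + 1 + m], dtype=int))
        k += m + 1
    scal = None
    if "SCALARS" in tokens:
        s = tokens.index("LOOKUP_TABLE")
        scal = np.asarray(tokens[s + 2 : s + 2 + n], dtype=float)
    return pts, lines, scal
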