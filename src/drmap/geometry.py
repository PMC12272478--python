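"""Organ-surface dose extraction: contours + 3D dose -> 91x90 dose-surface maps.

The bladder is unwrapped spherically (rays from the organ centre of mass at
2 deg polar / 4 deg azimuthal steps); the rectum cylindrically (per-slice rays
from the slice centroid, cut at the posterior wall so the anterior,
prostate-facing direction lands on the central column).  Surface dose is read
from the 3D grid by trilinear interpolation.  See :mod:`drmap.conventions`
for the axis conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import map_coordinates
from shapely.geometry import Point, Polygon

from .conventions import (
    MAP_AXES,
    N_COLS,
    N_ROWS,
    ORGANS,
    PHI_STEP_DEG,
    THETA_STEP_DEG,
    MapFailure,
)

log = logging.getLogger(__name__)

__all__ = [
    "DoseGrid",
    "OrganContours",
    "DoseSurfaceMap",
    "RawCylMap",
    "unwrap_bladder_spherical",
    "unwrap_rectum_cylindrical",
    "normalize_dsm",
    "apply_exclusion_mask",
    "polygon_radii",
]


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseGrid:
    """3D physical dose field in Gy on a regular (z, y, x) grid."""

    values: np.ndarray          # (nz, ny, nx), Gy
    spacing: tuple[float, float, float]   # (dz, dy, dx) mm
    origin: tuple[float, float, float]    # world coords of voxel (0, 0, 0), mm

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3:
            raise ValueError("dose values must be a 3D array")
        if not np.all(np.isfinite(v)):
            raise ValueError("dose values must be finite")
        if np.any(v < 0):
            raise ValueError("dose values must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacings must be positive")
        object.__setattr__(self, "values", v)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear dose at world-coordinate points (N, 3) in (z, y, x) mm.

        Points outside the grid return NaN; interpolation never extrapolates
        beyond the stored voxel values.
        """
        pts = np.asarray(points, dtype=float)
        idx = (pts - np.asarray(self.origin)) / np.asarray(self.spacing)
        out = map_coordinates(self.values, idx.T, order=1, mode="constant",
                              cval=np.nan)
        shape = np.asarray(self.values.shape)
        inside = np.all((idx >= 0) & (idx <= shape - 1), axis=1)
        out = np.where(inside, out, np.nan)
        return out


@dataclass(frozen=True)
class OrganContours:
    """Closed planar polygons per axial slice describing one organ's wall.

    ``slices`` is an ordered list of ``(z_mm, vertices)`` with vertices an
    (m, 2) array of (y, x) mm; the polygon ring is implicitly closed (the
    first vertex is not repeated).
    """

    slices: tuple[tuple[float, np.ndarray], ...]
    organ: str

    def __post_init__(self) -> None:
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}; expected one of {ORGANS}")
        if len(self.slices) < 2:
            raise ValueError("need at least 2 contour slices")
        zs = [z for z, _ in self.slices]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("slices must be strictly sorted by z")
        norm = []
        for z, verts in self.slices:
            v = np.asarray(verts, dtype=float)
            if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
                raise ValueError("each slice polygon needs >= 3 (y, x) vertices")
            norm.append((float(z), v))
        object.__setattr__(self, "slices", tuple(norm))

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([z for z, _ in self.slices])

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """(zmin, ymin, xmin), (zmax, ymax, xmax) in mm."""
        allv = np.vstack([v for _, v in self.slices])
        zs = self.z_positions
        lo = np.array([zs.min(), allv[:, 0].min(), allv[:, 1].min()])
        hi = np.array([zs.max(), allv[:, 0].max(), allv[:, 1].max()])
        return lo, hi

    def center_of_mass(self) -> np.ndarray:
        """Area-weighted centroid (z, y, x) of the enclosed volume."""
        zs = self.z_positions
        weights, cents = [], []
        for i, (z, verts) in enumerate(self.slices):
            poly = Polygon(verts[:, ::-1])  # shapely wants (x, y)
            # trapezoidal slab thickness
            lo = zs[max(i - 1, 0)]
            hi = zs[min(i + 1, len(zs) - 1)]
            w = poly.area * (hi - lo) / 2.0
            c = poly.centroid
            weights.append(w)
            cents.append((z, c.y, c.x))
        weights = np.asarray(weights)
        cents = np.asarray(cents)
        return (weights[:, None] * cents).sum(0) / weights.sum()

    def volume_cm3(self) -> float:
        """Enclosed volume by trapezoidal integration of slice areas."""
        zs = self.z_positions
        areas = np.array([Polygon(v[:, ::-1]).area for _, v in self.slices])
        return float(np.trapezoid(areas, zs) / 1000.0)


@dataclass(frozen=True)
class DoseSurfaceMap:
    """Normalized 91x90 surface-dose map with an explicit validity mask."""

    doses: np.ndarray           # (91, 90) Gy
    valid: np.ndarray           # (91, 90) bool
    organ: str
    dose_kind: str = "physical"   # "physical" | "EQD2"
    axes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        d = np.asarray(self.doses, dtype=float)
        v = np.asarray(self.valid, dtype=bool)
        if d.shape != (N_ROWS, N_COLS) or v.shape != (N_ROWS, N_COLS):
            raise ValueError(f"DSM must be exactly {N_ROWS}x{N_COLS}")
        if not np.all(np.isfinite(d[v])):
            raise ValueError("DSM doses must be finite where valid")
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")
        if self.dose_kind not in ("physical", "EQD2"):
            raise ValueError("dose_kind must be 'physical' or 'EQD2'")
        object.__setattr__(self, "doses", d)
        object.__setattr__(self, "valid", v)
        if not self.axes:
            object.__setattr__(self, "axes", dict(MAP_AXES[self.organ]))

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass(frozen=True)
class RawCylMap:
    """Cylindrical unwrap before row normalization: one row per axial slice."""

    doses: np.ndarray        # (n_slices, n_phi)
    valid: np.ndarray        # (n_slices, n_phi) bool
    z_positions: np.ndarray  # (n_slices,) mm, inferior -> superior


# --------------------------------------------------------------------------
# polygon ray casting
# --------------------------------------------------------------------------

def polygon_radii(vertices: np.ndarray, center: np.ndarray,
                  angles: np.ndarray) -> np.ndarray:
    """Distance from ``center`` to the first polygon-boundary crossing along
    each ray.

    Angles are measured from +y (anterior) toward +x (patient left); vertices
    are (m, 2) in (y, x).  Rays with no crossing (centre outside the polygon
    or degenerate geometry) return NaN.
    """
    v = np.asarray(vertices, dtype=float)
    c = np.asarray(center, dtype=float)
    a = np.asarray(angles, dtype=float)
    d = np.stack([np.cos(a), np.sin(a)], axis=-1)          # (A, 2) (dy, dx)
    e = np.roll(v, -1, axis=0) - v                          # (m, 2) edges
    w = v - c                                               # (m, 2)

    def cross(u, t):
        return u[..., 0] * t[..., 1] - u[..., 1] * t[..., 0]

    denom = cross(d[:, None, :], e[None, :, :])             # (A, m)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = cross(w[None, :, :], e[None, :, :]) / denom
        s = cross(w[None, :, :], d[:, None, :]) / denom
    # s-range padded slightly: a ray through a vertex can land just outside
    # [0, 1) on both adjacent edges; taking min-t makes double hits harmless
    ok = (np.abs(denom) > 1e-12) & (s >= -1e-9) & (s <= 1.0 + 1e-9) & (t > 1e-9)
    t = np.where(ok, t, np.inf)
    r = t.min(axis=1)
    return np.where(np.isfinite(r), r, np.nan)


def _radial_table(contours: OrganContours, axis_yx: np.ndarray,
                  n_angles: int = 720) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice boundary radius about a common vertical axis.

    Returns (angles, table) with table shape (n_slices, n_angles); NaN where
    a slice is not star-shaped about the axis point.
    """
    angles = -np.pi + 2 * np.pi * np.arange(n_angles) / n_angles
    table = np.empty((len(contours.slices), n_angles))
    for i, (_, verts) in enumerate(contours.slices):
        table[i] = polygon_radii(verts, axis_yx, angles)
    return angles, table


def _interp_radius(table: np.ndarray, angles_query: np.ndarray,
                   slice_idx: np.ndarray, frac: np.ndarray) -> np.ndarray:
    """Bilinear lookup of the radial table in (slice, angle), periodic in angle."""
    n_angles = table.shape[1]
    pos = (angles_query + np.pi) / (2 * np.pi) * n_angles
    i0 = np.floor(pos).astype(int) % n_angles
    i1 = (i0 + 1) % n_angles
    fa = pos - np.floor(pos)
    r_lo = (1 - fa) * table[slice_idx, i0] + fa * table[slice_idx, i1]
    r_hi = (1 - fa) * table[slice_idx + 1, i0] + fa * table[slice_idx + 1, i1]
    return (1 - frac) * r_lo + frac * r_hi


# --------------------------------------------------------------------------
# spherical unwrap (bladder)
# --------------------------------------------------------------------------

def unwrap_bladder_spherical(contours: OrganContours, dose: DoseGrid,
                             theta_step_deg: float = THETA_STEP_DEG,
                             phi_step_deg: float = PHI_STEP_DEG,
                             tol_mm: float = 0.01) -> DoseSurfaceMap:
    """Spherically unwrap a bladder surface onto the 91x90 dose lattice.

    Rays are cast from the organ centre of mass at polar angles theta in
    [0, 180] deg (inclusive, rows; theta=0 is the superior pole) and azimuths
    phi in [0, 360) deg (half-open, columns).  The surface crossing along each
    ray is located by bisection against a point-in-organ predicate built from
    the slice polygons (radii interpolated linearly between slices), then the
    dose there is sampled trilinearly.

    Rays that fail to cross the surface (non-star-shaped contour) are marked
    invalid and counted in a log warning; a centre of mass outside the organ
    raises :class:`MapFailure`.
    """
    n_rows = int(round(180.0 / theta_step_deg)) + 1
    n_cols = int(round(360.0 / phi_step_deg))

    com = contours.center_of_mass()
    zs = contours.z_positions
    _, table = _radial_table(contours, com[1:])

    def inside(pts: np.ndarray) -> np.ndarray:
        z = pts[:, 0]
        ok = (z >= zs[0]) & (z <= zs[-1])
        iz = np.clip(np.searchsorted(zs, z, side="right") - 1, 0, len(zs) - 2)
        frac = np.clip((z - zs[iz]) / (zs[iz + 1] - zs[iz]), 0.0, 1.0)
        dy = pts[:, 1] - com[1]
        dx = pts[:, 2] - com[2]
        ang = np.arctan2(dx, dy)
        r = _interp_radius(table, ang, iz, frac)
        horiz = np.hypot(dy, dx)
        with np.errstate(invalid="ignore"):
            res = ok & np.isfinite(r) & (horiz <= r)
        return res

    # exact point-in-polygon check on the slice nearest the centre of mass
    # (the radial predicate assumes star shape and cannot be trusted here)
    nearest = int(np.argmin(np.abs(zs - com[0])))
    poly = Polygon(contours.slices[nearest][1][:, ::-1])
    if not poly.contains(Point(com[2], com[1])):
        raise MapFailure("organ centre of mass lies outside the organ")

    theta = np.deg2rad(np.arange(n_rows) * theta_step_deg)
    phi = np.deg2rad(np.arange(n_cols) * phi_step_deg)
    tt, pp = np.meshgrid(theta, phi, indexing="ij")
    dirs = np.stack([np.cos(tt), np.sin(tt) * np.cos(pp),
                     np.sin(tt) * np.sin(pp)], axis=-1).reshape(-1, 3)

    lo, hi = contours.bounding_box()
    t_max = float(np.linalg.norm(hi - lo)) + 1.0
    t_lo = np.zeros(len(dirs))
    t_hi = np.full(len(dirs), t_max)
    valid = ~inside(com[None, :] + t_hi[:, None] * dirs)
    n_iter = int(np.ceil(np.log2(t_max / tol_mm))) + 1
    for _ in range(n_iter):
        mid = 0.5 * (t_lo + t_hi)
        ins = inside(com[None, :] + mid[:, None] * dirs)
        t_lo = np.where(ins, mid, t_lo)
        t_hi = np.where(ins, t_hi, mid)
    radius = 0.5 * (t_lo + t_hi)

    surf = com[None, :] + radius[:, None] * dirs
    doses = dose.sample(surf)
    # a ray that never entered the organ collapses to the centre; reject it
    valid &= radius > 10 * tol_mm
    valid &= np.isfinite(doses)
    n_bad = int((~valid).sum())
    if n_bad:
        log.warning("spherical unwrap: %d/%d rays marked invalid", n_bad, len(dirs))
    doses = np.where(valid, doses, np.nan)

    dsm_doses = doses.reshape(n_rows, n_cols)
    dsm_valid = valid.reshape(n_rows, n_cols)
    if (n_rows, n_cols) != (N_ROWS, N_COLS):
        return normalize_dsm(dsm_doses, valid=dsm_valid, organ="bladder")
    return DoseSurfaceMap(dsm_doses, dsm_valid, organ="bladder")


# --------------------------------------------------------------------------
# cylindrical unwrap (rectum)
# --------------------------------------------------------------------------

def unwrap_rectum_cylindrical(contours: OrganContours, dose: DoseGrid,
                              n_phi: int = N_COLS) -> RawCylMap:
    """Cylindrically unwrap a rectum surface, one map row per axial slice.

    Per slice, ``n_phi`` rays are cast in-plane from the slice centroid.  The
    map is cut at the posterior wall: column ``j`` carries the angle
    ``-180 deg + j * (360/n_phi) deg`` measured from anterior toward the
    patient's left, so the central column faces anterior (the high-dose,
    prostate-facing wall).  Slices whose centroid falls outside their polygon
    (crescent shapes) are filled by linear interpolation between the adjacent
    valid slices where possible, otherwise marked invalid.

    Rows are ordered inferior -> superior; pass the result to
    :func:`normalize_dsm` to obtain the 91x90 map.
    """
    if len(contours.slices) < 2:
        raise ValueError("need at least 2 slices")
    angles = -np.pi + 2 * np.pi * np.arange(n_phi) / n_phi  # from anterior, cut posterior
    zs = contours.z_positions
    n = len(zs)
    doses = np.full((n, n_phi), np.nan)
    row_ok = np.zeros(n, dtype=bool)

    for i, (z, verts) in enumerate(contours.slices):
        poly = Polygon(verts[:, ::-1])
        c = poly.centroid
        centroid = np.array([c.y, c.x])
        if not poly.contains(Point(c.x, c.y)):
            continue  # crescent slice; fill later
        r = polygon_radii(verts, centroid, angles)
        if np.any(~np.isfinite(r)):
            continue
        pts = np.column_stack([
            np.full(n_phi, z),
            centroid[0] + r * np.cos(angles),
            centroid[1] + r * np.sin(angles),
        ])
        row = dose.sample(pts)
        if np.all(np.isfinite(row)):
            doses[i] = row
            row_ok[i] = True

    valid = np.zeros((n, n_phi), dtype=bool)
    valid[row_ok] = True
    bad = np.flatnonzero(~row_ok)
    good = np.flatnonzero(row_ok)
    if len(good) >= 2:
        for i in bad:
            below = good[good < i]
            above = good[good > i]
            if len(below) and len(above):
                a, b = below[-1], above[0]
                w = (zs[i] - zs[a]) / (zs[b] - zs[a])
                doses[i] = (1 - w) * doses[a] + w * doses[b]
                valid[i] = True
    if len(bad):
        log.warning("cylindrical unwrap: %d/%d slices had unwrapping artifacts "
                    "(interpolated where flanked by valid slices)", len(bad), n)
    return RawCylMap(doses=doses, valid=valid, z_positions=zs)


# --------------------------------------------------------------------------
# spatial normalization & masking
# --------------------------------------------------------------------------

def normalize_dsm(raw, valid: np.ndarray | None = None, *,
                  organ: str = "rectum", dose_kind: str = "physical",
                  target_rows: int = N_ROWS,
                  target_cols: int = N_COLS) -> DoseSurfaceMap:
    """Bilinearly resample a raw map onto the normalized 91x90 lattice.

    The validity mask is resampled conservatively: an output voxel is valid
    only if every contributing input voxel is valid.
    """
    if isinstance(raw, RawCylMap):
        valid = raw.valid
        raw = raw.doses
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] < 2 or raw.shape[1] < 2:
        raise ValueError("raw map must be at least 2x2")
    if valid is None:
        valid = np.isfinite(raw)
    valid = np.asarray(valid, dtype=bool)
    if valid.shape != raw.shape:
        raise ValueError("validity mask shape mismatch")

    rows = np.linspace(0, raw.shape[0] - 1, target_rows)
    cols = np.linspace(0, raw.shape[1] - 1, target_cols)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()])
    filled = np.where(valid, raw, 0.0)
    out = map_coordinates(filled, coords, order=1, mode="nearest")
    vout = map_coordinates(valid.astype(float), coords, order=1, mode="nearest")
    out = out.reshape(target_rows, target_cols)
    new_valid = (vout >= 1.0 - 1e-9).reshape(target_rows, target_cols)
    out = np.where(new_valid, out, np.nan)
    return DoseSurfaceMap(out, new_valid, organ=organ, dose_kind=dose_kind)


def apply_exclusion_mask(dsm: DoseSurfaceMap, mask: np.ndarray) -> DoseSurfaceMap:
    """Mark voxels under ``mask`` invalid (dose values untouched).

    Used for visually identified unwrapping artifacts such as the bladder
    trigone region; the mask is an input, never auto-detected.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != dsm.valid.shape:
        raise ValueError("exclusion mask shape mismatch")
    return replace(dsm, valid=dsm.valid & ~mask)
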