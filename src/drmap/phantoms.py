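"""Analytic validation phantoms: closed-form geometries and dose fields whose
unwrapped surface maps are known exactly.

Used by the test suite as independent oracles for the unwrapping code: a
sphere of radius R in a radial field f(r) must map to the constant f(R); a
straight circular tube in a uniform field to a constant map; a tube in a
field linear in the anterior coordinate to rows peaking at the central
(anterior-facing) column.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .geometry import DoseGrid, OrganContours

__all__ = ["sphere_contours", "tube_contours", "field_grid"]


def sphere_contours(radius: float, center=(0.0, 0.0, 0.0),
                    n_theta: int = 180, n_vertices: int = 90) -> OrganContours:
    """Sphere sampled with slices dense near the poles (z_k = R cos(theta_k)),
    so the polygonal surface tracks the true sphere to high accuracy."""
    cz, cy, cx = center
    thetas = np.linspace(0, np.pi, n_theta + 1)[1:-1]
    phi = 2 * np.pi * np.arange(n_vertices) / n_vertices
    slices = []
    for th in thetas[::-1]:  # increasing z
        z = radius * np.cos(th)
        r = radius * np.sin(th)
        verts = np.column_stack([cy + r * np.cos(phi), cx + r * np.sin(phi)])
        slices.append((cz + z, verts))
    return OrganContours(slices=tuple(slices), organ="bladder")


def tube_contours(radius: float, length: float, center=(0.0, 0.0, 0.0),
                  n_slices: int = 30, n_vertices: int = 90,
                  crescent_slices: tuple[int, ...] = ()) -> OrganContours:
    """Straight circular tube along z.  Slices listed in ``crescent_slices``
    are replaced by crescent polygons whose centroid falls outside the
    contour, to exercise the adjacent-slice interpolation path."""
    cz, cy, cx = center
    phi = 2 * np.pi * np.arange(n_vertices) / n_vertices
    zs = np.linspace(-length / 2, length / 2, n_slices)
    slices = []
    for i, z in enumerate(zs):
        if i in crescent_slices:
            # thin crescent: outer arc of the circle plus a close inner arc
            arc = np.linspace(-0.75 * np.pi, 0.75 * np.pi, n_vertices // 2)
            outer = np.column_stack([cy + radius * np.cos(arc),
                                     cx + radius * np.sin(arc)])
            inner = np.column_stack([cy + 0.85 * radius * np.cos(arc[::-1]),
                                     cx + 0.85 * radius * np.sin(arc[::-1])])
            verts = np.vstack([outer, inner])
        else:
            verts = np.column_stack([cy + radius * np.cos(phi),
                                     cx + radius * np.sin(phi)])
        slices.append((cz + z, verts))
    return OrganContours(slices=tuple(slices), organ="rectum")


def field_grid(fn: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
               lo=(-60, -60, -60), hi=(60, 60, 60),
               spacing=(1.0, 1.0, 1.0)) -> DoseGrid:
    """Sample an analytic dose field fn(z, y, x) (mm -> Gy) onto a grid."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    shape = np.floor((hi - lo) / spacing).astype(int) + 1
    zz = lo[0] + spacing[0] * np.arange(shape[0])
    yy = lo[1] + spacing[1] * np.arange(shape[1])
    xx = lo[2] + spacing[2] * np.arange(shape[2])
    Z, Y, X = np.meshgrid(zz, yy, xx, indexing="ij")
    return DoseGrid(values=fn(Z, Y, X), spacing=tuple(spacing), origin=tuple(lo))
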