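"""Anatomical coordinate and map-axis conventions used throughout the package.

All 3D arrays are indexed (z, y, x):

* ``z`` increases toward the patient's **superior** (head),
* ``y`` increases toward the patient's **anterior**,
* ``x`` increases toward the patient's **left**.

Dose-surface maps (DSMs) are 91 x 90 matrices:

* **Bladder (spherical unwrap).** Rows index the polar angle theta sampled
  0..180 deg in 2 deg steps (91 rows); row 0 is the superior pole, row 90 the
  inferior pole.  Columns index the azimuth phi sampled on the half-open
  interval [0, 360) deg in 4 deg steps (90 columns, no duplicated seam);
  phi = 0 points anterior and increases toward the patient's left, so
  column 0 = anterior, column 22 ~ left, column 45 = posterior,
  column 67 ~ right.
* **Rectum (cylindrical unwrap).** Rows index axial slices ordered
  inferior -> superior (resampled to 91 rows).  Columns index the in-plane
  angle measured from the anterior direction, cut at the posterior wall:
  column 0 starts just past the posterior incision, the central column 45
  faces anterior (toward the prostate / high-dose region), and the angle
  increases toward the patient's left.

These constants are the single source of truth for plot axis labels and for
the synthetic-cohort generator's placement of the planted subregion.
"""

from __future__ import annotations

#: DSM lattice fixed by the 2-degree theta / 4-degree phi sampling.
N_ROWS = 91
N_COLS = 90
N_VOXELS = N_ROWS * N_COLS  # 8190

THETA_STEP_DEG = 2.0
PHI_STEP_DEG = 4.0

#: Column whose azimuth faces anterior / posterior under the conventions above.
BLADDER_ANTERIOR_COL = 0
BLADDER_POSTERIOR_COL = 45
RECTUM_ANTERIOR_COL = 45

#: Axis annotations used by the plotting helpers (edge labels follow the
#: figure conventions: L/R/S/I for bladder maps, P/A for rectum maps).
MAP_AXES = {
    "bladder": {
        "rows": "theta 0-180 deg (S superior pole -> I inferior pole)",
        "cols": "phi 0-360 deg (A anterior -> L left -> P posterior -> R right)",
        "top": "S",
        "bottom": "I",
        "left": "A",
        "right": "A",
        "center_col_label": "P",
    },
    "rectum": {
        "rows": "axial slices (I inferior -> S superior)",
        "cols": "angle from posterior cut (P -> L -> A -> R -> P)",
        "top": "S",
        "bottom": "I",
        "left": "P",
        "right": "P",
        "center_col_label": "A",
    },
}

ORGANS = ("bladder", "rectum")


class DrmapError(Exception):
    """Base class for package errors."""


class MapFailure(DrmapError):
    """Whole-map unwrapping failure (e.g. centre of mass outside the organ)."""


class MissingDataError(DrmapError):
    """A toxicity record lacks the grades a dichotomization method requires."""


class DegenerateGroupsError(DrmapError):
    """A statistical routine was handed a group too small to analyse."""
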