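"""Synthetic cohorts with a known, planted dose-toxicity structure.

Because the underlying trial data are not distributable, every downstream
stage is exercised on cohorts generated here.  Two paths are provided:

* the **full geometric path** — per-patient organ contours (star-shaped
  ellipsoidal bladder or curved tubular rectum), a smooth 3D dose field with
  a plateau over a prostate-like target placed infero-posterior to the
  bladder / anterior to the rectum, and toxicity grades drawn from a
  logistic link on the mean EQD2 dose inside a planted surface subregion;
* the **surface-map path** (:func:`simulate_dsm_cohort`,
  :func:`simulate_null_cohort`) — dose-surface maps drawn directly on the
  map lattice with the same logistic link, used for statistical calibration
  studies where thousands of unwrapping runs would be wasteful.

Cohort-level defaults follow the treatment summary the package emulates:
prescription 71.4 Gy in 34 fractions, bladder volumes ~162.9 +/- 123.8 cm^3,
rectum volume ~68.4 +/- 23.5 cm^3 and length ~9.7 +/- 1.3 cm.

Reproducibility: each patient consumes independent pseudo-random streams
derived from ``(seed, patient_index, stream)``, so cohorts are bit-identical
regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.special import expit, logit

from .conventions import N_COLS, N_ROWS, ORGANS
from .eqd2 import FractionationContext, eqd2_dsm
from .geometry import (
    DoseGrid,
    DoseSurfaceMap,
    OrganContours,
    normalize_dsm,
    unwrap_bladder_spherical,
    unwrap_rectum_cylindrical,
)
from .toxicity import ToxicityRecord

__all__ = [
    "CohortSpec",
    "SyntheticPatient",
    "generate_organ_geometry",
    "generate_dose",
    "generate_toxicity",
    "generate_cohort",
    "bladder_dsm_template",
    "simulate_dsm_cohort",
    "simulate_null_cohort",
    "default_planted_region",
]

# population parameters the generator emulates
_BLADDER_VOL_MEAN_CM3 = 162.9
_BLADDER_VOL_SD_CM3 = 123.8
_RECTUM_VOL_MEAN_CM3 = 68.4
_RECTUM_VOL_SD_CM3 = 23.5
_RECTUM_LEN_MEAN_MM = 97.0
_RECTUM_LEN_SD_MM = 13.0

_DEFAULT_ENDPOINTS = (
    "urinary_tract_obstruction",
    "urinary_retention",
    "urinary_urgency",
    "urinary_incontinence",
)


def default_planted_region(shape: tuple[int, int] = (N_ROWS, N_COLS)) -> tuple:
    """Default planted subregion: a block on the posterior-inferior surface
    (around theta ~ 116-160 deg, phi ~ posterior), scaled to ``shape``."""
    r0, r1 = int(0.62 * shape[0]), int(0.86 * shape[0])
    c0, c1 = int(0.38 * shape[1]), int(0.62 * shape[1])
    return tuple((r, c) for r in range(r0, r1) for c in range(c0, c1))


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to generate one reproducible synthetic cohort."""

    n_patients: int = 400
    prescription_dose: float = 71.4        # Gy
    n_fractions: int = 34
    organ: str = "bladder"
    planted_region: tuple = ()             # ((row, col), ...) on the map grid
    effect_size: float = 0.25              # log-odds per Gy of planted-region mean dose
    base_event_rate: float = 0.40          # event probability at the reference dose
    baseline_prevalence: float = 0.10      # P(baseline grade >= 1)
    baseline_boost: float = 0.5            # log-odds added per baseline grade
    grade_noise: float = 0.35              # escalation prob per extra severity step
    reference_dose: float | None = None    # centre of the logistic dose term
    endpoints: tuple = _DEFAULT_ENDPOINTS
    seed: int = 0
    # geometry / dose-field knobs
    slice_thickness_mm: float = 2.5
    grid_spacing: tuple[float, float, float] = (2.5, 2.0, 2.0)  # (dz, dy, dx)
    target_radius_mm: float = 24.0
    dose_falloff_mm: float = 6.0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.prescription_dose <= 0:
            raise ValueError("prescription_dose must be positive")
        if self.n_fractions < 1:
            raise ValueError("n_fractions must be >= 1")
        if self.organ not in ORGANS:
            raise ValueError(f"unknown organ {self.organ!r}")
        if not 0.0 <= self.baseline_prevalence <= 1.0:
            raise ValueError("baseline_prevalence must be in [0, 1]")
        if not 0.0 < self.base_event_rate < 1.0:
            raise ValueError("base_event_rate must be in (0, 1)")
        region = tuple(tuple(int(v) for v in rc) for rc in self.planted_region) \
            or default_planted_region()
        if not region:
            raise ValueError("planted_region must be non-empty")
        for r, c in region:
            if not (0 <= r < N_ROWS and 0 <= c < N_COLS):
                raise ValueError(f"planted voxel ({r}, {c}) outside the map grid")
        object.__setattr__(self, "planted_region", region)

    def planted_mask(self, shape: tuple[int, int] = (N_ROWS, N_COLS)) -> np.ndarray:
        mask = np.zeros(shape, dtype=bool)
        if shape == (N_ROWS, N_COLS):
            rows, cols = zip(*self.planted_region)
            mask[list(rows), list(cols)] = True
        else:
            for r, c in default_planted_region(shape):
                mask[r, c] = True
        return mask


@dataclass(frozen=True)
class SyntheticPatient:
    contours: OrganContours
    dose: DoseGrid
    n_fractions: int
    toxicity: tuple[ToxicityRecord, ...]
    truth_event_probability: float         # for the first simulated endpoint
    dsm: DoseSurfaceMap | None = None      # EQD2 map used to draw toxicity


def _rng(spec: CohortSpec, patient_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed,
                               spawn_key=(patient_index, stream)))


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------

def _slice_positions(half_extent: float, dz: float) -> np.ndarray:
    """Odd number of slice midpoints covering (-half_extent, half_extent),
    guaranteeing an equatorial slice at z = 0."""
    n = max(3, int(round(2 * half_extent / dz)))
    if n % 2 == 0:
        n += 1
    h = 2 * half_extent / n
    return -half_extent + (np.arange(n) + 0.5) * h


def _bladder_contours(rng: np.random.Generator, dz: float,
                      fixed_volume_cm3: float | None,
                      anisotropy: float, perturbation: float,
                      n_vertices: int) -> OrganContours:
    if fixed_volume_cm3 is None:
        sigma2 = np.log1p((_BLADDER_VOL_SD_CM3 / _BLADDER_VOL_MEAN_CM3) ** 2)
        mu = np.log(_BLADDER_VOL_MEAN_CM3) - sigma2 / 2.0
        vol = float(np.clip(rng.lognormal(mu, np.sqrt(sigma2)), 20.0, 800.0))
    else:
        vol = fixed_volume_cm3
    r0 = (3.0 * vol * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)  # mm
    l1, l2 = rng.normal(0.0, anisotropy, size=2)
    az, ay, ax = r0 * np.exp([l1, l2, -l1 - l2])
    center = rng.normal(0.0, 3.0, size=3) if anisotropy > 0 else np.zeros(3)

    phi = 2 * np.pi * np.arange(n_vertices) / n_vertices
    pert = np.ones(n_vertices)
    for m in (2, 3, 4):
        eps = rng.uniform(0.0, perturbation) / m
        pert += eps * np.cos(m * phi + rng.uniform(0, 2 * np.pi))

    slices = []
    for z in _slice_positions(az, dz):
        s = np.sqrt(max(1.0 - (z / az) ** 2, 0.0))
        y = center[1] + ay * s * np.cos(phi) * pert
        x = center[2] + ax * s * np.sin(phi) * pert
        slices.append((center[0] + z, np.column_stack([y, x])))
    return OrganContours(slices=tuple(slices), organ="bladder")


def _rectum_contours(rng: np.random.Generator, dz: float,
                     perturbation: float, n_vertices: int) -> OrganContours:
    length = float(np.clip(rng.normal(_RECTUM_LEN_MEAN_MM, _RECTUM_LEN_SD_MM),
                           60.0, 140.0))
    vol = float(np.clip(rng.normal(_RECTUM_VOL_MEAN_CM3, _RECTUM_VOL_SD_CM3),
                        25.0, 140.0))
    r0 = np.sqrt(vol * 1000.0 / (np.pi * length))   # mm
    bow = float(np.clip(rng.normal(6.0, 2.0), 0.0, 12.0))
    taper_phase = rng.uniform(0, 2 * np.pi)

    phi = 2 * np.pi * np.arange(n_vertices) / n_vertices
    pert = 1.0 + rng.uniform(0.0, perturbation) * np.cos(2 * phi + rng.uniform(0, 2 * np.pi))

    slices = []
    for z in _slice_positions(length / 2.0, dz):
        u = (z + length / 2.0) / length               # 0 at inferior end
        yc = -25.0 + bow * np.sin(np.pi * u)          # anterior bowing
        r = r0 * (1.0 + 0.1 * np.sin(2 * np.pi * u + taper_phase))
        y = yc + r * np.cos(phi) * pert
        x = r * np.sin(phi) * pert
        slices.append((z, np.column_stack([y, x])))
    return OrganContours(slices=tuple(slices), organ="rectum")


def generate_organ_geometry(spec: CohortSpec, patient_index: int, *,
                            fixed_volume_cm3: float | None = None,
                            anisotropy: float = 0.12,
                            perturbation: float = 0.04,
                            n_vertices: int = 48) -> OrganContours:
    """Generate one patient's organ contours.

    Bladders are star-shaped ellipsoids with semi-axes drawn so enclosed
    volumes follow the target log-normal distribution (mean 162.9 cm^3);
    rectums are gently curved near-circular tubes (~9.7 cm long, ~68 cm^3).
    Passing ``fixed_volume_cm3`` with ``anisotropy=0, perturbation=0`` yields
    an exact sphere (useful for validation phantoms).  Deterministic in
    ``(spec.seed, patient_index)``.
    """
    rng = _rng(spec, patient_index, 0)
    if spec.organ == "bladder":
        return _bladder_contours(rng, spec.slice_thickness_mm, fixed_volume_cm3,
                                 anisotropy, perturbation, n_vertices)
    return _rectum_contours(rng, spec.slice_thickness_mm, perturbation, n_vertices)


# --------------------------------------------------------------------------
# dose field
# --------------------------------------------------------------------------

def generate_dose(spec: CohortSpec, contours: OrganContours) -> DoseGrid:
    """Smooth 3D dose field: a plateau ~ prescription dose over a
    prostate-like spherical target with sigmoidal radial falloff.

    The target sits infero-posterior to a bladder / anterior to a rectum, so
    the high-dose region abuts the organ surface facing it.  The grid covers
    the contour bounding box with a 30 mm margin.  With
    ``spec.dose_falloff_mm == 0`` the field degenerates to
    prescription x indicator(target).
    """
    lo, hi = contours.bounding_box()
    com = contours.center_of_mass()
    if spec.organ == "bladder":
        target = np.array([lo[0] - 12.0, com[1] - 18.0, com[2]])
    else:
        target = np.array([com[0], hi[1] + 15.0, com[2]])

    margin = 30.0
    origin = lo - margin
    extent = hi + margin - origin
    spacing = np.asarray(spec.grid_spacing)
    shape = np.ceil(extent / spacing).astype(int) + 1
    zz = origin[0] + spacing[0] * np.arange(shape[0])
    yy = origin[1] + spacing[1] * np.arange(shape[1])
    xx = origin[2] + spacing[2] * np.arange(shape[2])
    d = np.sqrt((zz[:, None, None] - target[0]) ** 2
                + (yy[None, :, None] - target[1]) ** 2
                + (xx[None, None, :] - target[2]) ** 2)
    if spec.dose_falloff_mm == 0:
        values = spec.prescription_dose * (d <= spec.target_radius_mm)
    else:
        values = spec.prescription_dose * expit(
            (spec.target_radius_mm - d) / spec.dose_falloff_mm)
    return DoseGrid(values=values, spacing=tuple(spacing), origin=tuple(origin))


# --------------------------------------------------------------------------
# toxicity
# --------------------------------------------------------------------------

def generate_toxicity(spec: CohortSpec, dsm, patient_index: int = 0,
                      endpoint: str | None = None,
                      reference_dose: float | None = None,
                      ) -> tuple[ToxicityRecord, float]:
    """Draw one (record, event_probability) pair from the planted logistic link.

    The baseline grade is Bernoulli(``baseline_prevalence``) mapped to grade
    1.  The follow-up event probability is

        p = expit( logit(base_event_rate)
                   + effect_size * (mean planted-region dose - reference)
                   + baseline_boost * baseline_grade )

    and the maximum follow-up grade is >= 1 iff the event fires; higher
    grades come from thresholding a latent severity (1 + Binomial(2,
    grade_noise)).  ``reference`` defaults to ``spec.reference_dose`` or the
    prescription dose; cohort generators pass the cohort-mean planted dose so
    ``base_event_rate`` is attained on average.
    """
    if isinstance(dsm, DoseSurfaceMap):
        values, valid = dsm.doses, dsm.valid
    else:
        values = np.asarray(dsm, dtype=float)
        valid = np.isfinite(values)
    mask = spec.planted_mask(values.shape)
    if mask.shape != values.shape:
        raise ValueError("DSM shape does not match the planted-region grid")
    sel = mask & valid
    if not sel.any():
        raise ValueError("planted region contains no valid voxels")
    mean_dose = float(values[sel].mean())

    endpoint = endpoint or spec.endpoints[0]
    ep_idx = spec.endpoints.index(endpoint) if endpoint in spec.endpoints else 0
    rng = _rng(spec, patient_index, 1000 + ep_idx)

    g0 = 1 if rng.random() < spec.baseline_prevalence else 0
    ref = reference_dose if reference_dose is not None else (
        spec.reference_dose if spec.reference_dose is not None
        else spec.prescription_dose)
    lp = (logit(spec.base_event_rate)
          + spec.effect_size * (mean_dose - ref)
          + spec.baseline_boost * g0)
    p = float(expit(lp))
    event = rng.random() < p
    if event:
        severity = 1 + int(rng.binomial(2, spec.grade_noise))
        pattern = rng.choice(3, p=[0.3, 0.2, 0.5])  # 12m only / 24m only / both
        g12 = severity if pattern in (0, 2) else 0
        g24 = severity if pattern in (1, 2) else 0
    else:
        g12 = g24 = 0
    rec = ToxicityRecord(endpoint=endpoint, grade_baseline=g0, grade_12m=g12,
                         grade_24m=g24, patient_id=patient_index)
    return rec, p


# --------------------------------------------------------------------------
# full cohort (geometric path)
# --------------------------------------------------------------------------

def generate_cohort(spec: CohortSpec, alpha_beta: float = 1.0,
                    ) -> list[SyntheticPatient]:
    """Generate a full cohort: contours -> dose -> unwrap -> EQD2 -> toxicity.

    Toxicity is drawn from each patient's *normalized EQD2* surface map, with
    the logistic dose term centred on the cohort-mean planted-region dose
    (two passes), so the marginal event rate matches ``base_event_rate`` when
    ``effect_size * (dose - mean)`` averages out.
    """
    ctx = FractionationContext(n_fractions=spec.n_fractions, alpha_beta=alpha_beta)
    patients_geom = []
    for i in range(spec.n_patients):
        contours = generate_organ_geometry(spec, i)
        dose = generate_dose(spec, contours)
        if spec.organ == "bladder":
            dsm = unwrap_bladder_spherical(contours, dose)
        else:
            dsm = normalize_dsm(unwrap_rectum_cylindrical(contours, dose),
                                organ="rectum")
        dsm = eqd2_dsm(dsm, ctx)
        patients_geom.append((contours, dose, dsm))

    mask = spec.planted_mask()
    means = [float(d.doses[mask & d.valid].mean()) for _, _, d in patients_geom]
    reference = float(np.mean(means))

    cohort = []
    for i, (contours, dose, dsm) in enumerate(patients_geom):
        records, p_first = [], None
        for ep in spec.endpoints:
            rec, p = generate_toxicity(spec, dsm, i, endpoint=ep,
                                       reference_dose=reference)
            records.append(rec)
            if p_first is None:
                p_first = p
        cohort.append(SyntheticPatient(
            contours=contours, dose=dose, n_fractions=spec.n_fractions,
            toxicity=tuple(records), truth_event_probability=p_first,
            dsm=dsm))
    return cohort


# --------------------------------------------------------------------------
# surface-map path (calibration studies)
# --------------------------------------------------------------------------

def bladder_dsm_template(shape: tuple[int, int] = (N_ROWS, N_COLS),
                         low: float = 18.0, high: float = 69.0) -> np.ndarray:
    """Population-mean EQD2 surface-map template: a smooth high-dose bump on
    the posterior-inferior surface (where the target abuts the organ) over a
    ~18 Gy background, spanning the 18-69 Gy range typical of bladder maps."""
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    r0, c0 = 0.74 * (shape[0] - 1), 0.50 * (shape[1] - 1)
    sr, sc = 0.14 * shape[0], 0.18 * shape[1]
    dc = np.minimum(np.abs(cols - c0), shape[1] - np.abs(cols - c0))  # periodic phi
    bump = np.exp(-0.5 * ((rows - r0) / sr) ** 2 - 0.5 * (dc / sc) ** 2)
    return low + (high - low) * bump


def simulate_dsm_cohort(spec: CohortSpec, shape: tuple[int, int] = (N_ROWS, N_COLS),
                        dose_scale_sd: float = 0.06, noise_sd: float = 2.0,
                        noise_smooth: float = 3.0,
                        ) -> tuple[np.ndarray, list[ToxicityRecord], np.ndarray]:
    """Cohort of surface maps drawn directly on the map lattice.

    Per patient ``i``: map = template * s_i + smooth noise, with a per-patient
    global dose scale s_i ~ N(1, dose_scale_sd) (plan-to-plan variation) and
    spatially correlated Gaussian noise (sd ``noise_sd`` Gy, correlation
    length ``noise_smooth`` voxels).  Toxicity for the first endpoint is then
    drawn through the same planted logistic link as the geometric path.

    Returns (maps, records, event_probabilities).
    """
    template = bladder_dsm_template(shape)
    maps = np.empty((spec.n_patients,) + shape)
    for i in range(spec.n_patients):
        rng = _rng(spec, i, 2)
        s = 1.0 + dose_scale_sd * rng.standard_normal()
        noise = gaussian_filter(rng.standard_normal(shape), noise_smooth,
                                mode="wrap")
        noise *= noise_sd / max(noise.std(), 1e-12)
        maps[i] = template * s + noise
    mask = spec.planted_mask(shape)
    reference = float(maps[:, mask].mean())
    records, probs = [], []
    for i in range(spec.n_patients):
        rec, p = generate_toxicity(spec, maps[i], i, reference_dose=reference)
        records.append(rec)
        probs.append(p)
    return maps, records, np.asarray(probs)


def simulate_null_cohort(n_patients: int = 60, shape: tuple[int, int] = (20, 20),
                         n_events: int = 21, seed: int = 0, noise_smooth: float = 2.0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Exchangeable null cohort: smooth random surface maps plus outcome
    labels assigned independently of dose (fixed event count, random order).

    Used to check family-wise error calibration of the permutation Tmax
    procedure; under this construction any label permutation is equally
    likely, which is exactly the exchangeability the test assumes.
    """
    rng = np.random.default_rng(seed)
    maps = gaussian_filter(rng.standard_normal((n_patients,) + shape),
                           (0, noise_smooth, noise_smooth), mode="wrap")
    labels = np.zeros(n_patients, dtype=int)
    labels[:n_events] = 1
    return maps, rng.permutation(labels)
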