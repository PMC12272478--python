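# Methods

## Coordinate and map conventions

All 3D arrays are (z, y, x): z superior, y anterior, x patient-left.
Bladder maps: rows are the polar angle θ sampled inclusively 0–180° in 2°
steps (91 rows, θ = 0 at the superior pole), columns the azimuth φ sampled
half-open [0°, 360°) in 4° steps (90 columns, no duplicated seam; φ = 0
anterior, increasing toward patient-left, so posterior is column 45).
Rectum maps: rows are axial slices inferior→superior, columns the in-plane
angle measured from anterior with the cut at the posterior wall, so the
central column faces the prostate. The exact azimuthal origin and
handedness are package conventions (documented constants in
`drmap.conventions`), not anatomically canonical choices; any consistent
pair would serve, and the plotting helpers annotate axes from the same
table so figures and arrays cannot disagree.

## Surface extraction

The surface crossing along each spherical ray is found by bisection against
a point-in-organ predicate: per slice, boundary radii about the common
vertical axis through the centre of mass are pre-tabulated at 0.5°
resolution (first boundary crossing per ray) and interpolated linearly in
both angle and z between slices. Bisection runs to 0.01 mm; on a ~50 mm
organ that keeps the geometric contribution to surface-dose error near
2 × 10⁻⁴ relative, comfortably inside the 10⁻³ oracle tolerance the sphere
phantom test enforces (a 0.1 mm tolerance would already consume 2 × 10⁻³).
Rays that never enter the organ (non-star-shaped contour) are marked
invalid and counted in a logged warning; a centre of mass outside the organ
(checked by exact point-in-polygon on the nearest slice) fails the whole
map. Dose is sampled trilinearly and never extrapolated: surface points
outside the dose grid are invalid, and map values provably stay within the
grid's [min, max].

Cylindrical unwrapping casts 90 in-plane rays per slice from the slice
centroid. Slices whose centroid escapes the contour (crescents) are filled
by linear-in-z interpolation between the adjacent valid slices when both
exist, otherwise left invalid. The raw slice-by-angle map is then resampled
to 91 rows.

Spatial normalization is bilinear. The map is a 2D object, so a third
interpolation axis has nothing to act on; validity is resampled
conservatively (an output voxel is valid only when every contributing input
voxel is). Artifact regions such as the bladder trigone are excluded by an
explicit input mask (`apply_exclusion_mask`) — automating a visual QA step
would be invented behaviour, so the package deliberately does not detect
such regions itself.

## EQD2

EQD2 = D·(d + α/β)/(2 + α/β), d = D/n, applied voxel-wise after spatial
normalization with uniform fractionation assumed (d is each voxel's total
dose divided by the patient's fraction count). Default α/β = 1 Gy: low
values maximise the spread of EQD2 across fractionation schemes and hence
the sensitivity of voxel-wise inference; the conversion is exact (identity)
at 2 Gy per fraction and tends to the physical dose as α/β → ∞ — both
enforced as tests.

## Dichotomization and missing data

Grades stay integers end to end; the event threshold (grade ≥ 1 by default)
appears in exactly one place and is configurable (e.g. grade ≥ 2) without
touching the statistics. Missing-data policy: the follow-up maximum is
taken over whichever of the 12- and 24-month grades are present; a patient
is excluded for an endpoint only when a method's required inputs are absent
(both follow-ups, or — for baseline correction only — the baseline grade),
and exclusions are returned per endpoint per method, because the two
methods may analyse different denominators. Negative baseline-adjusted
scores map to non-event; this is a documented package choice, since graded
data can in principle improve from baseline.

## Permutation inference

Welch's t uses n−1 variances; voxels with zero pooled variance are removed
from the valid mask (not epsilon-padded) and logged. Permutations reshuffle
labels without replacement, preserving the observed event count, and are
evaluated in vectorized batches (group sums and sums of squares as a
label-matrix product), which is what makes 400 × 1000-permutation
calibration runs take seconds. Thresholds are **nearest-rank** percentiles
of the sorted per-permutation maxima (the 950th of 1000 at the 95th
percentile) — stated explicitly because percentile definitions differ
across ecosystems. Both tails are computed by default (upper from the Tmax
sample, lower symmetrically from the Tmin sample at the 5th percentile),
since dose–toxicity associations can be negative in low-dose regions; the
tail selection is a config flag. The Shapiro–Wilk screen is reported but
never gates the t-map (large-sample means justify the t under the central
limit theorem; the rank-based alternative is available for sensitivity
analysis). DSC of two empty masks is defined as 0, matching the convention
of reporting DSC = 0 whenever one method finds no voxels.

## Synthetic-data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs. Geometry: bladders are star-shaped ellipsoids whose enclosed
volume follows a log-normal with mean 162.9 and SD 123.8 cm³ (clipped to
[20, 800]), with volume-preserving random anisotropy and low-order
harmonic wall perturbation; rectums are gently bowed near-circular tubes,
length ~N(97, 13) mm and volume ~N(68.4, 23.5) cm³. Slice thickness 2.5 mm;
dose-grid spacing (2.5, 2.0, 2.0) mm, inside the clinically typical ranges.
Dose: a smooth field with a sigmoidal-falloff plateau (≈ prescription
71.4 Gy, 34 fractions) over a 24 mm-radius spherical target placed
infero-posterior to the bladder / anterior to the rectum, so the high-dose
region abuts the organ wall facing it; zero falloff degenerates to an
indicator field (a tested limit). Toxicity: baseline grade ~
Bernoulli(0.10); follow-up event probability
expit(logit(0.40) + 0.25·(planted-region mean EQD2 − reference) +
0.5·baseline grade), where the reference is the cohort-mean planted dose so
the marginal event rate sits near 40 %; the maximum follow-up grade is ≥ 1
iff the event fires, with higher grades drawn from a latent severity
(1 + Binomial(2, 0.35)) — only the ≥ 1 threshold matters downstream, so
higher-grade calibration is cosmetic. Every patient consumes independent
streams keyed (seed, patient index, stream), making cohorts bit-identical
under any generation order. The planted subregion defaults to a block over
the posterior-inferior bladder surface (rows 56–77, columns 34–55), where
the generator's own target projects.

What the generator does **not** emulate: CT intensities and segmentation
error, inter-observer contour variation, organ filling/motion, dose-grid
noise, correlated multi-endpoint toxicity, and prevalence-vs-incidence
structure in 24-month data. Passing tests therefore demonstrate the
*correctness and calibration of the analysis machinery* under known truth,
not clinical reproduction of any trial's counts.

Two cohort paths exist. The geometric path (contours → dose → unwrap →
EQD2 → toxicity) exercises everything and is used for end-to-end tests at
n ≈ 20–80. Large statistical studies use the surface-map path: maps drawn
directly on the lattice as template × patient-scale (SD 0.06) + correlated
Gaussian noise (SD 2 Gy, correlation length 3 voxels), with the same
logistic link; the template spans 18–69 Gy with its peak inside the default
planted region. Problem sizes used by the calibration studies — 400 null
cohorts of n = 60 on reduced 20 × 20 maps for family-wise error, 20 seeded
runs of n = 400 on the full 91 × 90 lattice for planted-effect recovery,
1000 permutations throughout — were chosen so each study completes in
minutes on a single core while keeping Monte-Carlo error well inside the
assertion bands (binomial SE ≈ 0.011 at 400 cohorts).

## Numerical and degenerate-input choices

Ray–polygon intersection pads the edge-parameter range by 1e-9 so rays
passing exactly through a vertex are never lost (taking the minimum
crossing distance makes double hits harmless). Bisection uses a fixed
iteration count derived from the bracket length and tolerance. Groups with
fewer than two patients, empty common-valid masks, and all-event /
all-non-event labelings are refused with a dedicated exception rather than
producing NaN maps. The 1×1-map degenerate case is legal and used heavily
in tests. `RunConfig` validates every field before any computation and is
echoed verbatim into the output directory.

## Known limitations

Univariable dose-only inference cannot adjust for confounders; the package
deliberately implements the univariable chain (plus baseline correction via
dichotomization) and stops short of multivariable or mixed-effects voxel
models. Cluster-extent and FDR-style corrections are out of scope. The
spherical unwrap assumes organs star-shaped about their centre of mass;
strongly non-convex bladders degrade to partially invalid maps rather than
failing loudly unless the centre of mass itself leaves the organ. DICOM
RTSTRUCT/RTDOSE ingestion is not implemented; contours and grids enter
through the documented in-memory types and HDF5 bundle.
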