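"""Synthetic-cohort generator: seeded determinism, calibrated geometry,
dose-field structure and the planted logistic toxicity link."""

import numpy as np
import pytest

from drmap.cohort import (
    CohortSpec,
    bladder_dsm_template,
    generate_dose,
    generate_organ_geometry,
    generate_toxicity,
    simulate_dsm_cohort,
    simulate_null_cohort,
)
from drmap.conventions import N_COLS, N_ROWS


def slab_volume_cm3(contours):
    """Independent volume oracle: shoelace slice areas x uniform slab height."""
    areas = []
    for _, v in contours.slices:
        y, x = v[:, 0], v[:, 1]
        areas.append(0.5 * abs(np.sum(y * np.roll(x, -1) - x * np.roll(y, -1))))
    zs = contours.z_positions
    h = np.diff(zs).mean()
    return np.sum(areas) * h / 1000.0


class TestGeometry:
    def test_seeded_determinism(self):
        spec = CohortSpec(n_patients=5, seed=123)
        a = generate_organ_geometry(spec, 3)
        b = generate_organ_geometry(spec, 3)
        for (za, va), (zb, vb) in zip(a.slices, b.slices):
            assert za == zb
            np.testing.assert_array_equal(va, vb)
        c = generate_organ_geometry(spec, 4)
        assert not np.array_equal(a.slices[0][1], c.slices[0][1])

    def test_sphere_request_fixed_radius(self):
        """Fixed-volume, zero-anisotropy request yields an exact sphere:
        vertices within r of the axis, touching r on the equatorial slice."""
        r = 50.0  # 5 cm
        spec = CohortSpec(n_patients=2, seed=0)
        sph = generate_organ_geometry(spec, 0,
                                      fixed_volume_cm3=4 / 3 * np.pi * 5.0 ** 3,
                                      anisotropy=0.0, perturbation=0.0)
        dists = [np.hypot(v[:, 0], v[:, 1]).max() for _, v in sph.slices]
        assert max(dists) == pytest.approx(r, rel=1e-9)
        assert all(d <= r + 1e-9 for d in dists)
        equatorial = int(np.argmin(np.abs(sph.z_positions)))
        assert dists[equatorial] == pytest.approx(r, rel=1e-9)

    def test_bladder_volume_distribution_calibrated(self):
        """1000 draws: mean enclosed volume within 10% of the 162.9 cm^3
        population target (independent slab-integration oracle)."""
        spec = CohortSpec(n_patients=2, seed=2024)
        vols = [slab_volume_cm3(generate_organ_geometry(spec, i))
                for i in range(1000)]
        assert np.mean(vols) == pytest.approx(162.9, rel=0.10)

    def test_rectum_geometry_plausible(self):
        spec = CohortSpec(n_patients=2, organ="rectum", seed=5)
        for i in range(20):
            c = generate_organ_geometry(spec, i)
            assert all(len(v) >= 24 for _, v in c.slices)
            length = c.z_positions[-1] - c.z_positions[0]
            assert 55.0 <= length <= 145.0
            assert 20.0 <= slab_volume_cm3(c) <= 150.0

    def test_invalid_organ_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_patients=5, organ="prostate")


class TestDoseField:
    def test_zero_falloff_is_target_indicator(self):
        spec = CohortSpec(n_patients=2, seed=1, dose_falloff_mm=0.0)
        c = generate_organ_geometry(spec, 0)
        dose = generate_dose(spec, c)
        vals = np.unique(dose.values)
        assert set(vals) <= {0.0, spec.prescription_dose}

    def test_monotone_falloff_along_rays(self):
        spec = CohortSpec(n_patients=2, seed=1)
        c = generate_organ_geometry(spec, 0)
        dose = generate_dose(spec, c)
        # dose is a decreasing function of distance to the target centre,
        # so along any grid line moving away from the max it cannot increase
        zi, yi, xi = np.unravel_index(np.argmax(dose.values), dose.values.shape)
        line = dose.values[zi, yi, xi:]
        assert np.all(np.diff(line) <= 1e-12)

    def test_peak_dose_near_prescription(self):
        spec = CohortSpec(n_patients=2, seed=1)
        for i in range(5):
            c = generate_organ_geometry(spec, i)
            dose = generate_dose(spec, c)
            assert dose.values.max() == pytest.approx(spec.prescription_dose,
                                                      rel=0.05)

    def test_grid_covers_contours(self):
        spec = CohortSpec(n_patients=2, organ="rectum", seed=3)
        c = generate_organ_geometry(spec, 1)
        dose = generate_dose(spec, c)
        lo, hi = c.bounding_box()
        origin = np.asarray(dose.origin)
        top = origin + np.asarray(dose.spacing) * (np.asarray(dose.values.shape) - 1)
        assert np.all(origin <= lo) and np.all(top >= hi)


class TestToxicityLink:
    def test_null_event_rate_calibrated(self):
        """effect=0, no baseline component, base rate 0.3: the empirical
        event rate over 10^4 draws must sit within 0.3 +/- 0.015."""
        spec = CohortSpec(n_patients=2, effect_size=0.0,
                          baseline_prevalence=0.0, base_event_rate=0.3, seed=9)
        dsm = np.full((N_ROWS, N_COLS), 50.0)
        events = 0
        for i in range(10_000):
            rec, p = generate_toxicity(spec, dsm, i, reference_dose=50.0)
            assert p == pytest.approx(0.3)
            events += int(max(rec.grade_12m, rec.grade_24m) >= 1)
        assert events / 10_000 == pytest.approx(0.3, abs=0.015)

    def test_degenerate_baseline_prevalence_one(self):
        spec = CohortSpec(n_patients=2, baseline_prevalence=1.0, seed=4)
        dsm = np.full((N_ROWS, N_COLS), 50.0)
        for i in range(50):
            rec, _ = generate_toxicity(spec, dsm, i, reference_dose=50.0)
            assert rec.grade_baseline >= 1

    def test_grades_in_domain_and_event_structure(self):
        spec = CohortSpec(n_patients=2, seed=11)
        dsm = np.full((N_ROWS, N_COLS), 55.0)
        for i in range(300):
            rec, _ = generate_toxicity(spec, dsm, i, reference_dose=55.0)
            for g in (rec.grade_baseline, rec.grade_12m, rec.grade_24m):
                assert g in (0, 1, 2, 3)

    def test_shape_mismatch_rejected(self):
        spec = CohortSpec(n_patients=2, seed=0)
        with pytest.raises(ValueError):
            generate_toxicity(spec, np.full((N_ROWS, N_COLS), np.nan), 0)

    def test_dose_quartile_stratification(self):
        """With a strong planted effect, top-quartile planted-dose patients
        must show a strictly higher event rate than bottom-quartile."""
        spec = CohortSpec(n_patients=400, effect_size=0.5,
                          baseline_prevalence=0.0, seed=21)
        maps, recs, probs = simulate_dsm_cohort(spec)
        mask = spec.planted_mask()
        means = maps[:, mask].mean(axis=1)
        events = np.array([int(max(r.grade_12m, r.grade_24m) >= 1) for r in recs])
        q1, q3 = np.quantile(means, [0.25, 0.75])
        assert events[means >= q3].mean() > events[means <= q1].mean()


class TestSurfaceMapPath:
    def test_template_high_dose_inside_planted_region(self):
        spec = CohortSpec(n_patients=2)
        t = bladder_dsm_template()
        r, c = np.unravel_index(np.argmax(t), t.shape)
        assert spec.planted_mask()[r, c]
        assert t.min() == pytest.approx(18.0, abs=1.0)
        assert t.max() == pytest.approx(69.0, abs=1.0)

    def test_dsm_cohort_deterministic(self):
        spec = CohortSpec(n_patients=30, seed=77)
        m1, r1, p1 = simulate_dsm_cohort(spec)
        m2, r2, p2 = simulate_dsm_cohort(spec)
        np.testing.assert_array_equal(m1, m2)
        assert r1 == r2
        np.testing.assert_array_equal(p1, p2)

    def test_null_cohort_exchangeable_structure(self):
        maps, labels = simulate_null_cohort(n_patients=60, seed=3)
        assert maps.shape == (60, 20, 20)
        assert labels.sum() == 21
        m2, l2 = simulate_null_cohort(n_patients=60, seed=3)
        np.testing.assert_array_equal(maps, m2)
        np.testing.assert_array_equal(labels, l2)
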