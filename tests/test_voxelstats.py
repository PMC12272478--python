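"""Voxel-wise statistics: Welch/Mann-Whitney oracle equivalence, the
Shapiro-Wilk screen, permutation Tmax behaviour and Dice overlap."""

import numpy as np
import pytest
from scipy import stats

from drmap.conventions import DegenerateGroupsError
from drmap.voxelstats import (
    count_significant,
    dsc,
    mannwhitney_map,
    permutation_tmax,
    shapiro_screen,
    welch_tmap,
)


def _maps(values_by_patient):
    """Wrap per-patient scalar lists as 1x1 'maps'."""
    return [np.array([[v]], dtype=float) for v in values_by_patient]


class TestWelch:
    def test_hand_computed_example(self):
        # means 4 vs 2, equal unit variances, n=3: t = 2 / sqrt(2/3)
        t = welch_tmap(_maps([3, 4, 5]), _maps([1, 2, 3]))
        assert t.t[0, 0] == pytest.approx(2.449489742783178, abs=1e-12)

    def test_identical_means_give_zero(self):
        t = welch_tmap(_maps([1.0, 2.0, 3.0]), _maps([3.0, 2.0, 1.0]))
        assert t.t[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_sign_convention_events_higher_dose_positive(self):
        t = welch_tmap(_maps([10, 11, 12]), _maps([1, 2, 3]))
        assert t.t[0, 0] > 0

    def test_matches_scipy_voxelwise(self):
        """50 vs 50 random maps: every voxel within 1e-10 of the reference
        Welch implementation."""
        rng = np.random.default_rng(42)
        ev = rng.normal(50, 5, (50, 13, 17))
        nv = rng.normal(48, 7, (50, 13, 17))
        tmap = welch_tmap(list(ev), list(nv))
        ref = stats.ttest_ind(ev, nv, axis=0, equal_var=False).statistic
        np.testing.assert_allclose(tmap.t, ref, atol=1e-10)

    def test_constant_voxels_removed_from_valid(self):
        ev = [np.array([[1.0, 5.0]]), np.array([[1.0, 6.0]])]
        nv = [np.array([[1.0, 2.0]]), np.array([[1.0, 3.0]])]
        tmap = welch_tmap(ev, nv)
        assert not tmap.valid[0, 0] and tmap.valid[0, 1]

    def test_degenerate_groups_refused(self):
        with pytest.raises(DegenerateGroupsError):
            welch_tmap(_maps([1.0]), _maps([1.0, 2.0]))


class TestMannWhitney:
    def test_complete_separation_maximal_u(self):
        m = mannwhitney_map(_maps([6, 7, 8, 9, 10]), _maps([1, 2, 3, 4, 5]))
        assert m.u_raw[0, 0] == 25.0

    def test_identical_pooled_samples_standardized_zero(self):
        m = mannwhitney_map(_maps([1, 2, 3, 4]), _maps([1, 2, 3, 4]))
        assert m.t[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_raw_u_matches_scipy_exactly(self):
        rng = np.random.default_rng(3)
        ev = rng.normal(0, 1, (20, 4, 5))
        nv = rng.normal(0.5, 2, (25, 4, 5))
        m = mannwhitney_map(list(ev), list(nv))
        for r in range(4):
            for c in range(5):
                ref = stats.mannwhitneyu(ev[:, r, c], nv[:, r, c]).statistic
                assert m.u_raw[r, c] == ref


class TestShapiroScreen:
    def test_constant_voxel_non_analysable(self):
        group = [np.array([[1.0, float(i)]]) for i in range(10)]
        scr = shapiro_screen(group)
        assert not scr.analysable[0, 0] and scr.analysable[0, 1]

    def test_calibrated_under_normality(self):
        rng = np.random.default_rng(7)
        group = list(rng.normal(0, 1, (200, 10, 50)))  # 500 voxels, n=200
        scr = shapiro_screen(group, alpha=0.05)
        # failing fraction ~ alpha; 4 sigma binomial band
        assert abs(scr.failing_fraction - 0.05) < 4 * np.sqrt(0.05 * 0.95 / 500)

    def test_powerful_against_skew(self):
        rng = np.random.default_rng(8)
        group = list(rng.exponential(1.0, (200, 5, 20)))
        scr = shapiro_screen(group, alpha=0.05)
        assert scr.failing_fraction > 0.9


class TestPermutationTmax:
    @staticmethod
    def _cohort(seed=0, n=30, shape=(8, 9), effect=0.0):
        rng = np.random.default_rng(seed)
        maps = rng.normal(50, 5, (n,) + shape)
        labels = np.zeros(n, int)
        labels[: n // 3] = 1
        labels = rng.permutation(labels)
        maps[labels == 1, 2:5, 3:6] += effect
        return maps, labels

    def test_reproducible_under_seed(self):
        maps, labels = self._cohort()
        a = permutation_tmax(list(maps), labels, n_iterations=200, seed=5)
        b = permutation_tmax(list(maps), labels, n_iterations=200, seed=5)
        np.testing.assert_array_equal(a.tmax_samples, b.tmax_samples)
        assert a.threshold_upper == b.threshold_upper

    def test_observed_map_independent_of_seed(self):
        maps, labels = self._cohort()
        a = permutation_tmax(list(maps), labels, n_iterations=200, seed=1)
        b = permutation_tmax(list(maps), labels, n_iterations=200, seed=2)
        np.testing.assert_array_equal(a.observed.t, b.observed.t)
        assert a.threshold_upper != b.threshold_upper  # permutation noise

    def test_threshold_monotone_in_percentile_and_masks_shrink(self):
        maps, labels = self._cohort(effect=6.0)
        lo = permutation_tmax(list(maps), labels, n_iterations=400,
                              percentile=90, seed=3)
        hi = permutation_tmax(list(maps), labels, n_iterations=400,
                              percentile=99, seed=3)
        assert hi.threshold_upper >= lo.threshold_upper
        assert not np.any(hi.sig_mask_high & ~lo.sig_mask_high)

    def test_patient_order_invariance_of_observed_map(self):
        maps, labels = self._cohort(effect=4.0)
        perm = np.random.default_rng(9).permutation(len(labels))
        a = permutation_tmax(list(maps), labels, n_iterations=150, seed=4)
        b = permutation_tmax(list(maps[perm]), labels[perm],
                             n_iterations=150, seed=4)
        np.testing.assert_allclose(a.observed.t, b.observed.t, atol=1e-12)

    def test_planted_effect_detected_in_upper_tail(self):
        maps, labels = self._cohort(effect=8.0, n=60)
        res = permutation_tmax(list(maps), labels, n_iterations=500, seed=6)
        assert res.sig_mask_high[2:5, 3:6].any()
        assert res.sig_mask_high.sum() <= res.observed.valid.sum() <= 72

    def test_mannwhitney_statistic_plugs_in(self):
        maps, labels = self._cohort(effect=8.0, n=60)
        res = permutation_tmax(list(maps), labels, statistic="mannwhitney",
                               n_iterations=300, seed=6)
        assert res.sig_mask_high[2:5, 3:6].any()

    def test_degenerate_labels_refused(self):
        maps, _ = self._cohort()
        labels = np.zeros(len(maps), int)
        labels[0] = 1
        with pytest.raises(DegenerateGroupsError):
            permutation_tmax(list(maps), labels, n_iterations=150, seed=0)


class TestDice:
    def test_identical_nonempty_masks(self):
        m = np.zeros((91, 90), bool)
        m[: 10] = True
        assert dsc(m, m).dsc == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((91, 90), bool)
        b = np.zeros((91, 90), bool)
        a[0], b[1] = True, True
        assert dsc(a, b).dsc == 0.0

    def test_both_empty_defined_as_zero(self):
        z = np.zeros((5, 5), bool)
        assert dsc(z, z).dsc == 0.0

    def test_symmetry_and_range(self):
        rng = np.random.default_rng(0)
        a = rng.random((91, 90)) > 0.7
        b = rng.random((91, 90)) > 0.4
        r1, r2 = dsc(a, b), dsc(b, a)
        assert r1.dsc == r2.dsc
        assert 0.0 <= r1.dsc <= 1.0

    def test_formula_self_check_at_printed_counts(self):
        """Mask sizes 1143 and 186 with full overlap of the smaller mask give
        2*186/1329 = 0.28 (2 d.p.) -- a pure formula check."""
        a = np.zeros((91, 90), bool)
        b = np.zeros((91, 90), bool)
        a.ravel()[:1143] = True
        b.ravel()[:186] = True
        r = dsc(a, b)
        assert (r.n_a, r.n_b, r.n_intersection) == (1143, 186, 186)
        assert round(r.dsc, 2) == 0.28

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dsc(np.zeros((2, 2), bool), np.zeros((3, 3), bool))


def test_count_significant():
    assert count_significant(np.zeros((91, 90), bool)) == 0
    assert count_significant(np.ones((91, 90), bool)) == 8190
    m = np.zeros((91, 90), bool)
    m.ravel()[np.random.default_rng(1).choice(8190, 137, replace=False)] = True
    assert count_significant(m) == 137
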