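"""DVH engine, isodose sphere fitting, profiles, and Wilcoxon comparison."""

import itertools

import numpy as np
import pytest

from latticeplan.dose_eval import (
    DVHMetrics,
    compare_plans,
    dose_profile,
    dvh_curve,
    dvh_metrics,
    fit_spheres_from_isodose,
)
from latticeplan.grids import BinaryMask, DoseGrid, ImageVolume
from latticeplan.lattice import SphereSet
from latticeplan.phantom import ellipsoid_mask, synth_lattice_dose


def dose_of(arr, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return DoseGrid(np.asarray(arr, dtype=float), spacing, origin)


def mask_of(arr, spacing=(1, 1, 1), origin=(0, 0, 0)):
    return BinaryMask(np.asarray(arr, dtype=np.uint8), spacing, origin)


def full_mask(shape, spacing=(1, 1, 1)):
    return mask_of(np.ones(shape), spacing)


class TestDvhCurve:
    def test_uniform_dose_step_function(self):
        d = dose_of(np.full((10, 10, 10), 2000.0))
        c = dvh_curve(d, full_mask((10, 10, 10)))
        assert c.volume_fraction[0] == 1.0
        assert c.volume_fraction[np.searchsorted(c.dose_cGy, 2000.0)] == 1.0
        assert c.volume_fraction[np.searchsorted(c.dose_cGy, 2001.0)] == 0.0

    def test_two_voxel_hand_enumeration(self):
        arr = np.zeros((2, 1, 1))
        arr[0] = 100.0
        arr[1] = 300.0
        c = dvh_curve(dose_of(arr), full_mask((2, 1, 1)))
        f = lambda dose: c.volume_fraction[np.searchsorted(c.dose_cGy, dose)]
        assert f(0.0) == 1.0 and f(100.0) == 1.0
        assert f(101.0) == 0.5 and f(300.0) == 0.5
        assert f(301.0) == 0.0

    def test_matches_sorted_voxel_oracle(self, rng):
        arr = rng.random((10, 10, 10)) * 1500
        d = dose_of(arr)
        c = dvh_curve(d, full_mask((10, 10, 10)), bin_width_cGy=1.0)
        flat = np.sort(arr.ravel())
        for edge, frac in zip(c.dose_cGy[::97], c.volume_fraction[::97]):
            expect = (flat >= edge).sum() / flat.size if edge > 0 else 1.0
            assert frac == pytest.approx(expect, abs=1e-12)

    def test_empty_mask_names_structure(self):
        d = dose_of(np.ones((4, 4, 4)))
        with pytest.raises(ValueError, match="cord"):
            dvh_curve(d, mask_of(np.zeros((4, 4, 4))), name="cord")

    def test_curve_non_increasing(self, rng):
        d = dose_of(rng.random((8, 8, 8)) * 900)
        c = dvh_curve(d, full_mask((8, 8, 8)))
        assert np.all(np.diff(c.volume_fraction) <= 1e-12)


class TestDvhMetrics:
    def test_uniform_dose_degenerate(self):
        d = dose_of(np.full((6, 6, 6), 800.0))
        m = dvh_metrics(d, full_mask((6, 6, 6)))
        for v in (m.Dmax, m.Dmin, m.Dmean, m.D10, m.D50, m.D90):
            assert v == 800.0
        assert m.heterogeneity == 1.0

    def test_linear_ramp_closed_form(self):
        # 1000 voxels with doses 0.5, 1.5, ..., 999.5 (uniform over (0, 1000))
        arr = (np.arange(1000.0).reshape(10, 10, 10) + 0.5)
        m = dvh_metrics(dose_of(arr), full_mask((10, 10, 10)), mvs_level_cGy=740.0)
        assert m.D50 == pytest.approx(500.0, abs=1.0)
        assert m.D90 == pytest.approx(100.0, abs=1.0)
        assert m.D10 == pytest.approx(900.0, abs=1.0)
        # MVS(740): volume below 740 cGy = 74% of 1 cc
        assert m.MVS_cc == pytest.approx(0.74 * 0.001 * 1000, abs=0.002)

    def test_d003cc_hand_count(self, rng):
        # 1000 voxels of 1 mm^3; hottest 30 voxels at 600, rest 100
        arr = np.full(1000, 100.0)
        arr[:30] = 600.0
        rng.shuffle(arr)
        m = dvh_metrics(dose_of(arr.reshape(10, 10, 10)), full_mask((10, 10, 10)),
                        dv_cc=(0.03,))
        assert m.D003cc == 600.0

    def test_matches_sort_oracle_exactly(self, rng):
        d = dose_of(rng.random((12, 12, 12)) * 2000)
        m = dvh_metrics(d, full_mask((12, 12, 12)))
        s = np.sort(np.asarray(d.voxels, dtype=np.float64).ravel())[::-1]
        n = s.size

        def oracle_dx(x):
            k = (x / 100.0) * n  # voxels
            if k <= 1:
                return s[0]
            i = int(np.floor(k - 1.0))
            fr = (k - 1.0) - i
            if i >= n - 1:
                return s[-1]
            return s[i] * (1 - fr) + s[i + 1] * fr

        assert m.D10 == pytest.approx(oracle_dx(10), abs=1e-9)
        assert m.D50 == pytest.approx(oracle_dx(50), abs=1e-9)
        assert m.D90 == pytest.approx(oracle_dx(90), abs=1e-9)
        assert m.Dmax == s[0] and m.Dmin == s[-1]

    def test_ordering_invariant_on_random_doses(self, rng):
        for _ in range(100):
            arr = rng.random((6, 6, 6)) * rng.integers(10, 3000)
            m = dvh_metrics(dose_of(arr), full_mask((6, 6, 6)))
            assert m.Dmin <= m.D90 <= m.D50 <= m.D10 <= m.Dmax
            assert m.heterogeneity >= 1.0

    def test_dv_exceeding_volume_errors(self):
        d = dose_of(np.ones((2, 2, 2)))  # 8 mm^3 = 0.008 cc
        with pytest.raises(ValueError):
            dvh_metrics(d, full_mask((2, 2, 2)), dv_cc=(1.0,))


class TestIsodoseFit:
    def _setup(self):
        ref = ImageVolume(np.zeros((80, 80, 60)), (2, 2, 2), (-79, -79, -59))
        gtv = ellipsoid_mask(ref, (0, 0, 0), (65, 60, 50))
        centers = np.array([[-30.0, 0.0, -20.0], [30.0, 0.0, -20.0], [0.0, 10.0, 25.0]])
        spheres = SphereSet(centers, 15.0)
        dose = synth_lattice_dose(spheres, gtv, 2000.0, valley_ratio=0.3)
        return centers, dose

    def test_recovers_generating_centers(self):
        centers, dose = self._setup()
        fitted = fit_spheres_from_isodose(dose, 2000.0, level_fraction=0.5)
        assert len(fitted) == len(centers)
        got = fitted.centers_mm[np.lexsort(fitted.centers_mm.T)]
        want = centers[np.lexsort(centers.T)]
        assert np.abs(got - want).max() <= 2.0  # within one voxel

    def test_fitted_diameter_fixed_at_15mm(self):
        _, dose = self._setup()
        fitted = fit_spheres_from_isodose(dose, 2000.0)
        assert fitted.diameter_mm == 15.0

    def test_subthreshold_dose_empty(self):
        d = dose_of(np.full((8, 8, 8), 100.0))
        assert len(fit_spheres_from_isodose(d, 2000.0)) == 0

    def test_speckle_filtered(self):
        arr = np.zeros((20, 20, 20))
        arr[10, 10, 10] = 1500.0  # single hot voxel, 0.001 cc < 0.1 cc filter
        assert len(fit_spheres_from_isodose(dose_of(arr), 2000.0)) == 0


class TestDoseProfile:
    def test_profile_through_sphere_center_peaks_at_center(self):
        ref = ImageVolume(np.zeros((60, 60, 40)), (2, 2, 2), (-59, -59, -39))
        gtv = ellipsoid_mask(ref, (0, 0, 0), (50, 50, 35))
        dose = synth_lattice_dose(SphereSet(np.array([[0.0, 0.0, 0.0]]), 15.0),
                                  gtv, 2000.0, 0.3)
        prof = dose_profile(dose, (-40, 0, 0), (40, 0, 0), n_samples=81)
        assert abs(int(np.argmax(prof)) - 40) <= 1

    def test_zero_dose_region_zero_profile(self):
        d = dose_of(np.zeros((10, 10, 10)))
        assert np.all(dose_profile(d, (1, 1, 1), (8, 8, 8), 20) == 0)

    def test_constant_dose_constant_profile(self):
        d = dose_of(np.full((10, 10, 10), 500.0))
        prof = dose_profile(d, (1, 1, 1), (8, 8, 8), 20)
        assert np.allclose(prof, 500.0)

    def test_endpoint_outside_grid_errors(self):
        d = dose_of(np.zeros((10, 10, 10)))
        with pytest.raises(ValueError):
            dose_profile(d, (0, 0, 0), (100, 0, 0))


def wilcoxon_enumeration_oracle(diffs):
    """Exact two-sided p by enumerating all sign assignments of |diffs| ranks."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_plus = ranks[d > 0].sum()
    w_obs = min(w_plus, n * (n + 1) / 2 - w_plus)
    count = 0
    total = 2 ** n
    for signs in itertools.product((0, 1), repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        w = min(wp, n * (n + 1) / 2 - wp)
        if w <= w_obs:
            count += 1
    return count / total


def metrics_dict(values):
    return {"s": DVHMetrics(Dmax=values, Dmin=values, Dmean=values,
                            D10=values, D50=values, D90=values)}


class TestComparePlans:
    def test_identical_plans_degenerate(self):
        a = [metrics_dict(100.0 + i) for i in range(6)]
        cmp = compare_plans(a, [metrics_dict(100.0 + i) for i in range(6)])
        assert np.all(cmp.deviations["s"]["Dmax"] == 0.0)
        assert cmp.tests["s"]["Dmax"]["degenerate"]

    def test_p_matches_exhaustive_enumeration(self, rng):
        for n in (6, 8, 10):
            da = rng.normal(0, 30, n)
            a = [metrics_dict(1000.0 + x) for x in da]
            b = [metrics_dict(1000.0) for _ in range(n)]
            cmp = compare_plans(a, b)
            got = cmp.tests["s"]["D50%"]["p_value"]
            want = wilcoxon_enumeration_oracle(da)
            assert got == pytest.approx(want, abs=1e-12)

    def test_constant_offset_smallest_p(self):
        n = 6
        a = [metrics_dict(1000.0) for _ in range(n)]
        b = [metrics_dict(1050.0) for _ in range(n)]
        cmp = compare_plans(a, b)
        assert np.all(cmp.deviations["s"]["Dmean"] == -50.0)
        # all-negative differences: two-sided p = 2/2^n, the smallest possible
        assert cmp.tests["s"]["Dmean"]["p_value"] == pytest.approx(2.0 / 2 ** n, abs=1e-12)

    def test_under_five_cases_no_tests(self):
        a = [metrics_dict(1.0)] * 3
        cmp = compare_plans(a, a)
        assert cmp.tests["s"] == {}

    def test_unmatched_structures_error(self):
        a = [{"gtv": metrics_dict(1.0)["s"]}]
        b = [{"cord": metrics_dict(1.0)["s"]}]
        with pytest.raises(ValueError, match="cord|gtv"):
            compare_plans(a, b)
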