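"""Saturation metrics: fractions, H^A_sat, surfaces, isoclines, equivalence."""

import numpy as np
import pytest

from seacanopy.radiosity import LeafIrradianceField
from seacanopy.saturation import (DEFAULT_ISOCLINE_LEVELS, Ek,
                                  SaturationSeries, build_hasat_surface,
                                  compare_wave_treatments,
                                  equivalent_unshaded_lai, extract_isoclines,
                                  hasat, hsat_top, leaf_par_histogram,
                                  saturated_fraction,
                                  shading_equivalence_error, wave_average)


def _field(par, areas=None):
    par = np.asarray(par, dtype=float)
    areas = (np.ones_like(par) if areas is None
             else np.asarray(areas, dtype=float))
    return LeafIrradianceField(areas=areas, par=par,
                               spectral=np.zeros((par.size, 17)),
                               toc_par=500.0)


def _surface(values, lais=(1.0, 2.0, 4.0, 8.0),
             shadings=(0.0, 25.0, 50.0, 75.0), ek=50.0):
    res = {(l, s): values[i][j] for i, l in enumerate(lais)
           for j, s in enumerate(shadings)}
    return build_hasat_surface(res, lais, shadings, Ek(ek))


def _smooth_surface(fn, lais=(1.0, 2.0, 4.0, 8.0),
                    shadings=(0.0, 25.0, 50.0, 75.0)):
    vals = [[fn(l, s) for s in shadings] for l in lais]
    return _surface(vals, lais, shadings)


class TestSaturatedFraction:
    def test_all_above_all_below_and_split(self):
        ek = Ek(50.0)
        assert saturated_fraction(_field([100.0, 100.0]), ek) == 100.0
        assert saturated_fraction(_field([0.0, 0.0]), ek) == 0.0
        assert saturated_fraction(_field([50.0 - 1e-9, 50.0 + 1e-9]), ek) == 50.0

    def test_threshold_is_inclusive(self):
        assert saturated_fraction(_field([50.0]), Ek(50.0)) == 100.0

    def test_area_weighting(self):
        f = _field([100.0, 0.0], areas=[3.0, 1.0])
        assert saturated_fraction(f, Ek(50.0)) == 75.0

    def test_zero_leaf_area_rejected(self):
        with pytest.raises(ValueError):
            saturated_fraction(_field([], []), Ek(50.0))

    def test_ek_must_be_positive(self):
        with pytest.raises(ValueError):
            Ek(0.0)


class TestHistogram:
    def test_single_facet_single_bin(self):
        h = leaf_par_histogram(_field([75.0]), np.array([0, 50, 100, 200]))
        assert h[1] == 100.0 and h.sum() == 100.0

    def test_fractions_sum_to_100(self):
        rng = np.random.default_rng(0)
        f = _field(rng.uniform(1, 900, 200), rng.uniform(0.5, 2, 200))
        h = leaf_par_histogram(f, np.array([0, 10, 100, 1000]))
        assert h.sum() == pytest.approx(100.0, abs=1e-9)

    def test_halving_shifts_one_octave_in_log2_bins(self):
        rng = np.random.default_rng(1)
        par = rng.uniform(2.0, 500.0, 300)
        edges = 2.0 ** np.arange(0, 11)
        f1 = _field(par)
        f2 = _field(par / 2.0)
        h1 = leaf_par_histogram(f1, edges)
        h2 = leaf_par_histogram(f2, edges)
        assert np.allclose(h2[:-1], h1[1:], atol=1e-9)


class TestHasat:
    def test_ceiling_600_and_zero(self):
        hours = np.arange(12.0)
        toc = np.full(12, 600.0)
        assert hasat(SaturationSeries(hours, np.full(12, 100.0), toc)) == 1200.0
        assert hasat(SaturationSeries(hours, np.full(12, 50.0), toc)) == 600.0
        assert hasat(SaturationSeries(hours, np.zeros(12), toc)) == 0.0

    def test_monotone_functional(self):
        hours = np.arange(12.0)
        toc = np.full(12, 600.0)
        rng = np.random.default_rng(2)
        a = rng.uniform(0, 100, 12)
        b = np.clip(a - rng.uniform(0, 20, 12), 0, None)
        assert hasat(SaturationSeries(hours, a, toc)) >= hasat(
            SaturationSeries(hours, b, toc))


class TestHsatTop:
    def test_counting(self):
        hours = np.arange(12.0)
        sat = np.zeros(12)
        assert hsat_top(SaturationSeries(hours, sat, np.full(12, 100.0)),
                        Ek(50.0)) == 12.0
        assert hsat_top(SaturationSeries(hours, sat, np.full(12, 10.0)),
                        Ek(50.0)) == 0.0
        toc = np.where((hours >= 3) & (hours < 9), 80.0, 10.0)
        assert hsat_top(SaturationSeries(hours, sat, toc), Ek(50.0)) == 6.0


class TestWaveStatistics:
    def test_identical_snapshots_zero_sd(self):
        assert wave_average([5.0] * 14) == (5.0, 0.0)

    def test_hand_computed_sample_sd(self):
        mean, sd = wave_average([40.0, 60.0])
        assert mean == 50.0
        assert sd == pytest.approx(14.142, abs=1e-3)

    def test_mean_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 100, 14)
        mean, _ = wave_average(vals)
        assert mean == pytest.approx(vals.sum() / 14.0, rel=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            wave_average([])


class TestCompareWaveTreatments:
    def test_identical_pairs(self):
        d, t, p = compare_wave_treatments([1, 2, 3], [1, 2, 3])
        assert (d, t, p) == (0.0, 0.0, 1.0)

    def test_textbook_pairs_limit_case(self):
        """Constant difference -1: zero variance, flagged limit p."""
        d, t, p = compare_wave_treatments([1, 2, 3], [2, 3, 4])
        assert d == -1.0
        assert p == 0.0 and np.isinf(t)

    def test_matches_scipy_on_noisy_pairs(self):
        rng = np.random.default_rng(4)
        a = rng.uniform(100, 800, 10)
        b = a + rng.normal(0, 30, 10)
        from scipy import stats
        expected = stats.ttest_rel(a, b)
        d, t, p = compare_wave_treatments(a, b)
        assert t == pytest.approx(expected.statistic, rel=1e-12)
        assert p == pytest.approx(expected.pvalue, rel=1e-12)


class TestSurface:
    def test_bounds_and_double_monotonicity_enforced(self):
        s = _smooth_surface(lambda l, sh: 1000 * np.exp(-0.2 * l) * (1 - sh / 100))
        assert np.all(s.values >= 0) and np.all(s.values <= 1200)
        with pytest.raises(ValueError, match="monotone"):
            _surface([[100, 90, 80, 70],
                      [120, 85, 75, 65],   # increases with LAI
                      [90, 80, 70, 60],
                      [80, 70, 60, 50]])

    def test_missing_cells_rejected_with_list(self):
        res = {(1.0, 0.0): 100.0}
        with pytest.raises(ValueError, match="missing"):
            build_hasat_surface(res, [1.0, 2.0], [0.0], Ek(50.0))

    def test_full_shading_column_is_zero(self):
        s = _smooth_surface(
            lambda l, sh: 0.0 if sh == 100.0 else 500 * np.exp(-0.2 * l),
            shadings=(0.0, 50.0, 100.0))
        assert np.all(s.values[:, -1] == 0.0)

    def test_corner_ordering(self):
        s = _smooth_surface(lambda l, sh: 900 * np.exp(-0.3 * l) * (1 - sh / 100))
        assert s.values[0, 0] >= s.values[-1, -1]


class TestIsoclines:
    def test_default_levels(self):
        assert DEFAULT_ISOCLINE_LEVELS == (50.0, 100.0, 200.0, 300.0, 400.0,
                                           500.0, 600.0, 700.0, 800.0)

    def test_constant_surface_rejected(self):
        s = _smooth_surface(lambda l, sh: 400.0)
        with pytest.raises(ValueError, match="degenerate"):
            extract_isoclines(s, [400.0])

    def test_linear_surface_contours_match_closed_form(self):
        """Plane H = 1100 - 60 L - 5 s: contour points satisfy the plane."""
        s = _smooth_surface(lambda l, sh: 1100.0 - 60.0 * l - 5.0 * sh)
        iso = extract_isoclines(s, [600.0])
        assert len(iso[600.0]) >= 1
        for poly in iso[600.0]:
            vals = 1100.0 - 60.0 * poly[:, 0] - 5.0 * poly[:, 1]
            assert np.allclose(vals, 600.0, atol=1e-6)

    def test_out_of_range_level_empty(self):
        s = _smooth_surface(lambda l, sh: 1100.0 - 60.0 * l - 5.0 * sh)
        iso = extract_isoclines(s, [5000.0])
        assert iso[5000.0] == []

    def test_contour_points_reinterpolate_to_level(self):
        s = _smooth_surface(
            lambda l, sh: 1000 * np.exp(-0.25 * l) * (1 - sh / 100) ** 1.3)
        iso = extract_isoclines(s)
        for level, polys in iso.items():
            for poly in polys:
                for lai, sh in poly[::3]:
                    assert s.interpolate(lai, sh) == pytest.approx(
                        level, abs=0.01 * 1200)


class TestEquivalentLai:
    def test_identity_on_unshaded_axis(self):
        s = _smooth_surface(lambda l, sh: 800 * np.exp(-0.25 * l) * (1 - sh / 100))
        for lai in (1.0, 2.0, 4.0, 8.0):
            r = equivalent_unshaded_lai(s, lai, 0.0)
            assert r.value == pytest.approx(lai, abs=1e-9)
            assert not r.extrapolated

    def test_closed_form_inversion(self):
        """H = C exp(-bL)(1-s): equivalent L* = L - ln(1-s)/b (piecewise
        linear interpolation error allowed)."""
        s = _smooth_surface(
            lambda l, sh: 800 * np.exp(-0.25 * l) * (1 - sh / 100),
            lais=tuple(np.linspace(0.5, 10, 20)))
        r = equivalent_unshaded_lai(s, 2.0, 50.0)
        assert r.value == pytest.approx(2.0 + np.log(2.0) / 0.25, abs=0.1)

    def test_extrapolation_is_flagged(self):
        s = _smooth_surface(lambda l, sh: 800 * np.exp(-0.25 * l) * (1 - sh / 100))
        r = equivalent_unshaded_lai(s, 8.0, 75.0)
        assert r.extrapolated
        assert r.value > 8.0


class TestShadingEquivalence:
    def test_identical_surfaces_zero(self):
        s = _smooth_surface(lambda l, sh: 700 * np.exp(-0.2 * l) * (1 - sh / 100))
        max_shift, shifts = shading_equivalence_error(s, s)
        assert max_shift == pytest.approx(0.0, abs=1e-9)

    def test_constructed_five_point_shift(self):
        """B equals A shifted 5 points along the shading axis."""
        shadings = tuple(np.linspace(0.0, 80.0, 17))

        def h(l, sh):
            return 800 * np.exp(-0.2 * l) * (1 - sh / 100.0)

        a = _smooth_surface(lambda l, sh: h(l, sh + 5.0), shadings=shadings)
        b = _smooth_surface(h, shadings=shadings)
        max_shift, _ = shading_equivalence_error(a, b)
        assert max_shift == pytest.approx(5.0, abs=0.1)

    def test_mismatched_grids_rejected(self):
        a = _smooth_surface(lambda l, sh: 700 * np.exp(-0.2 * l) * (1 - sh / 100))
        b = _smooth_surface(lambda l, sh: 700 * np.exp(-0.2 * l) * (1 - sh / 100),
                            lais=(1.0, 2.0, 4.0, 9.0))
        with pytest.raises(ValueError):
            shading_equivalence_error(a, b)
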