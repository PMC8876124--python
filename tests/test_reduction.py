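"""Stress–strain reduction and DIN-50134-style summary statistics."""

import math

import numpy as np
import pytest

from mycomech import neohooke as nh
from mycomech import reduction as red
from mycomech.reduction import (
    LoadDisplacementCurve,
    SpecimenGeometry,
    StressStrainCurve,
)


def make_curve(u, f, geom, **kw):
    return LoadDisplacementCurve(np.asarray(u, float), np.asarray(f, float), geom, **kw)


class TestToStressStrain:
    def test_hand_computed_stress(self, standard_geometry):
        # 1800 N on a 70 mm cylinder: sigma = 1800 / (pi 35^2) MPa
        c = make_curve([0, 10, 20], [0, 900, 1800], standard_geometry)
        ssc = red.to_stress_strain(c, preload=0)
        assert ssc.stress[-1] == pytest.approx(1800 / (math.pi * 35**2), rel=1e-12)
        assert ssc.stress[-1] == pytest.approx(0.4677, abs=2e-4)

    def test_zero_maps_to_zero(self, standard_geometry):
        c = make_curve([0, 5], [0, 10], standard_geometry)
        ssc = red.to_stress_strain(c, preload=0)
        assert ssc.strain[0] == 0.0 and ssc.stress[0] == 0.0

    def test_strain_is_displacement_ratio(self):
        g = SpecimenGeometry(diameter=70, height=64)
        c = make_curve([0, 32], [0, 100], g)
        ssc = red.to_stress_strain(c, preload=0)
        assert ssc.strain[-1] == pytest.approx(0.5)

    def test_preload_trimming(self, standard_geometry):
        c = make_curve([0, 1, 2, 3], [0.1, 0.5, 2.0, 5.0], standard_geometry)
        ssc = red.to_stress_strain(c)  # default 1 N pre-load
        assert ssc.strain[0] == pytest.approx(2 / 65)
        assert len(ssc.strain) == 2

    def test_rejects_strain_reaching_one(self):
        g = SpecimenGeometry(diameter=70, height=10)
        c = make_curve([0, 10], [0, 100], g)
        with pytest.raises(ValueError):
            red.to_stress_strain(c, preload=0)

    def test_order_preserved(self, standard_geometry, rng):
        u = np.sort(rng.uniform(0, 30, 40))
        u[0] = 0.0
        f = rng.uniform(2, 100, 40)
        ssc = red.to_stress_strain(make_curve(u, f, standard_geometry), preload=0)
        np.testing.assert_allclose(np.diff(ssc.strain), np.diff(u) / 65)


class TestElasticModulus:
    def test_recovers_constructed_slope(self):
        eps = np.linspace(0, 0.3, 100)
        ssc = StressStrainCurve(eps, 2.37 * eps, area=1, height=1)
        m, _ = red.elastic_modulus(ssc, window=(0.0, 0.3))
        assert m == pytest.approx(2.37, rel=1e-12)

    def test_constant_stress_gives_zero(self):
        eps = np.linspace(0, 0.3, 50)
        ssc = StressStrainCurve(eps, np.full_like(eps, 0.2), area=1, height=1)
        m, _ = red.elastic_modulus(ssc, window=(0.0, 0.3))
        assert m == pytest.approx(0.0, abs=1e-12)

    def test_neo_hookean_curve_matches_secant(self, foam_params):
        eps = np.linspace(0, 0.4, 400)
        lam = 1 - eps
        sig = np.abs(nh.uniaxial_stress(np.maximum(lam, 1e-6), foam_params))
        ssc = StressStrainCurve(eps, sig, area=1, height=1)
        window = (0.10, 0.30)
        m, _ = red.elastic_modulus(ssc, window=window)
        s_lo = abs(nh.uniaxial_stress(1 - window[0], foam_params))
        s_hi = abs(nh.uniaxial_stress(1 - window[1], foam_params))
        secant = (s_hi - s_lo) / (window[1] - window[0])
        assert m == pytest.approx(secant, rel=0.03)

    def test_recovery_based_default_window(self):
        eps = np.linspace(0, 0.5, 200)
        ssc = StressStrainCurve(eps, 1.5 * eps, area=1, height=1)
        m, win = red.elastic_modulus(ssc, elastic_recovery=0.2)
        assert win == (0.10, pytest.approx(0.30))
        assert m == pytest.approx(1.5, rel=1e-9)
        # absolute-bound variant uses the recovery itself as upper strain
        m2, win2 = red.elastic_modulus(
            ssc, elastic_recovery=0.2, recovery_is_span=False
        )
        assert win2 == (0.10, pytest.approx(0.2))

    def test_shift_and_scale_invariance(self, rng):
        eps = np.linspace(0, 0.4, 100)
        sig = 0.8 * eps + 0.05 * rng.standard_normal(100) * 0
        sig = 0.8 * eps
        ssc = StressStrainCurve(eps, sig, area=1, height=1)
        m0, _ = red.elastic_modulus(ssc, window=(0.05, 0.35))
        shifted = StressStrainCurve(eps, sig + 0.3, area=1, height=1)
        m1, _ = red.elastic_modulus(shifted, window=(0.05, 0.35))
        scaled = StressStrainCurve(eps, 7 * sig, area=1, height=1)
        m2, _ = red.elastic_modulus(scaled, window=(0.05, 0.35))
        assert m1 == pytest.approx(m0, rel=1e-9)
        assert m2 == pytest.approx(7 * m0, rel=1e-9)

    def test_window_errors(self):
        eps = np.linspace(0, 0.2, 50)
        ssc = StressStrainCurve(eps, eps, area=1, height=1)
        with pytest.raises(ValueError):
            red.elastic_modulus(ssc, window=(0.5, 0.8))  # outside data
        with pytest.raises(ValueError):
            red.elastic_modulus(ssc, window=(0.199, 0.2))  # < 5 points


class TestStrengthAndInterpolation:
    def test_strength_on_a_line(self):
        eps = np.linspace(0, 0.4, 200)
        ssc = StressStrainCurve(eps, 0.5 * eps, area=1, height=1)
        assert red.compressive_strength(ssc) == pytest.approx(0.10, rel=1e-12)

    def test_midpoint_interpolation(self):
        ssc = StressStrainCurve(
            np.array([0.0, 0.19, 0.21]), np.array([0.0, 0.09, 0.11]), 1, 1
        )
        assert red.compressive_strength(ssc) == pytest.approx(0.10)

    def test_truncated_curve_gives_absent(self):
        eps = np.linspace(0, 0.15, 50)
        ssc = StressStrainCurve(eps, eps, area=1, height=1)
        assert red.compressive_strength(ssc) is None

    def test_knot_exactness(self):
        eps = np.array([0.0, 0.1, 0.37, 0.5])
        sig = np.array([0.0, 0.03, 0.21, 0.5])
        ssc = StressStrainCurve(eps, sig, area=1, height=1)
        for e, s in zip(eps, sig):
            assert red.stress_at_strain(ssc, e) == pytest.approx(s, rel=1e-15)

    def test_stress_at_half_strain(self):
        eps = np.linspace(0, 0.6, 100)
        ssc = StressStrainCurve(eps, 0.4 * eps, area=1, height=1)
        assert red.stress_at_strain(ssc, 0.5) == pytest.approx(0.2, rel=1e-12)
        short = StressStrainCurve(eps[:50], 0.4 * eps[:50], 1, 1)
        assert red.stress_at_strain(short, 0.5) is None


class TestRecoverySplit:
    def test_fully_elastic(self):
        g = SpecimenGeometry(diameter=70, height=65, post_test_height=65)
        c = make_curve([0, 26], [0, 100], g)
        assert red.recovery_split(c) == (0.0, pytest.approx(0.4))

    def test_partial_recovery(self):
        g = SpecimenGeometry(diameter=70, height=65, post_test_height=52)
        c = make_curve([0, 32.5], [0, 100], g)
        plastic, rec = red.recovery_split(c)
        assert plastic == pytest.approx(0.2)
        assert rec == pytest.approx(0.3)

    def test_impossible_recovery_clipped_with_warning(self):
        g = SpecimenGeometry(diameter=70, height=65, post_test_height=20)
        c = make_curve([0, 13], [0, 100], g)  # eps_max = 0.2 but plastic 0.69
        with pytest.warns(UserWarning):
            plastic, rec = red.recovery_split(c)
        assert rec == 0.0

    def test_post_height_above_initial_rejected(self):
        with pytest.raises(ValueError):
            SpecimenGeometry(diameter=70, height=65, post_test_height=66)


class TestMeanCurve:
    def test_identical_replicates_zero_band(self):
        eps = np.linspace(0, 0.5, 60)
        reps = [StressStrainCurve(eps, eps**2, 1, 1) for _ in range(4)]
        mc = red.mean_curve(reps)
        assert np.all(mc.ci_halfwidth == pytest.approx(0.0, abs=1e-15))

    def test_two_replicate_t_band(self):
        from scipy import stats

        eps = np.linspace(0, 0.5, 60)
        reps = [
            StressStrainCurve(eps, 1.0 * eps, 1, 1),
            StressStrainCurve(eps, 3.0 * eps, 1, 1),
        ]
        mc = red.mean_curve(reps)
        np.testing.assert_allclose(mc.mean_stress, 2 * mc.strain, atol=1e-14)
        sd = np.std([mc.strain, 3 * mc.strain], axis=0, ddof=1)
        expected = stats.t.ppf(0.975, df=1) * sd / math.sqrt(2)
        np.testing.assert_allclose(mc.ci_halfwidth, expected, atol=1e-12)

    def test_grid_respects_shortest_replicate(self):
        r1 = StressStrainCurve(np.linspace(0, 0.5, 50), np.ones(50), 1, 1)
        r2 = StressStrainCurve(np.linspace(0, 0.3, 50), np.ones(50), 1, 1)
        mc = red.mean_curve([r1, r2])
        assert mc.strain[-1] == pytest.approx(0.3)

    def test_single_replicate_rejected(self):
        r = StressStrainCurve(np.linspace(0, 0.5, 50), np.ones(50), 1, 1)
        with pytest.raises(ValueError):
            red.mean_curve([r])


class TestFileReading:
    @pytest.mark.parametrize(
        "text",
        [
            "displacement_mm,force_N\n0,0\n1,10\n2,20\n",
            "displacement_mm;force_N\n0;0\n1;10\n2;20\n",
            "displacement_mm\tforce_N\n0\t0\n1\t10\n2\t20\n",
            "displacement_mm;force_N\n0,0;0,0\n1,0;10,0\n2,0;20,0\n",  # decimal comma
            "0,0\n1,10\n2,20\n",  # headerless two-column
        ],
        ids=["comma", "semicolon", "tab", "decimal-comma", "headerless"],
    )
    def test_dialects(self, tmp_path, standard_geometry, text):
        f = tmp_path / "rec.csv"
        f.write_text(text)
        c = red.read_load_displacement(f, standard_geometry)
        np.testing.assert_allclose(c.displacement, [0, 1, 2])
        np.testing.assert_allclose(c.force, [0, 10, 20])

    def test_missing_columns_rejected(self, tmp_path, standard_geometry):
        f = tmp_path / "bad.csv"
        f.write_text("a,b,c\n1,2,3\n4,5,6\n")
        with pytest.raises(ValueError, match="columns"):
            red.read_load_displacement(f, standard_geometry)


class TestCurveValidation:
    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            SpecimenGeometry(diameter=0, height=65)
        with pytest.raises(ValueError):
            SpecimenGeometry(diameter=70, height=65, slant_deg=15)

    def test_non_monotone_displacement_rejected(self, standard_geometry):
        with pytest.raises(ValueError):
            make_curve([0, 2, 1], [0, 1, 2], standard_geometry)

    def test_non_finite_force_rejected(self, standard_geometry):
        with pytest.raises(ValueError):
            make_curve([0, 1], [0, np.nan], standard_geometry)
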