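"""Constitutive model: closed form, oracle agreement, linearization, fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mycomech import neohooke as nh
from mycomech.neohooke import NeoHookeParams


def random_params(rng, n):
    c = 10.0 ** rng.uniform(-3, 1, n)
    d = 10.0 ** rng.uniform(-3, 1, n)
    return [NeoHookeParams(ci, di) for ci, di in zip(c, d)]


class TestStrainEnergy:
    def test_zero_at_identity(self):
        assert nh.strain_energy(1, 1, 1, NeoHookeParams(0.3, 0.7)) == 0.0

    def test_hand_computed_value(self):
        # w(2,1,1) with c = d = 1: (4+1+1-3-2 ln 2) + (2-1)^2 = 4 - 2 ln 2
        w = nh.strain_energy(2, 1, 1, NeoHookeParams(1, 1))
        assert w == pytest.approx(4 - 2 * math.log(2), rel=1e-12)

    def test_permutation_invariance(self, rng):
        p = NeoHookeParams(0.2, 0.9)
        for a, b, c in rng.uniform(0.5, 2.0, size=(20, 3)):
            w1 = nh.strain_energy(a, b, c, p)
            w2 = nh.strain_energy(b, a, c, p)
            w3 = nh.strain_energy(c, b, a, p)
            assert w1 == pytest.approx(w2, rel=1e-12)
            assert w1 == pytest.approx(w3, rel=1e-12)

    def test_nonnegative_over_sampled_domain(self, rng):
        for p in random_params(rng, 10):
            stretches = rng.uniform(0.3, 3.0, size=(200, 3))
            w = nh.strain_energy(*stretches.T, p)
            assert np.all(w >= -1e-14)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(ValueError):
            nh.strain_energy(0.0, 1, 1, NeoHookeParams(1, 1))


class TestLateralSolution:
    def test_identity_is_stress_free(self, rng):
        for p in random_params(rng, 50):
            J, psi = nh.lateral_solution(1.0, p)
            assert J == pytest.approx(1.0, abs=1e-13)
            assert psi == pytest.approx(2.0, abs=1e-13)

    def test_published_form_breaks_identity(self):
        # the plus-sign variant does not satisfy psi(1) = 2, hence S33(1) != 0
        p = NeoHookeParams(0.1, 0.1)
        _, psi = nh.lateral_solution(1.0, p, as_published=True)
        assert abs(psi - 2.0) > 0.5
        s = nh.uniaxial_stress(1.0, p, as_published=True)
        assert abs(s) > 1e-3

    def test_matches_generic_quadratic_solver(self):
        # J solves d J^2 + (c/lam - d) J - c = 0
        for lam in (0.6, 0.8, 0.95):
            p = NeoHookeParams(0.07, 0.07)
            J, _ = nh.lateral_solution(lam, p)
            roots = np.roots([p.d, p.c / lam - p.d, -p.c])
            pos = roots[roots > 0]
            assert len(pos) == 1
            assert J == pytest.approx(float(pos[0]), rel=1e-12)

    def test_psi_satisfies_quadratic(self, rng):
        for p in random_params(rng, 20):
            for lam in rng.uniform(0.4, 1.0, 5):
                _, psi = nh.lateral_solution(lam, p)
                r = p.c / p.d
                resid = psi**2 + (2 * r - 2 * lam) * psi - 4 * lam**2 * r
                assert abs(resid) < 1e-9 * max(psi**2, 1.0)

    def test_incompressible_limit(self):
        p = NeoHookeParams(1e-6, 1.0)  # d/c = 1e6
        lam = np.linspace(0.5, 1.0, 20)
        J, _ = nh.lateral_solution(lam, p)
        assert np.all(np.abs(J - 1.0) < 1e-3)


class TestUniaxialStress:
    def test_zero_at_identity(self, rng):
        for p in random_params(rng, 20):
            assert nh.uniaxial_stress(1.0, p) == pytest.approx(0.0, abs=1e-14)

    def test_compressive_sign(self):
        p = NeoHookeParams(0.1, 0.2)
        lam = np.linspace(0.4, 0.99, 30)
        assert np.all(nh.uniaxial_stress(lam, p) < 0)

    def test_nominal_is_lambda_times_s33(self):
        p = NeoHookeParams(0.3, 0.1)
        lam = np.linspace(0.5, 0.99, 7)
        np.testing.assert_allclose(
            nh.uniaxial_stress(lam, p, "nominal"),
            lam * nh.uniaxial_stress(lam, p),
            rtol=1e-14,
        )

    @pytest.mark.parametrize("ratio", [0.01, 0.1, 1.0, 10.0, 100.0])
    def test_matches_brute_force_oracle(self, ratio):
        p = NeoHookeParams(ratio * 0.05, 0.05)
        for lam in np.linspace(0.5, 0.99, 6):
            closed = nh.uniaxial_stress(lam, p)
            brute = nh.brute_force_stress(lam, p)
            assert closed == pytest.approx(brute, rel=1e-8)

    def test_oracle_lateral_stretch_consistency(self):
        # the energy stationary point q satisfies q^2 = J / lam
        from scipy import optimize

        p = NeoHookeParams(0.08, 0.03)
        lam = 0.7
        J, _ = nh.lateral_solution(lam, p)

        def dw_dq(q):
            h = 1e-6 * q
            return float(
                nh.strain_energy(q + h, q + h, lam, p)
                - nh.strain_energy(q - h, q - h, lam, p)
            ) / (2 * h)

        q = optimize.brentq(dw_dq, 0.8, 1.5, xtol=1e-14, rtol=1e-15)
        assert q**2 == pytest.approx(J / lam, abs=1e-10)

    def test_magnitude_increases_with_compression(self, rng):
        lam = np.linspace(0.41, 0.999, 200)
        for p in random_params(rng, 10):
            mag = np.abs(nh.uniaxial_stress(lam, p))
            assert np.all(np.diff(mag) < 0)  # |S33| grows as lam drops

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        lam=st.floats(0.4, 0.999),
        c=st.floats(1e-3, 10.0),
        d=st.floats(1e-3, 10.0),
    )
    def test_compression_always_gives_negative_stress(self, lam, c, d):
        assert nh.uniaxial_stress(lam, NeoHookeParams(c, d)) < 0


class TestSmallStrainModuli:
    def test_formula_example(self):
        E, nu = nh.small_strain_moduli(NeoHookeParams(1, 1))
        assert E == pytest.approx(5.0)
        assert nu == pytest.approx(0.25)

    def test_incompressible_and_compressible_limits(self):
        E, nu = nh.small_strain_moduli(NeoHookeParams(1.0, 1e8))
        assert nu == pytest.approx(0.5, abs=1e-7)
        assert E == pytest.approx(6.0, rel=1e-7)  # E -> 3 mu, mu = 2c
        E, nu = nh.small_strain_moduli(NeoHookeParams(1.0, 1e-8))
        assert nu == pytest.approx(0.0, abs=1e-7)
        assert E == pytest.approx(4.0, rel=1e-7)  # E -> 2 mu

    def test_poisson_ratio_range(self, rng):
        for p in random_params(rng, 100):
            _, nu = nh.small_strain_moduli(p)
            assert 0.0 < nu < 0.5

    def test_stress_slope_at_identity(self, rng):
        # dS33/dlam at identity equals the Young modulus 2c(2c+3d)/(c+d)
        h = 1e-6
        for p in random_params(rng, 10):
            num = (nh.uniaxial_stress(1 + h, p) - nh.uniaxial_stress(1 - h, p)) / (
                2 * h
            )
            E, _ = nh.small_strain_moduli(p)
            assert num == pytest.approx(E, rel=1e-6)


class TestFit:
    @staticmethod
    def _curve(params, eps_max=0.4, n=200, interpretation="nominal"):
        eps = np.linspace(0.0, eps_max, n)
        lam = 1.0 - eps
        sig = np.abs(
            nh.uniaxial_stress(np.maximum(lam, 1e-6), params, interpretation)
        )
        return eps, sig

    def test_noiseless_self_consistency(self):
        truth = NeoHookeParams(0.05, 0.08)
        eps, sig = self._curve(truth)
        fit = nh.fit_parameters(eps, sig, interpretation="nominal")
        assert fit.success
        assert fit.params.c == pytest.approx(truth.c, rel=1e-6)
        assert fit.params.d == pytest.approx(truth.d, rel=1e-6)

    def test_second_piola_interpretation_self_consistency(self):
        truth = NeoHookeParams(0.12, 0.04)
        eps, sig = self._curve(truth, interpretation="second_piola")
        fit = nh.fit_parameters(eps, sig, interpretation="second_piola")
        assert fit.params.c == pytest.approx(truth.c, rel=1e-6)
        assert fit.params.d == pytest.approx(truth.d, rel=1e-6)

    def test_all_zero_stress_rejected(self):
        eps = np.linspace(0, 0.3, 50)
        with pytest.raises(ValueError):
            nh.fit_parameters(eps, np.zeros_like(eps))

    def test_non_monotone_strain_rejected(self):
        eps = np.array([0, 0.1, 0.05, 0.2, 0.3])
        with pytest.raises(ValueError):
            nh.fit_parameters(eps, np.ones_like(eps))

    def test_short_span_rejected(self):
        eps = np.linspace(0, 0.01, 50)
        with pytest.raises(ValueError):
            nh.fit_parameters(eps, eps)

    def test_identifiability_jacobian_full_rank(self):
        # the residual Jacobian in log-parameters has rank 2 at the optimum
        truth = NeoHookeParams(0.05, 0.05)
        eps, sig = self._curve(truth, eps_max=0.4)
        lam = 1.0 - eps

        def resid(logc, logd):
            p = NeoHookeParams(math.exp(logc), math.exp(logd))
            return np.abs(nh.uniaxial_stress(lam, p, "nominal")) - sig

        h = 1e-6
        l0 = (math.log(truth.c), math.log(truth.d))
        Jc = (resid(l0[0] + h, l0[1]) - resid(l0[0] - h, l0[1])) / (2 * h)
        Jd = (resid(l0[0], l0[1] + h) - resid(l0[0], l0[1] - h)) / (2 * h)
        s = np.linalg.svd(np.column_stack([Jc, Jd]), compute_uv=False)
        assert s[1] / s[0] > 1e-4


class TestParams:
    @pytest.mark.parametrize("c,d", [(0, 1), (-1, 1), (1, 0), (1, -2), (np.inf, 1)])
    def test_invalid_rejected(self, c, d):
        with pytest.raises(ValueError):
            NeoHookeParams(c, d)

    def test_json_roundtrip_full_precision(self):
        p = NeoHookeParams(0.05000000001234, 1.7e-3)
        q = NeoHookeParams.from_json(p.to_json())
        assert q.c == p.c and q.d == p.d
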