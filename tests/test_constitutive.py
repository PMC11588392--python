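"""Constitutive layer: fiber geometry, energies, stresses, invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.spatial.transform import Rotation

import fetmem as fm
from fetmem.constitutive import (AmnionMaterial, energy_breakdown,
                                 cauchy_stress_amnion, cauchy_stress_isotropic,
                                 g3_stability_check, material_kernel)
from fetmem.errors import (ParameterError, StabilityControlError,
                           ValidationError)

from oracles import amnion_energy_brute, eig_charpoly_max


# ---------------------------------------------------------------------------
# fiber directions


class TestFiberDirections:
    def test_n4_hand_values(self):
        fs = fm.build_fiber_directions(4, 0.0)
        c = np.cos(np.pi / 4)
        expect = np.array([[c, -c, 0], [c, c, 0], [c, -c, 0], [c, c, 0]])
        np.testing.assert_allclose(fs.directions, expect, atol=1e-15)

    def test_in_plane_when_no_inclination(self):
        fs = fm.build_fiber_directions(32, 0.0)
        assert fs.directions.shape == (32, 3)
        assert np.all(fs.directions[:, 2] == 0.0)

    def test_off_plane_component_is_sin_phi(self):
        fs = fm.build_fiber_directions(32, 10.0)
        np.testing.assert_allclose(np.abs(fs.directions[:, 2]),
                                   np.sin(np.deg2rad(10.0)), rtol=1e-14)

    def test_pairs_mirror_through_plane(self):
        fs = fm.build_fiber_directions(8, 25.0)
        up, down = fs.directions[:4], fs.directions[4:]
        np.testing.assert_allclose(up[:, :2], down[:, :2], atol=1e-15)
        np.testing.assert_allclose(up[:, 2], -down[:, 2], atol=1e-15)

    @given(st.integers(1, 40), st.floats(0.0, 89.0))
    def test_unit_norm_property(self, half, phi):
        fs = fm.build_fiber_directions(2 * half, phi)
        np.testing.assert_allclose(np.linalg.norm(fs.directions, axis=1),
                                   1.0, rtol=1e-12)

    @pytest.mark.parametrize("bad_n", [0, 3, 7, -2])
    def test_rejects_bad_counts(self, bad_n):
        with pytest.raises(ParameterError):
            fm.build_fiber_directions(bad_n, 0.0)

    def test_rejects_bad_angle(self):
        with pytest.raises(ParameterError):
            fm.build_fiber_directions(4, 90.0)


class TestFiberStretches:
    def test_identity_and_axis_aligned(self):
        fs = fm.build_fiber_directions(8, 0.0)
        np.testing.assert_allclose(fm.fiber_stretches(np.eye(3), fs), 1.0)
        fs1 = fm.FiberSet(directions=np.array([[1.0, 0, 0]]),
                          betas=np.zeros(1), thetas=np.zeros(1))
        lam = fm.fiber_stretches(np.diag([1.5, 1.0, 1.0]), fs1)
        assert lam[0] == pytest.approx(1.5)

    def test_matches_matrix_vector_oracle(self, rng):
        fs = fm.build_fiber_directions(32, 12.0)
        for _ in range(5):
            F = np.eye(3) + 0.3 * (rng.random((3, 3)) - 0.5)
            if np.linalg.det(F) <= 0.2:
                continue
            lam = fm.fiber_stretches(F, fs)
            brute = [np.sqrt(sum((sum(F[i, k] * M[k] for k in range(3))) ** 2
                                 for i in range(3))) for M in fs.directions]
            np.testing.assert_allclose(lam, brute, rtol=1e-12)


# ---------------------------------------------------------------------------
# energy


class TestEnergyBreakdown:
    def test_zero_at_identity(self, amnion):
        eb = energy_breakdown(np.eye(3), amnion)
        assert eb.psi == 0.0 and eb.g2 == 0.0 and eb.g3 == 0.0

    def test_compressed_fibers_do_not_contribute(self, amnion):
        eb = energy_breakdown(np.diag([0.9, 1.0, 1.0]), amnion)
        # every in-plane fiber has stretch <= 1 under uniaxial compression
        assert eb.g3 == 0.0

    def test_matches_brute_force_summation(self, amnion, rng):
        for _ in range(10):
            F = np.eye(3) + 0.15 * (rng.random((3, 3)) - 0.5)
            if np.linalg.det(F) <= 0.3:
                continue
            eb = energy_breakdown(F, amnion)
            psi_b, g2_b, g3_b = amnion_energy_brute(
                F, amnion.mu0_kpa, amnion.q, amnion.m2, amnion.m3, amnion.m4,
                amnion.m5, amnion.n_fibers, amnion.phi_deg)
            assert eb.psi == pytest.approx(psi_b, rel=1e-10)
            assert eb.g2 == pytest.approx(g2_b, rel=1e-10, abs=1e-14)
            assert eb.g3 == pytest.approx(g3_b, rel=1e-10, abs=1e-14)

    def test_table1_example_value(self, amnion):
        eb = energy_breakdown(np.diag([1.1, 1.0, 1.0]), amnion)
        psi_b, _, _ = amnion_energy_brute(
            np.diag([1.1, 1.0, 1.0]), 2400.0, 2.96, 0.00228, 41.12, 1.27,
            0.463, 32, 0.0)
        assert eb.psi == pytest.approx(psi_b, rel=1e-10)

    def test_objectivity_under_rotations(self, amnion, rng):
        fs = fm.build_fiber_directions(amnion.n_fibers, amnion.phi_deg)
        F = np.diag([1.15, 0.95, 0.98])
        psi0 = energy_breakdown(F, amnion, fs).psi
        rots = Rotation.random(50, random_state=np.random.RandomState(7))
        for Q in rots.as_matrix():
            psi = energy_breakdown(Q @ F, amnion, fs).psi
            assert psi == pytest.approx(psi0, rel=1e-10)

    def test_g3_monotone_in_fiber_stretch(self, amnion):
        kern = AmnionMaterial(amnion)
        lams = np.linspace(1.0, 1.4, 30)
        g3 = kern.g3(lams, lams, np.ones_like(lams))
        assert np.all(np.diff(g3) > 0)

    def test_stability_cap_raises(self, amnion):
        import dataclasses
        tight = dataclasses.replace(amnion, g3_cap=1e-6)
        with pytest.raises(StabilityControlError):
            energy_breakdown(np.diag([1.3, 1.0, 1.0]), tight)


class TestStabilityCheck:
    def test_pass_retry_signals(self):
        assert g3_stability_check(0.0, 50.0)
        assert not g3_stability_check(50.5, 50.0)
        with pytest.raises(ParameterError):
            g3_stability_check(1.0, 0.0)


# ---------------------------------------------------------------------------
# stress


class TestCauchyStress:
    def test_stress_free_reference_both_laws(self, amnion, chorion):
        assert np.all(cauchy_stress_amnion(np.eye(3), amnion).sigma == 0.0)
        assert np.all(cauchy_stress_isotropic(np.eye(3), chorion).sigma == 0.0)

    def test_amnion_matches_finite_difference_oracle(self, amnion, rng):
        fs = fm.build_fiber_directions(amnion.n_fibers, amnion.phi_deg)
        checked = 0
        while checked < 20:
            F = np.eye(3) + 0.2 * (rng.random((3, 3)) - 0.5)
            if np.linalg.det(F) <= 0.3:
                continue
            sig = cauchy_stress_amnion(F, amnion, fs).sigma
            h = 1e-6
            P = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fmn = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fmn[i, j] -= h
                    P[i, j] = (energy_breakdown(Fp, amnion, fs).psi
                               - energy_breakdown(Fmn, amnion, fs).psi) / (2 * h)
            sig_fd = P @ F.T / np.linalg.det(F)
            sig_fd = 0.5 * (sig_fd + sig_fd.T)
            np.testing.assert_allclose(sig, sig_fd, rtol=1e-6,
                                       atol=1e-6 * max(1.0, np.abs(sig).max()))
            checked += 1

    def test_amnion_symmetry(self, amnion, rng):
        F = np.eye(3) + 0.2 * (rng.random((3, 3)) - 0.5)
        sig = cauchy_stress_amnion(F, amnion).sigma
        np.testing.assert_allclose(sig, sig.T, atol=1e-10 * np.abs(sig).max())

    def test_isotropic_recovers_hookes_law(self, chorion, rng):
        mu, la = chorion.shear_kpa, chorion.lame_kpa
        eps_mag = 1e-6
        strain = eps_mag * (rng.random((3, 3)) - 0.5)
        strain = 0.5 * (strain + strain.T)
        F = np.eye(3) + strain
        sig = cauchy_stress_isotropic(F, chorion).sigma
        hooke = la * np.trace(strain) * np.eye(3) + 2.0 * mu * strain
        np.testing.assert_allclose(sig, hooke, atol=50.0 * eps_mag ** 2 * (mu + la))

    def test_isotropic_uniaxial_modulus(self):
        par = fm.IsotropicLayerParameters(E=1.0, nu=0.49)
        eps = 1e-5
        F = np.diag([1 + eps, 1 - par.nu * eps, 1 - par.nu * eps])
        sig = cauchy_stress_isotropic(F, par).sigma
        assert sig[0, 0] / eps == pytest.approx(1000.0, rel=1e-3)

    def test_incompressible_limit_rejected(self):
        with pytest.raises(ParameterError):
            fm.IsotropicLayerParameters(E=1.0, nu=0.5)


class TestMembraneTension:
    def test_hand_arithmetic(self):
        assert fm.membrane_tension(0.0, 0.062, 1.0, 1.0) == 0.0
        assert fm.membrane_tension(1000.0, 0.062, 1.0, 1.0) == pytest.approx(0.062)

    @given(st.floats(0.5, 2.0), st.floats(0.5, 2.0),
           st.floats(-500.0, 500.0), st.floats(0.01, 1.0))
    def test_quartering_homogeneity(self, l1, l2, sig, h0):
        t = fm.membrane_tension(sig, h0, l1, l2)
        t2 = fm.membrane_tension(sig, h0, 2 * l1, 2 * l2)
        assert t2 == pytest.approx(t / 4.0, rel=1e-12, abs=1e-15)

    def test_rejects_nonpositive_stretch(self):
        with pytest.raises(ParameterError):
            fm.membrane_tension(1.0, 0.062, 0.0, 1.0)


class TestMaxPrincipalStress:
    def test_diagonal_and_zero(self):
        assert fm.max_principal_stress(np.diag([3.0, 2.0, 1.0])) == 3.0
        assert fm.max_principal_stress(np.zeros((3, 3))) == 0.0

    def test_matches_charpoly_oracle(self, rng):
        for _ in range(10):
            A = rng.random((3, 3)) - 0.5
            A = A + A.T
            assert fm.max_principal_stress(A) == pytest.approx(
                eig_charpoly_max(A), rel=1e-8, abs=1e-8)

    def test_rejects_asymmetric(self):
        bad = np.array([[0.0, 1.0, 0], [0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValidationError):
            fm.max_principal_stress(bad)


# ---------------------------------------------------------------------------
# vectorized kernels vs the tensor-valued API


class TestKernelConsistency:
    def test_sigma_diag_matches_full_tensor_path(self, amnion, chorion):
        for params, full in ((amnion, cauchy_stress_amnion),
                             (chorion, cauchy_stress_isotropic)):
            kern = material_kernel(params)
            for l1, l2, l3 in [(1.2, 1.1, 0.9), (1.05, 0.95, 1.02),
                               (1.4, 0.6, 1.3)]:
                s = kern.sigma_diag(l1, l2, l3)
                ref = full(np.diag([l1, l2, l3]), params).sigma
                np.testing.assert_allclose(
                    [float(s[0]), float(s[1]), float(s[2])],
                    np.diag(ref), rtol=1e-9, atol=1e-9)

    def test_planestress_thickness_zeroes_sigma33(self, amnion, chorion):
        for params in (amnion, chorion):
            kern = material_kernel(params)
            l1 = np.array([1.05, 1.2, 1.35])
            l2 = np.array([1.02, 1.15, 1.25])
            l3 = kern.thickness_stretch(l1, l2)
            s33 = kern.sigma_diag(l1, l2, l3)[2]
            assert np.max(np.abs(s33)) < 1e-6 * 1000.0
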