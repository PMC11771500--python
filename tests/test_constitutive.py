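"""Strain energy, stress and uniaxial response of the material models."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from aussim.constitutive import (
    DeformationState,
    InvalidDeformationError,
    LinearElasticMaterial,
    NeoHookeanMaterial,
    OgdenMaterial,
    cauchy_stress,
    strain_energy,
    uniaxial_deformation_gradient,
    uniaxial_nominal_stress,
)


def random_isochoric_F(rng, scale=0.3):
    """Random deformation gradient with det F = 1."""

    F = np.eye(3) + scale * rng.standard_normal((3, 3))
    d = np.linalg.det(F)
    if d <= 0:
        F = -F if np.linalg.det(-F) > 0 else np.eye(3)
        d = np.linalg.det(F)
    return F / d ** (1.0 / 3.0)


class TestMaterialValidation:
    def test_rejects_nonpositive_modulus(self):
        with pytest.raises(ValueError):
            OgdenMaterial(mu=-1.0, alpha=6.178)
        with pytest.raises(ValueError):
            NeoHookeanMaterial(mu=0.0)

    def test_rejects_zero_alpha_and_bad_poisson(self):
        with pytest.raises(ValueError):
            OgdenMaterial(mu=1.0, alpha=0.0)
        with pytest.raises(ValueError):
            LinearElasticMaterial(E=100.0, nu=0.5)

    def test_rejects_singular_or_nonfinite_F(self):
        mat = OgdenMaterial(20.0, 6.178)
        with pytest.raises(InvalidDeformationError):
            strain_energy(mat, np.zeros((3, 3)))
        with pytest.raises(InvalidDeformationError):
            strain_energy(mat, np.full((3, 3), np.nan))


class TestStrainEnergy:
    def test_zero_at_reference(self):
        mat = OgdenMaterial(20.0, 6.178)
        assert strain_energy(mat, np.eye(3)) == 0.0

    def test_positive_away_from_reference(self):
        mat = OgdenMaterial(20.0, 6.178)
        rng = np.random.default_rng(0)
        for _ in range(20):
            F = random_isochoric_F(rng)
            if not np.allclose(F, np.eye(3)):
                assert strain_energy(mat, F) > 0.0

    def test_uniaxial_energy_equals_integrated_stress_work(self):
        # W(1.2) must equal the work of the nominal stress along the
        # incompressible uniaxial path, by work conjugacy
        mat = OgdenMaterial(20.0, 6.178)
        lam_end = 1.2
        lam = np.linspace(1.0, lam_end, 2001)
        work = np.trapezoid(uniaxial_nominal_stress(mat, lam), lam)
        W = strain_energy(mat, uniaxial_deformation_gradient(lam_end))
        assert W > 0.0
        assert W == pytest.approx(work, rel=1e-6)

    def test_alpha_two_is_neo_hookean(self):
        rng = np.random.default_rng(1)
        mu = 3.7
        for _ in range(10):
            F = random_isochoric_F(rng)
            lam2 = np.linalg.eigvalsh(F.T @ F)
            expected = 0.5 * mu * (lam2.sum() - 3.0)
            assert strain_energy(OgdenMaterial(mu, 2.0), F) == pytest.approx(
                expected, rel=1e-12)
            assert strain_energy(NeoHookeanMaterial(mu), F) == pytest.approx(
                expected, rel=1e-12)

    def test_frame_indifference_and_isotropy(self):
        mat = OgdenMaterial(20.0, 6.178)
        rng = np.random.default_rng(2)
        for _ in range(10):
            F = random_isochoric_F(rng)
            Q = Rotation.random(rng=np.random.default_rng(rng.integers(2**31))).as_matrix()
            W = strain_energy(mat, F)
            assert strain_energy(mat, Q @ F) == pytest.approx(W, rel=1e-10)
            assert strain_energy(mat, F @ Q) == pytest.approx(W, rel=1e-10)


class TestCauchyStress:
    def test_zero_at_reference_and_pure_pressure(self):
        mat = OgdenMaterial(20.0, 6.178)
        assert np.allclose(cauchy_stress(mat, np.eye(3)), 0.0)
        state = DeformationState(np.eye(3), p=5.0)
        assert np.allclose(cauchy_stress(mat, state), -5.0 * np.eye(3))

    def test_symmetry_and_objectivity(self):
        mat = OgdenMaterial(20.0, 6.178)
        rng = np.random.default_rng(3)
        for _ in range(5):
            F = random_isochoric_F(rng)
            s = cauchy_stress(mat, F)
            assert np.allclose(s, s.T)
            Q = Rotation.random(rng=np.random.default_rng(rng.integers(2**31))).as_matrix()
            assert np.allclose(cauchy_stress(mat, Q @ F), Q @ s @ Q.T, atol=1e-9)

    @pytest.mark.parametrize("mat", [
        OgdenMaterial(20.0, 6.178), OgdenMaterial(1.1, 6.178),
        NeoHookeanMaterial(5.0),
    ], ids=["lining", "spongiosum", "rubber"])
    def test_work_conjugacy_with_finite_differences(self, mat):
        # analytic first Piola P = J sigma F^{-T} must match the central
        # finite difference of the strain energy for random states
        rng = np.random.default_rng(4)
        h = 1e-6
        for _ in range(100):
            F = random_isochoric_F(rng, scale=0.2)
            sigma = cauchy_stress(mat, F)
            J = np.linalg.det(F)
            P = J * sigma @ np.linalg.inv(F).T
            P_fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P_fd[i, j] = (strain_energy(mat, Fp) - strain_energy(mat, Fm)) / (2 * h)
            scale = max(np.abs(P_fd).max(), 1.0)
            assert np.abs(P - P_fd).max() / scale < 1e-6

    def test_neo_hookean_stress_matches_ogden_alpha_two(self):
        rng = np.random.default_rng(5)
        for _ in range(5):
            F = random_isochoric_F(rng)
            s1 = cauchy_stress(OgdenMaterial(4.2, 2.0), F)
            s2 = cauchy_stress(NeoHookeanMaterial(4.2), F)
            assert np.allclose(s1, s2, rtol=1e-14, atol=1e-14)

    def test_titanium_linear_elasticity_units(self):
        ti = LinearElasticMaterial(E=114000.0, nu=0.315)
        eps = 1e-4
        F = np.eye(3)
        F[0, 0] += eps
        s = cauchy_stress(ti, F)
        # uniaxial strain state: sigma_xx = (lam + 2 mu) * eps, in kPa
        expected = (ti.lame_lambda_kPa + 2 * ti.shear_modulus_kPa) * eps
        assert s[0, 0] == pytest.approx(expected, rel=1e-9)


class TestUniaxialNominalStress:
    def test_reference_and_neo_hookean_closed_form(self):
        assert uniaxial_nominal_stress(OgdenMaterial(20.0, 6.178), 1.0) == pytest.approx(0.0)
        # mu (lam - lam^-2) at mu=1, lam=2 -> 1.75
        assert uniaxial_nominal_stress(OgdenMaterial(1.0, 2.0), 2.0) == pytest.approx(1.75)

    def test_printed_lining_point_against_energy_derivative(self):
        mat = OgdenMaterial(20.0, 6.178)
        lam = 1.2
        h = 1e-6
        dW = (strain_energy(mat, uniaxial_deformation_gradient(lam + h))
              - strain_energy(mat, uniaxial_deformation_gradient(lam - h))) / (2 * h)
        P = uniaxial_nominal_stress(mat, lam)
        assert P == pytest.approx(dW, rel=1e-8)
        assert P == pytest.approx(13.57, abs=0.01)

    @pytest.mark.parametrize("mu", [20.0, 1.1], ids=["lining", "spongiosum"])
    def test_strictly_increasing_for_tissue_parameters(self, mu):
        lam = np.linspace(1.0, 1.6, 200)
        P = uniaxial_nominal_stress(OgdenMaterial(mu, 6.178), lam)
        assert np.all(np.diff(P) > 0.0)
        assert np.all(np.sign(P[1:]) == 1.0)

    def test_compression_sign_and_domain_error(self):
        mat = OgdenMaterial(20.0, 6.178)
        assert uniaxial_nominal_stress(mat, 0.8) < 0.0
        with pytest.raises(ValueError):
            uniaxial_nominal_stress(mat, 0.0)
        with pytest.raises(ValueError):
            uniaxial_nominal_stress(mat, -1.0)
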