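"""Hyperelastic and elastic material models for tissue and device components.

The urethral wall is modelled as an isotropic, nearly incompressible
hyperelastic solid.  Both tissue layers (the thin dense-connective lining
around the lumen and the thick spongiosum stratum) use a one-term Ogden
strain-energy function written on the isochoric principal stretches

    W_iso = (2 mu / alpha^2) * (lb1^alpha + lb2^alpha + lb3^alpha - 3),

with ``lb_i = J**(-1/3) * lambda_i``.  In this convention ``mu`` is the
small-strain shear modulus and ``alpha`` controls the strain-stiffening
typical of soft tissue; ``alpha = 2`` recovers the neo-Hookean model.
Incompressibility is enforced weakly through a volumetric penalty

    W_vol = kappa / 2 * (J - 1)^2,    kappa = bulk_factor * mu,

so the total strain energy is ``W = W_iso + W_vol``.

Units are a consistent mm--kPa system (stresses in kPa, lengths in mm,
forces per unit thickness in mN/mm).  The titanium device body is described
by a small-strain linear elastic law whose Young modulus is given in MPa
and converted to kPa internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DEFAULT_BULK_FACTOR",
    "InvalidDeformationError",
    "OgdenMaterial",
    "NeoHookeanMaterial",
    "LinearElasticMaterial",
    "DeformationState",
    "principal_stretches",
    "strain_energy",
    "cauchy_stress",
    "uniaxial_nominal_stress",
]

#: Default ratio kappa/mu of the volumetric penalty (near-incompressibility).
DEFAULT_BULK_FACTOR = 1000.0


class InvalidDeformationError(ValueError):
    """Raised for non-finite, singular or inverted deformation gradients."""


def _finite_positive(name: str, value: float) -> None:
    if not (np.isfinite(value) and value > 0.0):
        raise ValueError(f"{name} must be finite and positive, got {value!r}")


@dataclass(frozen=True)
class OgdenMaterial:
    """One-term Ogden material.

    Parameters
    ----------
    mu : float
        Shear-like modulus in kPa (equal to the small-strain shear modulus
        in the adopted convention).  Printed tissue values: 20 kPa for the
        dense connective lining, 1.1 kPa for the spongiosum.
    alpha : float
        Dimensionless stiffening exponent (6.178 for both tissue layers).
    """

    mu: float
    alpha: float
    name: str = ""

    def __post_init__(self) -> None:
        _finite_positive("mu", self.mu)
        if not np.isfinite(self.alpha) or self.alpha == 0.0:
            raise ValueError(f"alpha must be finite and nonzero, got {self.alpha!r}")


@dataclass(frozen=True)
class NeoHookeanMaterial:
    """Neo-Hookean material (Ogden with alpha = 2); mu in kPa."""

    mu: float
    name: str = ""

    def __post_init__(self) -> None:
        _finite_positive("mu", self.mu)

    def as_ogden(self) -> OgdenMaterial:
        return OgdenMaterial(self.mu, 2.0, name=self.name)


@dataclass(frozen=True)
class LinearElasticMaterial:
    """Small-strain isotropic elasticity; E in MPa, nu dimensionless.

    Used for the rigid metallic device body (Ti6Al4V: E = 114000 MPa,
    nu = 0.315); in the simulations the device is treated kinematically as
    rigid, so this material mainly carries metadata and unit conversion.
    """

    E: float
    nu: float
    name: str = ""

    def __post_init__(self) -> None:
        _finite_positive("E", self.E)
        if not (0.0 <= self.nu < 0.5):
            raise ValueError(f"nu must lie in [0, 0.5), got {self.nu!r}")

    @property
    def E_kPa(self) -> float:
        return self.E * 1000.0

    @property
    def shear_modulus_kPa(self) -> float:
        return self.E_kPa / (2.0 * (1.0 + self.nu))

    @property
    def lame_lambda_kPa(self) -> float:
        return self.E_kPa * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))


@dataclass
class DeformationState:
    """Deformation gradient plus constraint pressure at a material point.

    ``F`` is the 3x3 deformation gradient (dimensionless, det F > 0) and
    ``p`` an optional Lagrange/penalty pressure in kPa entering the stress
    as ``-p I``.
    """

    F: np.ndarray
    p: float = 0.0

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (3, 3):
            raise InvalidDeformationError(f"F must be 3x3, got shape {self.F.shape}")
        _check_F(self.F)


def _check_F(F: np.ndarray) -> float:
    if not np.all(np.isfinite(F)):
        raise InvalidDeformationError("deformation gradient has non-finite entries")
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise InvalidDeformationError(f"det(F) must be positive, got {J}")
    return J


def _as_F(state) -> tuple[np.ndarray, float]:
    if isinstance(state, DeformationState):
        return state.F, state.p
    F = np.asarray(state, dtype=float)
    if F.shape != (3, 3):
        raise InvalidDeformationError(f"F must be 3x3, got shape {F.shape}")
    _check_F(F)
    return F, 0.0


def principal_stretches(F: np.ndarray) -> np.ndarray:
    """Principal stretches of ``F`` (square roots of eigenvalues of F^T F)."""

    C = F.T @ F
    w = np.linalg.eigvalsh(C)
    return np.sqrt(np.clip(w, 0.0, None))


def _ogden_params(material) -> tuple[float, float]:
    if isinstance(material, NeoHookeanMaterial):
        return material.mu, 2.0
    if isinstance(material, OgdenMaterial):
        return material.mu, material.alpha
    raise TypeError(f"unsupported material for hyperelastic evaluation: {material!r}")


def strain_energy(material, state, bulk_factor: float = DEFAULT_BULK_FACTOR) -> float:
    """Strain-energy density W(F) in kPa.

    Zero at the reference state, invariant under rotations applied on
    either side of ``F`` (isotropy and frame indifference).  Includes the
    volumetric penalty, which vanishes for isochoric deformations.
    """

    if isinstance(material, LinearElasticMaterial):
        F, _ = _as_F(state)
        eps = 0.5 * (F + F.T) - np.eye(3)
        lam = material.lame_lambda_kPa
        mu = material.shear_modulus_kPa
        return float(0.5 * lam * np.trace(eps) ** 2 + mu * np.sum(eps * eps))

    mu, alpha = _ogden_params(material)
    F, _ = _as_F(state)
    J = float(np.linalg.det(F))
    lam = principal_stretches(F)
    lbar = J ** (-1.0 / 3.0) * lam
    w_iso = (2.0 * mu / alpha**2) * (np.sum(lbar**alpha) - 3.0)
    kappa = bulk_factor * mu
    w_vol = 0.5 * kappa * (J - 1.0) ** 2
    return float(w_iso + w_vol)


def cauchy_stress(material, state, bulk_factor: float = DEFAULT_BULK_FACTOR) -> np.ndarray:
    """Cauchy stress tensor (3x3, kPa) at a deformation state.

    For the hyperelastic materials the stress is the exact gradient of
    :func:`strain_energy` (deviatoric Ogden part plus penalty pressure
    ``kappa (J - 1)``), minus ``p I`` for an externally supplied constraint
    pressure.
    """

    F, p = _as_F(state)

    if isinstance(material, LinearElasticMaterial):
        eps = 0.5 * (F + F.T) - np.eye(3)
        lam = material.lame_lambda_kPa
        mu = material.shear_modulus_kPa
        return lam * np.trace(eps) * np.eye(3) + 2.0 * mu * eps - p * np.eye(3)

    mu, alpha = _ogden_params(material)
    J = float(np.linalg.det(F))
    b = F @ F.T
    w, vecs = np.linalg.eigh(b)
    lam = np.sqrt(np.clip(w, 1e-30, None))
    lbar = J ** (-1.0 / 3.0) * lam
    A = lbar**alpha
    sdev = (2.0 * mu / (alpha * J)) * (A - A.mean())
    kappa = bulk_factor * mu
    svol = kappa * (J - 1.0)
    sigma = (vecs * (sdev + svol)) @ vecs.T - p * np.eye(3)
    return 0.5 * (sigma + sigma.T)


def uniaxial_nominal_stress(material, stretch):
    """Nominal (first Piola) stress for incompressible uniaxial tension.

    Closed form for the one-term Ogden model with lateral stretches
    ``lambda**(-1/2)``:

        P(lambda) = (2 mu / alpha) * (lambda**(alpha-1) - lambda**(-alpha/2-1))

    ``stretch`` may be a scalar or array of positive stretches; the result
    has the same shape, in kPa.
    """

    mu, alpha = _ogden_params(material)
    lam = np.asarray(stretch, dtype=float)
    if not np.all(np.isfinite(lam)) or np.any(lam <= 0.0):
        raise ValueError("stretch must be finite and positive")
    P = (2.0 * mu / alpha) * (lam ** (alpha - 1.0) - lam ** (-alpha / 2.0 - 1.0))
    if np.isscalar(stretch) or np.ndim(stretch) == 0:
        return float(P)
    return P


def uniaxial_deformation_gradient(stretch: float) -> np.ndarray:
    """Incompressible uniaxial deformation gradient diag(l, 1/sqrt(l), 1/sqrt(l))."""

    if stretch <= 0.0:
        raise ValueError("stretch must be positive")
    s = 1.0 / math.sqrt(stretch)
    return np.diag([stretch, s, s])
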