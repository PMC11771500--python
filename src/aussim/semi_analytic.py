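"""Semi-analytic inflation of a two-layer incompressible circular tube.

Plane-strain, incompressible kinematics map a reference radius ``R`` to

    r(R) = sqrt(R^2 + r_i^2 - R_i^2),

so the motion is fully determined by the inner-radius stretch
``lam_i = r_i / R_i``.  Radial equilibrium then gives the net inflation
pressure (internal minus external) as a single quadrature across the wall,

    p = int_{r_i}^{r_o} (sigma_tt - sigma_rr) / r dr,

where for an incompressible isotropic material in plane strain
``sigma_tt - sigma_rr = lam * dW/dlam`` evaluated at the hoop stretch
``lam = r / R``.  For the one-term Ogden model this is
``(2 mu / alpha) * (lam**alpha - lam**(-alpha))``.

This closed-form structure serves two purposes: it reproduces the
structure-level inflation response of the urethra idealised as a circular
two-layer tube (stiff thin lining inside, soft thick spongiosum outside),
and it is the independent oracle against which the finite-element solver is
verified.  Negative ``lam_i - 1`` (external compression) is handled by the
same formulas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .constitutive import NeoHookeanMaterial, OgdenMaterial, strain_energy

__all__ = [
    "TwoLayerTubeSpec",
    "pressure_for_inner_stretch",
    "inflation_curve",
    "radial_stress",
    "stored_energy",
]


@dataclass(frozen=True)
class TwoLayerTubeSpec:
    """Reference geometry and materials of a two-layer circular tube (mm)."""

    inner_radius: float
    interface_radius: float
    outer_radius: float
    inner_material: OgdenMaterial
    outer_material: OgdenMaterial

    def __post_init__(self) -> None:
        if not (0.0 < self.inner_radius < self.interface_radius < self.outer_radius):
            raise ValueError(
                "radii must satisfy 0 < inner < interface < outer, got "
                f"({self.inner_radius}, {self.interface_radius}, {self.outer_radius})"
            )

    @property
    def layers(self):
        return (
            (self.inner_radius, self.interface_radius, _ogden(self.inner_material)),
            (self.interface_radius, self.outer_radius, _ogden(self.outer_material)),
        )


def _ogden(material):
    if isinstance(material, NeoHookeanMaterial):
        return material.mu, 2.0
    return material.mu, material.alpha


def _hoop_minus_radial(lam, mu, alpha):
    return (2.0 * mu / alpha) * (lam**alpha - lam ** (-alpha))


def _check_lam_i(spec: TwoLayerTubeSpec, lam_i: float) -> float:
    if not np.isfinite(lam_i) or lam_i <= 0.0:
        raise ValueError(f"inner stretch must be positive, got {lam_i!r}")
    d = (lam_i * spec.inner_radius) ** 2 - spec.inner_radius**2
    if spec.inner_radius**2 + d <= 0.0:
        raise ValueError(f"inner stretch {lam_i} collapses the tube (r^2 <= 0)")
    return d


def pressure_for_inner_stretch(spec: TwoLayerTubeSpec, lam_i: float) -> float:
    """Net pressure (internal minus external, kPa) producing inner stretch lam_i.

    Zero at ``lam_i = 1``; positive for inflation, negative for external
    compression.  Continuous across the layer interface by construction.
    """

    d = _check_lam_i(spec, lam_i)
    total = 0.0
    for R_a, R_b, (mu, alpha) in spec.layers:
        def integrand(R, mu=mu, alpha=alpha):
            r2 = R * R + d
            lam = np.sqrt(r2) / R
            return _hoop_minus_radial(lam, mu, alpha) * R / r2

        val, _ = integrate.quad(integrand, R_a, R_b, epsrel=1e-10, epsabs=1e-12, limit=200)
        total += val
    return float(total)


def radial_stress(spec: TwoLayerTubeSpec, lam_i: float, r_query, p_external: float = 0.0):
    """Radial Cauchy stress sigma_rr (kPa) at deformed radii ``r_query``.

    Integrates equilibrium inward from the outer surface where
    ``sigma_rr = -p_external``.  Continuous across the interface.
    """

    d = _check_lam_i(spec, lam_i)

    def integrand(R):
        r2 = R * R + d
        lam = np.sqrt(r2) / R
        if R <= spec.interface_radius:
            mu, alpha = _ogden(spec.inner_material)
        else:
            mu, alpha = _ogden(spec.outer_material)
        return _hoop_minus_radial(lam, mu, alpha) * R / r2

    r_query = np.atleast_1d(np.asarray(r_query, dtype=float))
    out = np.empty_like(r_query)
    for i, r in enumerate(r_query):
        R = np.sqrt(r * r - d)
        if not (spec.inner_radius - 1e-9 <= R <= spec.outer_radius + 1e-9):
            raise ValueError(f"query radius {r} outside the deformed wall")
        R0 = float(np.clip(R, spec.inner_radius, spec.outer_radius))
        pieces = [R0] + [x for x in (spec.interface_radius, spec.outer_radius)
                         if x > R0]
        R0 = pieces[0]
        total = 0.0
        for R1 in pieces[1:]:
            if R1 > R0:
                val, _ = integrate.quad(integrand, R0, R1, epsrel=1e-10, epsabs=1e-12, limit=200)
                total += val
                R0 = R1
        out[i] = -p_external - total
    return out if out.size > 1 else float(out[0])


def stored_energy(spec: TwoLayerTubeSpec, lam_i: float) -> float:
    """Stored strain energy per unit tube length (mN·mm / mm... i.e. kPa·mm^2)."""

    d = _check_lam_i(spec, lam_i)
    total = 0.0
    for R_a, R_b, (mu, alpha) in spec.layers:
        def integrand(R, mu=mu, alpha=alpha):
            lam = np.sqrt(R * R + d) / R
            w = (2.0 * mu / alpha**2) * (lam**alpha + lam ** (-alpha) - 2.0)
            return w * 2.0 * np.pi * R

        val, _ = integrate.quad(integrand, R_a, R_b, epsrel=1e-10, epsabs=1e-12, limit=200)
        total += val
    return float(total)


def inflation_curve(spec: TwoLayerTubeSpec, pressures, lam_max: float = 3.0):
    """Inner and outer deformed radii along an increasing pressure grid.

    Returns an array with columns (pressure kPa, inner radius mm, outer
    radius mm), obtained by bracketed root finding on
    :func:`pressure_for_inner_stretch`.  Pressures beyond the solvable
    range (inner stretch ``lam_max``) truncate the curve with a warning.
    """

    pressures = np.asarray(pressures, dtype=float)
    if np.any(pressures < 0.0) or np.any(np.diff(pressures) < 0.0):
        raise ValueError("pressures must be non-negative and non-decreasing")
    p_cap = pressure_for_inner_stretch(spec, lam_max)
    rows = []
    for p in pressures:
        if p > p_cap:
            warnings.warn(
                f"pressure {p} kPa exceeds the solvable range (max {p_cap:.3g} kPa); "
                "curve truncated",
                stacklevel=2,
            )
            break
        if p == 0.0:
            lam = 1.0
        else:
            lam = optimize.brentq(
                lambda s: pressure_for_inner_stretch(spec, s) - p, 1.0, lam_max,
                xtol=1e-12, rtol=1e-12,
            )
        r_i = lam * spec.inner_radius
        d = r_i**2 - spec.inner_radius**2
        r_o = float(np.sqrt(spec.outer_radius**2 + d))
        rows.append((float(p), float(r_i), r_o))
    return np.array(rows)
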