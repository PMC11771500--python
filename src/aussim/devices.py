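"""Device loading scenarios: extraluminal cuff and intraluminal shaft fixation.

Two artificial-sphincter actions are encoded as solver inputs:

* **Cuff** (extraluminal, AMS 800-type): the wrapped band transmits the
  blister pressure to the urethral surface.  Because the fibre-reinforced
  supporting band is nearly inextensible, the blister pressure is idealised
  as a uniform follower pressure on the outer boundary of the cross-section,
  ramped linearly to the target (default 8 kPa, the upper end of the 6-8 kPa
  clinical band).  Lumen self-contact with friction 0.02 models occlusion.

* **Shaft** (intraluminal, Relief-type): the cylindrical device body
  (diameter 7 mm) is inserted in the lumen and its distal shaft structure
  — four arms that expand radially beyond the body — pins the device by
  stretching the urethral wall.  The body and arm tips are treated as rigid
  circles in the cross-section; the body first expands from an inscribed
  radius to the device radius, then the arm tips protrude by a further
  radial excursion ``delta`` (not printed for the real device; default
  0.5 mm with a {0.25, 0.5, 1.0} mm sensitivity range).  Device-tissue
  friction is 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constitutive import LinearElasticMaterial
from .geometry import Mesh
from .solver import ConfigurationError, ContactPair, LoadScenario, PressureLoad

__all__ = [
    "CuffScenario",
    "ShaftScenario",
    "ReliefDeviceSpec",
    "cuff_loading",
    "shaft_loading",
]

TI6AL4V = LinearElasticMaterial(E=114000.0, nu=0.315, name="Ti6Al4V")


@dataclass(frozen=True)
class CuffScenario:
    """Cuff insufflation: target pressure (kPa) and load-factor ramp."""

    pressure_kPa: float = 8.0
    n_steps: int = 40

    def __post_init__(self) -> None:
        if not (0.0 <= self.pressure_kPa <= 10.0):
            raise ValueError("cuff pressure outside the sane 0-10 kPa band")
        if self.n_steps < 1:
            raise ValueError("need at least one load step")

    @property
    def ramp(self) -> np.ndarray:
        return np.linspace(1.0 / self.n_steps, 1.0, self.n_steps)


@dataclass(frozen=True)
class ReliefDeviceSpec:
    """Intraluminal device body: printed dimensions and materials.

    The valve threshold pressure (16 kPa) and the body material are carried
    as metadata; in the cross-section analysis the body is kinematically
    rigid (its stiffness exceeds the tissue's by seven orders of magnitude).
    """

    external_diameter_mm: float = 7.0
    length_mm: float = 52.5
    valve_threshold_kPa: float = 16.0
    body_material: LinearElasticMaterial = TI6AL4V

    def __post_init__(self) -> None:
        if min(self.external_diameter_mm, self.length_mm, self.valve_threshold_kPa) <= 0:
            raise ValueError("device dimensions must be positive")

    @property
    def radius(self) -> float:
        return self.external_diameter_mm / 2.0


@dataclass(frozen=True)
class ShaftScenario:
    """Distal shaft fixation: arm count, tip size, radial expansion.

    ``angles_deg`` defaults to one arm centred in each quadrant
    (45, 135, 225, 315 for four arms), so a quarter model contains exactly
    one arm.  ``delta_mm`` is the radial protrusion of the arm tips beyond
    the device surface; ``body_fraction`` is the portion of the ramp spent
    expanding the body before the arms deploy.
    """

    n_arms: int = 4
    tip_radius_mm: float = 0.5
    delta_mm: float = 0.5
    angles_deg: tuple | None = None
    friction: float = 0.1
    n_steps: int = 60
    body_fraction: float = 0.7

    def __post_init__(self) -> None:
        if self.n_arms < 1:
            raise ValueError("need at least one arm")
        if self.delta_mm < 0.0 or self.tip_radius_mm <= 0.0:
            raise ValueError("tip radius must be positive and delta non-negative")
        if not (0.0 < self.body_fraction < 1.0):
            raise ValueError("body_fraction must lie in (0, 1)")

    @property
    def angles_rad(self) -> np.ndarray:
        if self.angles_deg is not None:
            return np.deg2rad(np.asarray(self.angles_deg, dtype=float))
        step = 360.0 / self.n_arms
        return np.deg2rad(step / 2.0 + step * np.arange(self.n_arms))

    @property
    def ramp(self) -> np.ndarray:
        return np.linspace(1.0 / self.n_steps, 1.0, self.n_steps)


def cuff_loading(scenario: CuffScenario, mesh: Mesh):
    """Cuff scenario as (LoadScenario, contacts) for :func:`aussim.solver.solve`.

    Pressure at load factor f is ``f * pressure_kPa`` on the outer boundary;
    lumen self-contact handles occlusion.
    """

    if "outer_boundary" not in mesh.loops:
        raise ConfigurationError("mesh has no outer_boundary loop")
    loading = LoadScenario(
        ramp=scenario.ramp,
        pressures=[PressureLoad("outer_boundary", scenario.pressure_kPa, side="outside")],
    )
    contacts = [ContactPair("self_lumen")]
    return loading, contacts


def shaft_loading(scenario: ShaftScenario, device: ReliefDeviceSpec, mesh: Mesh):
    """Shaft scenario as (LoadScenario, contacts) with rigid-indenter contact.

    The rigid geometry at load factor f is one central circle (the body)
    whose radius grows from an inscribed starting value to the device
    radius over the first ``body_fraction`` of the ramp, plus ``n_arms``
    tip circles that then translate radially outward until they protrude
    by ``delta_mm`` at f = 1.
    """

    if "lumen_boundary" not in mesh.loops:
        raise ConfigurationError("mesh has no lumen_boundary loop")
    lumen = mesh.nodes[mesh.loops["lumen_boundary"]]
    r_min = float(np.linalg.norm(lumen, axis=1).min())
    r_dev = device.radius
    # the outer radius grows with incompressible area conservation; the
    # arm tips must remain inside the tissue domain
    outer_r = float(np.linalg.norm(mesh.nodes[mesh.loops["outer_boundary"]], axis=1).max())
    if r_dev + scenario.delta_mm >= outer_r:
        raise ConfigurationError(
            f"arm tips at {r_dev + scenario.delta_mm} mm would exceed the "
            f"outer boundary ({outer_r} mm)"
        )
    r0 = 0.95 * r_min
    f1 = scenario.body_fraction
    angles = scenario.angles_rad
    tip_r = scenario.tip_radius_mm

    def circles_fn(lf: float) -> np.ndarray:
        body_r = r0 + (r_dev - r0) * min(lf / f1, 1.0)
        out = [(0.0, 0.0, body_r)]
        # tips sit flush inside the body until it is fully expanded, then
        # move radially outward
        g = 0.0 if lf <= f1 else (lf - f1) / (1.0 - f1)
        c = (body_r - tip_r) + g * scenario.delta_mm
        for a in angles:
            out.append((c * np.cos(a), c * np.sin(a), tip_r))
        return np.asarray(out)

    loading = LoadScenario(ramp=scenario.ramp)
    contacts = [
        ContactPair("rigid_indenter", friction=scenario.friction,
                    circles_fn=circles_fn),
    ]
    return loading, contacts
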