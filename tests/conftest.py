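"""Shared fixtures: tissue materials and the two device-scenario reference runs.

The cuff and shaft runs at the printed study conditions are expensive, so
they are computed once per session and shared between the acceptance tests
and the invariant tests that inspect the same states.
"""

from __future__ import annotations

import numpy as np
import pytest

from aussim.constitutive import OgdenMaterial
from aussim.devices import CuffScenario, ReliefDeviceSpec, ShaftScenario, cuff_loading, shaft_loading
from aussim.geometry import CrossSectionSpec, build_cross_section
from aussim.postprocess import stimulation_report
from aussim.solver import solve


@pytest.fixture(scope="session")
def lining_material():
    return OgdenMaterial(mu=20.0, alpha=6.178, name="lining")


@pytest.fixture(scope="session")
def spongiosum_material():
    return OgdenMaterial(mu=1.1, alpha=6.178, name="spongiosum")


@pytest.fixture(scope="session")
def tissue_materials(lining_material, spongiosum_material):
    return {"lining": lining_material, "spongiosum": spongiosum_material}


@pytest.fixture(scope="session")
def cuff_run(tissue_materials):
    """8 kPa cuff occlusion of the printed cross-section, quarter symmetry."""

    mesh = build_cross_section(CrossSectionSpec(), 0.2, quarter_symmetry=True)
    loading, contacts = cuff_loading(CuffScenario(pressure_kPa=8.0, n_steps=40), mesh)
    states = solve(mesh, tissue_materials, loading, contacts=contacts)
    report = stimulation_report(states[-1], mesh)
    return {"mesh": mesh, "states": states, "report": report}


@pytest.fixture(scope="session")
def shaft_run(tissue_materials):
    """Intraluminal device insertion plus arm deployment at default delta."""

    mesh = build_cross_section(CrossSectionSpec(), 0.2, quarter_symmetry=True)
    loading, contacts = shaft_loading(ShaftScenario(), ReliefDeviceSpec(), mesh)
    states = solve(mesh, tissue_materials, loading, contacts=contacts)
    report = stimulation_report(states[-1], mesh)
    return {"mesh": mesh, "states": states, "report": report}
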