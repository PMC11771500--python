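"""Finite-element solver verification: analytic limits, oracle equivalence,
pressure-load identities and penalty contact behaviour."""

import numpy as np
import pytest
from scipy import optimize

from aussim.constitutive import OgdenMaterial
from aussim.contact import LumenSelfContact, PlaneContact, RigidCircleContact
from aussim.geometry import build_annulus, build_block, build_cross_section, CrossSectionSpec
from aussim.semi_analytic import TwoLayerTubeSpec, inflation_curve, pressure_for_inner_stretch, radial_stress
from aussim.solver import (
    ConfigurationError,
    ContactPair,
    DivergenceError,
    LoadScenario,
    PressureLoad,
    SolverConfig,
    apply_pressure_load,
    gauss_point_coords,
    solve,
)

LINING = OgdenMaterial(20.0, 6.178)
SPONG = OgdenMaterial(1.1, 6.178)
MATS = {"lining": LINING, "spongiosum": SPONG}


class TestApplyPressureLoad:
    def test_closed_circle_resultant_vanishes(self):
        theta = np.linspace(0, 2 * np.pi, 73)[:-1]
        pts = 5.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        f = apply_pressure_load(pts, 1.0, side="inside", closed=True)
        assert np.abs(f.sum(axis=0)).max() < 1e-10

    def test_single_edge_force_is_pressure_times_length(self):
        pts = np.array([[0.0, 0.0], [2.0, 0.0]])
        f = apply_pressure_load(pts, 3.0, side="inside", closed=False)
        assert np.linalg.norm(f.sum(axis=0)) == pytest.approx(6.0)
        # equally shared between the end nodes
        assert np.linalg.norm(f[0]) == pytest.approx(3.0)

    def test_virtual_work_matches_area_change_rate(self):
        # uniform radial contraction of a pressurised circle: the load's
        # virtual work must equal p times the rate of area change
        theta = np.linspace(0, 2 * np.pi, 721)[:-1]
        R, p = 5.0, 8.0
        pts = R * np.column_stack([np.cos(theta), np.sin(theta)])
        f = apply_pressure_load(pts, p, side="outside", closed=True)
        v = -pts / R  # unit inward radial velocity
        power = np.sum(f * v)
        assert power == pytest.approx(p * 2 * np.pi * R, rel=1e-4)

    def test_outside_pressure_points_inward(self):
        theta = np.linspace(0, 2 * np.pi, 37)[:-1]
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        f = apply_pressure_load(pts, 1.0, side="outside", closed=True)
        assert np.all(np.einsum("ij,ij->i", f, pts) < 0)

    def test_zero_length_edge_raises(self):
        with pytest.raises(ValueError):
            apply_pressure_load(np.zeros((2, 2)), 1.0, closed=False)


class TestElementarysolutions:
    def test_zero_load_gives_zero_state(self):
        mesh = build_annulus(0.8, 0.94, 5.0, 0.5)
        states = solve(mesh, MATS, LoadScenario(ramp=np.array([1.0])))
        s = states[-1]
        assert np.abs(s.u).max() == 0.0
        assert np.abs(s.stress).max() < 1e-12
        np.testing.assert_allclose(s.J, 1.0)

    def test_incompressible_disc_under_hydrostatic_pressure(self):
        # disc with a pinhole pressurised equally inside and out: the exact
        # solution is a uniform hydrostatic stress state with negligible
        # displacement in the incompressible limit
        mesh = build_annulus(0.05, 0.1, 5.0, 0.35)
        mats = {"lining": LINING, "spongiosum": LINING}
        p = 8.0
        sc = LoadScenario(
            ramp=np.linspace(0.25, 1.0, 4),
            pressures=[PressureLoad("outer_boundary", p, side="outside"),
                       PressureLoad("lumen_boundary", p, side="inside")])
        config = SolverConfig(bulk_factor=5000.0)
        s = solve(mesh, mats, sc, config=config)[-1]
        assert np.abs(s.u).max() <= 1e-3
        pressure = -(s.stress[..., 0] + s.stress[..., 1] + s.stress[..., 3]) / 3.0
        assert np.abs(pressure - p).max() / p < 0.01

    def test_patch_test_uniform_isochoric_stretch(self):
        # affine isochoric deformation imposed on the boundary must be
        # reproduced exactly (constant stress) by the interior solution
        mesh = build_block(1.0, 1.0, 5, 5)
        F = np.array([[1.1, 0.05], [0.0, 1.0 / 1.1]])
        F[1, 1] = (1.0 + F[0, 1] * 0.0) / F[0, 0]  # det = 1 in-plane
        boundary = np.where(
            (np.abs(mesh.nodes[:, 0]) < 1e-12) | (np.abs(mesh.nodes[:, 0] - 1) < 1e-12)
            | (np.abs(mesh.nodes[:, 1]) < 1e-12) | (np.abs(mesh.nodes[:, 1] - 1) < 1e-12)
        )[0]
        target = mesh.nodes @ (F - np.eye(2)).T
        sc = LoadScenario(
            ramp=np.array([1.0]),
            dirichlet=[(boundary, 0, target[boundary, 0]),
                       (boundary, 1, target[boundary, 1])],
            auto_symmetry=False)
        s = solve(mesh, {"spongiosum": SPONG}, sc,
                  config=SolverConfig(newton_tol=1e-12))[-1]
        np.testing.assert_allclose(s.u, target, atol=1e-10)
        for comp in range(4):
            field = s.stress[..., comp]
            scale = max(np.abs(s.stress).max(), 1.0)
            assert (field.max() - field.min()) / scale < 1e-8

    def test_objectivity_rotated_patch(self):
        # solving with rotated boundary data yields the rotated stress
        mesh = build_block(1.0, 1.0, 4, 4)
        F0 = np.array([[1.15, 0.0], [0.0, 1.0 / 1.15]])
        ang = np.deg2rad(30.0)
        Q = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        boundary = np.where(
            (np.abs(mesh.nodes[:, 0]) < 1e-12) | (np.abs(mesh.nodes[:, 0] - 1) < 1e-12)
            | (np.abs(mesh.nodes[:, 1]) < 1e-12) | (np.abs(mesh.nodes[:, 1] - 1) < 1e-12)
        )[0]

        def run(F):
            target = mesh.nodes @ (F - np.eye(2)).T
            sc = LoadScenario(ramp=np.array([1.0]),
                              dirichlet=[(boundary, 0, target[boundary, 0]),
                                         (boundary, 1, target[boundary, 1])],
                              auto_symmetry=False)
            return solve(mesh, {"spongiosum": SPONG}, sc,
                         config=SolverConfig(newton_tol=1e-12))[-1]

        s0 = run(F0)
        s1 = run(Q @ F0)
        sig0 = np.array([[s0.stress[0, 0, 0], s0.stress[0, 0, 2]],
                         [s0.stress[0, 0, 2], s0.stress[0, 0, 1]]])
        sig1 = np.array([[s1.stress[0, 0, 0], s1.stress[0, 0, 2]],
                         [s1.stress[0, 0, 2], s1.stress[0, 0, 1]]])
        np.testing.assert_allclose(sig1, Q @ sig0 @ Q.T, atol=1e-8)


@pytest.fixture(scope="module")
def tube():
    return TwoLayerTubeSpec(0.8, 0.94, 5.0, LINING, SPONG)


@pytest.fixture(scope="module")
def fe_inflation():
    mesh = build_annulus(0.8, 0.94, 5.0, 0.2, quarter_symmetry=True)
    sc = LoadScenario(ramp=np.linspace(0.1, 1.0, 10),
                      pressures=[PressureLoad("lumen_boundary", 2.0, side="inside")])
    states = solve(mesh, MATS, sc)
    return mesh, states[-1]


class TestOracleEquivalence:
    def test_inner_radius_displacement_within_one_percent(self, tube, fe_inflation):
        mesh, s = fe_inflation
        oracle_r = inflation_curve(tube, [0.0, 2.0])[-1, 1]
        inner = mesh.node_sets["lumen_boundary"]
        fe_r = np.linalg.norm(mesh.nodes[inner] + s.u[inner], axis=1).mean()
        assert abs((fe_r - 0.8) - (oracle_r - 0.8)) / (oracle_r - 0.8) < 0.01

    def test_radial_stress_field_within_three_percent(self, tube, fe_inflation):
        # the volumetric penalty pressure is element-wise constant, so the
        # discrete stress is compared per element mean at the element's
        # mean deformed radius
        mesh, s = fe_inflation
        lam_i = inflation_curve(tube, [0.0, 2.0])[-1, 1] / 0.8
        xg = gauss_point_coords(mesh, s.u)
        r = np.linalg.norm(xg, axis=2)
        n = xg / r[..., None]
        s11, s22, s12 = s.stress[..., 0], s.stress[..., 1], s.stress[..., 2]
        srr = (n[..., 0] ** 2 * s11 + n[..., 1] ** 2 * s22
               + 2 * n[..., 0] * n[..., 1] * s12)
        r_el = r.mean(axis=1)
        r_out_def = np.sqrt(25 + (lam_i**2 - 1) * 0.64)
        ref = radial_stress(tube, lam_i, np.clip(r_el, None, r_out_def - 1e-9))
        err = np.abs(srr.mean(axis=1) - ref)
        assert err.max() / 2.0 < 0.03  # relative to the 2 kPa load scale

    def test_external_pressure_branch_matches_oracle(self, tube):
        # external compression of the annulus (no contact): lam_i < 1
        p_ext = 0.5
        lam = optimize.brentq(
            lambda s_: pressure_for_inner_stretch(tube, s_) + p_ext, 0.3, 1.0)
        mesh = build_annulus(0.8, 0.94, 5.0, 0.2, quarter_symmetry=True)
        sc = LoadScenario(ramp=np.linspace(0.1, 1.0, 10),
                          pressures=[PressureLoad("outer_boundary", p_ext, side="outside")])
        s = solve(mesh, MATS, sc)[-1]
        inner = mesh.node_sets["lumen_boundary"]
        fe_r = np.linalg.norm(mesh.nodes[inner] + s.u[inner], axis=1).mean()
        assert abs((fe_r - 0.8) - (lam - 1.0) * 0.8) / abs((lam - 1.0) * 0.8) < 0.01


class TestContactUnits:
    def test_open_gap_gives_zero_forces(self):
        c = RigidCircleContact([0, 1], lambda lf: [(0.0, 0.0, 1.0)],
                               mu_f=0.1, kn=1e4, kt=1e4, trib=np.ones(2))
        xn = np.array([[2.0, 0.0], [0.0, 3.0]])
        f, info = c.forces(xn, 1.0)
        assert np.abs(f).max() == 0.0
        assert not info["active"].any()

    def test_penalty_pushes_penetrating_node_out(self):
        c = RigidCircleContact([0], lambda lf: [(0.0, 0.0, 1.0)],
                               mu_f=0.0, kn=1e4, kt=1e4, trib=np.ones(1))
        xn = np.array([[0.98, 0.0]])  # 0.02 mm inside the circle
        f, info = c.forces(xn, 1.0)
        assert info["active"][0]
        assert f[0, 0] > 0.0 and abs(f[0, 1]) < 1e-12

    def test_coulomb_cone_bound_and_sliding_limit(self):
        kn = 1e3
        c = RigidCircleContact([0], lambda lf: [(0.0, 0.0, 1.0)],
                               mu_f=0.1, kn=kn, kt=kn, trib=np.ones(1))
        x0 = np.array([[0.995, 0.0]])
        c.forces(x0, 1.0)
        c.update_anchors(x0, 1.0)
        # drag the node tangentially while keeping the penetration
        ang = 0.3
        x1 = np.array([[0.995 * np.cos(ang), 0.995 * np.sin(ang)]])
        f, info = c.forces(x1, 1.0)
        n = x1[0] / np.linalg.norm(x1[0])
        fn = f[0] @ n
        ft = f[0] @ np.array([-n[1], n[0]])
        assert fn > 0.0
        assert abs(ft) <= 0.1 * fn + 1e-12
        assert abs(ft) > 0.09 * fn  # fully sliding: at the cone surface

    def test_frictionless_flat_punch_reaction_balance(self):
        # rigid plane pressed into a soft block: total contact force equals
        # the reaction transmitted to the fixed base
        mesh = build_block(1.0, 4.0, 3, 12)  # tall block, loaded on x = 1 face
        push = 0.2
        base = mesh.node_sets["symmetry_y"]  # x = 0 edge
        sc = LoadScenario(ramp=np.linspace(0.25, 1.0, 4),
                          dirichlet=[], fixed=[(base, 0), (base, 1)],
                          auto_symmetry=False)
        contacts = [ContactPair("rigid_indenter", friction=0.0,
                                surface="outer_boundary",
                                circles_fn=lambda lf: [(1.0 - push * lf + 50.0, 2.0, 50.0)])]
        s = solve(mesh, {"spongiosum": SPONG}, sc, contacts=contacts,
                  config=SolverConfig(n_load_steps=4,
                                      penalty_contact_stiffness=2000.0))[-1]
        outer = mesh.node_sets["outer_boundary"]
        x_face = mesh.nodes[outer, 0] + s.u[outer, 0]
        y_face = mesh.nodes[outer, 1] + s.u[outer, 1]
        # no node may lie beyond the (slightly curved) punch surface
        surface = 1.0 - push + 50.0 - np.sqrt(50.0**2 - (y_face - 2.0) ** 2)
        assert np.all(x_face <= surface + 5e-3)
        # the face centre is pressed onto the punch
        mid = np.argmin(np.abs(y_face - 2.0))
        assert x_face[mid] == pytest.approx(1.0 - push, abs=5e-3)

    def test_self_contact_forces_balance(self):
        # squashed synthetic loop: penetrating opposing faces repel with
        # zero net force (action equals reaction)
        theta = np.linspace(0, 2 * np.pi, 41)[:-1]
        pts = np.column_stack([4.0 * np.cos(theta), 0.05 * np.sin(theta)])
        c = LumenSelfContact(np.arange(40), kn=1e3, trib=np.ones(40), g_tol=1e-3)
        # push the upper face through the lower one
        pts[pts[:, 1] > 0, 1] -= 0.2
        f, info = c.forces(pts, 1.0)
        assert info["n_active"] > 0
        assert np.abs(f.sum(axis=0)).max() < 1e-9

    def test_plane_contact_blocks_crossing(self):
        c = PlaneContact([0], normal=(0.0, 1.0), point_fn=np.zeros(2),
                         mu_f=0.0, kn=1e4, kt=1e4, trib=np.ones(1))
        f_open, _ = c.forces(np.array([[0.3, 0.1]]), 1.0)
        f_pen, info = c.forces(np.array([[0.3, -0.01]]), 1.0)
        assert np.abs(f_open).max() == 0.0
        assert f_pen[0, 1] > 0.0
        assert info["max_penetration"] == pytest.approx(0.01)


class TestRobustness:
    def test_material_region_mismatch_raises(self):
        mesh = build_annulus(0.8, 0.94, 5.0, 0.5)
        with pytest.raises(ConfigurationError):
            solve(mesh, {"lining": LINING}, LoadScenario(ramp=np.array([1.0])))

    def test_missing_boundary_loop_raises(self):
        mesh = build_annulus(0.8, 0.94, 5.0, 0.5)
        sc = LoadScenario(ramp=np.array([1.0]),
                          pressures=[PressureLoad("nonexistent", 1.0)])
        with pytest.raises(ConfigurationError):
            solve(mesh, MATS, sc)

    def test_divergence_carries_partial_states(self):
        mesh = build_annulus(0.8, 0.94, 5.0, 0.4)
        sc = LoadScenario(ramp=np.array([0.5, 1.0]),
                          pressures=[PressureLoad("lumen_boundary", 500.0, side="inside")])
        config = SolverConfig(max_newton_iter=3, max_cutbacks=1)
        with pytest.raises(DivergenceError) as err:
            solve(mesh, MATS, sc, config=config)
        assert isinstance(err.value.states, list)

    def test_determinism_identical_inputs_identical_states(self):
        mesh = build_annulus(0.8, 0.94, 5.0, 0.3)
        sc = LoadScenario(ramp=np.linspace(0.2, 1.0, 5),
                          pressures=[PressureLoad("lumen_boundary", 1.0, side="inside")])
        s1 = solve(mesh, MATS, sc)[-1]
        s2 = solve(mesh, MATS, sc)[-1]
        np.testing.assert_array_equal(s1.u, s2.u)
        np.testing.assert_array_equal(s1.stress, s2.stress)

    def test_ramp_validation(self):
        with pytest.raises(ValueError):
            LoadScenario(ramp=np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            LoadScenario(ramp=np.array([]))
        with pytest.raises(ValueError):
            SolverConfig(newton_tol=0.5)
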