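"""Quasi-static nonlinear finite-element solver for the tissue cross-section.

Plane-strain kinematics, 4-node quadrilaterals, total-Lagrangian state with
internal forces integrated on the deformed configuration.  Near
incompressibility is handled by selective reduced integration: the
deviatoric Ogden stress is evaluated at the 2x2 Gauss points while the
volumetric penalty pressure ``kappa (J - 1)`` is taken from the element
centroid, which avoids volumetric locking without introducing hourglass
modes (the deviatoric term remains fully integrated).

The solution is advanced by incremental loading with a Newton scheme:

* the global tangent is assembled from element-level finite differences of
  the exact internal-force vector (the residual, not the tangent, defines
  the discrete equilibrium, so this sacrifices nothing but a constant
  factor in assembly cost);
* follower pressure loads on boundary loops contribute an analytic load
  stiffness;
* a backtracking line search guards Newton steps, and load increments that
  fail to converge are bisected adaptively (up to ``max_cutbacks`` levels).

Assembly order is deterministic; identical inputs give identical states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import DEFAULT_BULK_FACTOR, NeoHookeanMaterial, OgdenMaterial
from .contact import LumenSelfContact, PlaneContact, RigidCircleContact
from .geometry import Mesh

__all__ = [
    "SolverConfig",
    "SolutionState",
    "LoadScenario",
    "PressureLoad",
    "ContactPair",
    "DivergenceError",
    "ConfigurationError",
    "apply_pressure_load",
    "solve",
]

_GAUSS = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]]) / np.sqrt(3.0)
_CORNERS = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
_FD_STEP = 1e-7  # mm; displacement perturbation for tangent assembly


class DivergenceError(RuntimeError):
    """Newton iteration failed after all cutbacks; carries partial states."""

    def __init__(self, message, states=None):
        super().__init__(message)
        self.states = states or []


class ConfigurationError(ValueError):
    """Mesh/material/loading mismatch."""


class _InversionError(RuntimeError):
    """An element Jacobian became non-positive during trial evaluation."""


@dataclass
class SolverConfig:
    """Numerical controls for the quasi-static solution.

    ``penalty_contact_stiffness`` (kPa/mm) defaults to
    ``100 * max(mu) / element size`` when left ``None``; ``bulk_factor`` is
    the kappa/mu ratio of the volumetric penalty.  Friction defaults follow
    the device-interaction model: 0.02 for lumen self-contact, 0.1 between
    tissue and other surfaces.
    """

    n_load_steps: int = 40
    newton_tol: float = 1e-6
    max_newton_iter: int = 30
    penalty_contact_stiffness: float | None = None
    friction_lumen_self: float = 0.02
    friction_device_tissue: float = 0.1
    bulk_factor: float = DEFAULT_BULK_FACTOR
    seed: int = 0
    max_cutbacks: int = 5
    g_tol: float = 1e-3
    slip_tol: float = 1e-3
    max_du: float | None = None  # per-iteration displacement cap, mm (None: element size)

    def __post_init__(self) -> None:
        if not (0.0 < self.newton_tol <= 1e-2):
            raise ValueError("newton_tol must lie in (0, 1e-2]")
        for name in ("n_load_steps", "max_newton_iter", "bulk_factor", "g_tol", "slip_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.friction_lumen_self < 0 or self.friction_device_tissue < 0:
            raise ValueError("friction coefficients must be non-negative")


@dataclass
class PressureLoad:
    """Uniform follower pressure on a named boundary loop.

    ``side='outside'`` pushes inward on the material enclosed by the loop
    (the cuff on the outer boundary); ``side='inside'`` pushes outward (a
    pressurised lumen).  The applied value is ``load_factor * pressure``.
    """

    loop: str
    pressure: float
    side: str = "outside"

    def __post_init__(self) -> None:
        if self.side not in ("inside", "outside"):
            raise ValueError("side must be 'inside' or 'outside'")


@dataclass
class ContactPair:
    """Declarative contact specification resolved by :func:`solve`.

    ``kind='self_lumen'`` activates lumen self-contact (reduced to
    symmetry-plane contact in quarter mode); ``kind='rigid_indenter'``
    requires ``circles_fn(load_factor) -> (c, 3)`` rigid circles.
    ``friction=None`` picks the matching SolverConfig default.
    """

    kind: str
    friction: float | None = None
    surface: str = "lumen_boundary"
    circles_fn: object = None

    def __post_init__(self) -> None:
        if self.kind not in ("self_lumen", "rigid_indenter"):
            raise ValueError(f"unknown contact kind {self.kind!r}")
        if self.kind == "rigid_indenter" and self.circles_fn is None:
            raise ConfigurationError("rigid_indenter contact needs circles_fn")


@dataclass
class LoadScenario:
    """Loading programme: pressure loads, prescribed displacements, ramp.

    ``dirichlet`` entries are (node_ids, component, values) with values
    scaled linearly by the load factor; ``fixed`` entries are
    (node_ids, component) pinned to zero.  The ramp must increase to 1.
    """

    ramp: np.ndarray = field(default_factory=lambda: np.linspace(0.025, 1.0, 40))
    pressures: list = field(default_factory=list)
    dirichlet: list = field(default_factory=list)
    fixed: list = field(default_factory=list)
    auto_symmetry: bool = True

    def __post_init__(self) -> None:
        self.ramp = np.asarray(self.ramp, dtype=float)
        if self.ramp.size == 0 or np.any(np.diff(self.ramp) <= 0.0) or self.ramp[-1] > 1.0 + 1e-12:
            raise ValueError("ramp must be strictly increasing with final value <= 1")


@dataclass
class SolutionState:
    """Converged fields at one load step.

    Per-element/Gauss-point arrays: in-plane deformation gradient ``F``
    (m, 4, 2, 2), volume ratio ``J`` (m, 4), element volumetric ratio
    ``J_bar`` (m,), Cauchy stress components (s11, s22, s12, s33) in
    ``stress`` (m, 4, 4) and reference integration weights ``gp_weight``
    (m, 4) for area-weighted statistics.
    """

    u: np.ndarray
    load_factor: float
    F: np.ndarray
    J: np.ndarray
    J_bar: np.ndarray
    stress: np.ndarray
    gp_weight: np.ndarray
    residual_norm: float
    n_iter: int
    contact_info: dict = field(default_factory=dict)


def _shape_data(points: np.ndarray):
    """Q4 shape-function derivatives w.r.t. (xi, eta) at given points."""

    out = np.empty((points.shape[0], 4, 2))
    for g, (xi, eta) in enumerate(points):
        for a, (xa, ea) in enumerate(_CORNERS):
            out[g, a, 0] = 0.25 * xa * (1.0 + ea * eta)
            out[g, a, 1] = 0.25 * ea * (1.0 + xa * xi)
    return out


_DN_GP = _shape_data(_GAUSS)          # (4 gp, 4 nodes, 2)
_DN_C = _shape_data(np.zeros((1, 2)))  # centroid


def _ogden_params(material):
    if isinstance(material, NeoHookeanMaterial):
        return material.mu, 2.0
    if isinstance(material, OgdenMaterial):
        return material.mu, material.alpha
    raise ConfigurationError(f"region material must be hyperelastic, got {material!r}")


class _ElementBlock:
    """Vectorised element-level internal-force evaluation."""

    def __init__(self, mesh: Mesh, materials: dict, bulk_factor: float):
        missing = set(np.unique(mesh.regions)) - set(materials)
        if missing:
            raise ConfigurationError(f"no material for regions {sorted(missing)}")
        self.mesh = mesh
        Xe = mesh.nodes[mesh.elems]  # (m, 4, 2)
        self.Xe = Xe
        m = Xe.shape[0]

        def grads(dN):
            # Jref_ij = sum_a X_ai dN_aj -> (m, g, 2, 2)
            Jref = np.einsum("mai,gaj->mgij", Xe, dN)
            det = Jref[..., 0, 0] * Jref[..., 1, 1] - Jref[..., 0, 1] * Jref[..., 1, 0]
            if np.any(det <= 0.0):
                raise ConfigurationError("non-positive reference Jacobian")
            inv = np.empty_like(Jref)
            inv[..., 0, 0] = Jref[..., 1, 1]
            inv[..., 1, 1] = Jref[..., 0, 0]
            inv[..., 0, 1] = -Jref[..., 0, 1]
            inv[..., 1, 0] = -Jref[..., 1, 0]
            inv /= det[..., None, None]
            # dN/dX_a,i = dN_aj inv_ji
            dNdX = np.einsum("gaj,mgji->mgai", dN, inv)
            return dNdX, det

        self.dNdX, self.detJ = grads(_DN_GP)          # (m,4,4,2), (m,4)
        self.dNdX0, self.detJ0 = grads(_DN_C)
        self.dNdX0 = self.dNdX0[:, 0]                 # (m,4,2)

        mu = np.empty(m)
        alpha = np.empty(m)
        for region in np.unique(mesh.regions):
            mu_r, a_r = _ogden_params(materials[region])
            sel = mesh.regions == region
            mu[sel] = mu_r
            alpha[sel] = a_r
        self.mu = mu[:, None]
        self.alpha = alpha[:, None]
        self.kappa = bulk_factor * mu  # (m,)
        self.max_mu = float(mu.max())

        # global dof indices per element, interleaved (x0, y0, x1, y1, ...)
        conn = mesh.elems
        self.edofs = np.empty((m, 8), dtype=np.int64)
        self.edofs[:, 0::2] = 2 * conn
        self.edofs[:, 1::2] = 2 * conn + 1

    def forces(self, ue: np.ndarray, want_fields: bool = False):
        """Internal nodal forces (..., m, 4, 2) for element displacements ``ue``.

        ``ue`` may carry leading batch dimensions (used to evaluate all
        finite-difference perturbations of the tangent in one vectorised
        call).
        """

        # H_ij = sum_a ue_ai dNdX_aj  via batched matmul; F = I + H
        ueT = np.swapaxes(ue, -1, -2)  # (..., m, 2, 4)
        H = np.matmul(ueT[..., None, :, :], self.dNdX)  # (..., m, g, 2, 2)
        F = H.copy()
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
        if np.any(J <= 1e-9):
            raise _InversionError("element inverted")
        H0 = np.matmul(ueT, self.dNdX0)  # (..., m, 2, 2)
        J0 = ((1.0 + H0[..., 0, 0]) * (1.0 + H0[..., 1, 1])
              - H0[..., 0, 1] * H0[..., 1, 0])
        if np.any(J0 <= 1e-9):
            raise _InversionError("element inverted at centroid")

        # principal stretches of b = F F^T (lam3 = 1, plane strain)
        b11 = F[..., 0, 0] ** 2 + F[..., 0, 1] ** 2
        b22 = F[..., 1, 0] ** 2 + F[..., 1, 1] ** 2
        b12 = F[..., 0, 0] * F[..., 1, 0] + F[..., 0, 1] * F[..., 1, 1]
        tr2 = 0.5 * (b11 + b22)
        disc = np.sqrt(np.maximum(0.25 * (b11 - b22) ** 2 + b12**2, 0.0))
        ev1 = np.maximum(tr2 + disc, 1e-18)
        ev2 = np.maximum(tr2 - disc, 1e-18)

        Jm = J ** (-1.0 / 3.0)
        lb1 = Jm * np.sqrt(ev1)
        lb2 = Jm * np.sqrt(ev2)
        lb3 = Jm
        al = self.alpha  # (m, 1), broadcasts over gauss points
        A1 = lb1**al
        A2 = lb2**al
        A3 = lb3**al
        mean = (A1 + A2 + A3) / 3.0
        coef = 2.0 * self.mu / (al * J)
        s1 = coef * (A1 - mean)
        s2 = coef * (A2 - mean)
        s3 = coef * (A3 - mean)

        # sigma_2x2 = phi0 I + phi1 b (isotropic function of b)
        denom = ev1 - ev2
        small = denom < 1e-12 * np.maximum(ev1, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            phi1 = np.where(small, 0.0, (s1 - s2) / np.where(small, 1.0, denom))
        phi0 = np.where(small, 0.5 * (s1 + s2), s1 - phi1 * ev1)

        pvol = (self.kappa * (J0 - 1.0))[..., None]  # (..., m, 1) over gp
        s11 = phi0 + phi1 * b11 + pvol
        s22 = phi0 + phi1 * b22 + pvol
        s12 = phi1 * b12
        s33 = s3 + pvol

        # spatial gradients: dN/dx = dN/dX F^{-1}
        Finv = np.empty_like(F)
        Finv[..., 0, 0] = F[..., 1, 1]
        Finv[..., 1, 1] = F[..., 0, 0]
        Finv[..., 0, 1] = -F[..., 0, 1]
        Finv[..., 1, 0] = -F[..., 1, 0]
        Finv /= J[..., None, None]
        dNdx = np.matmul(self.dNdX, Finv)  # (..., m, g, 4, 2)

        sig = np.empty(s11.shape + (2, 2))
        sig[..., 0, 0] = s11
        sig[..., 1, 1] = s22
        sig[..., 0, 1] = s12
        sig[..., 1, 0] = s12
        wvol = self.detJ * J  # gauss weight 1 each
        # f_ai = sum_g w sigma_ij dN_a/dx_j (sigma symmetric)
        f = (np.matmul(dNdx, sig) * wvol[..., None, None]).sum(axis=-3)

        if not want_fields:
            return f, None
        fields = {
            "F": F,
            "J": J,
            "J_bar": J0,
            "stress": np.stack([s11, s22, s12, s33], axis=-1),
        }
        return f, fields


def gauss_point_coords(mesh: Mesh, u: np.ndarray | None = None) -> np.ndarray:
    """Coordinates of the 2x2 Gauss points per element, shape (m, 4, 2).

    ``u`` (n_nodes, 2) deforms the mesh when given; used to compare
    integration-point fields with analytic radial solutions.
    """

    coords = mesh.nodes if u is None else mesh.nodes + u
    xe = coords[mesh.elems]  # (m, 4, 2)
    N = np.empty((4, 4))
    for g, (xi, eta) in enumerate(_GAUSS):
        for a, (xa, ea) in enumerate(_CORNERS):
            N[g, a] = 0.25 * (1.0 + xa * xi) * (1.0 + ea * eta)
    return np.einsum("ga,mai->mgi", N, xe)


def apply_pressure_load(positions: np.ndarray, pressure: float,
                        side: str = "inside", closed: bool = True) -> np.ndarray:
    """Consistent nodal forces of a uniform pressure on an ordered polyline.

    ``positions`` (k, 2) are the current boundary node positions ordered
    counter-clockwise around the enclosed region.  ``side='inside'``
    applies the pressure from the enclosed side (pushing outward across
    the boundary); ``'outside'`` pushes inward.  Returns (k, 2) forces in
    mN per unit thickness.  On a closed loop the resultant vanishes.
    """

    x = np.asarray(positions, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need at least two boundary points")
    sgn = {"inside": 1.0, "outside": -1.0}[side]
    if closed:
        t = np.roll(x, -1, axis=0) - x
    else:
        t = x[1:] - x[:-1]
    if np.any(np.linalg.norm(t, axis=1) < 1e-14):
        raise ValueError("zero-length boundary edge")
    f_edge = sgn * pressure * np.column_stack([t[:, 1], -t[:, 0]])
    f = np.zeros_like(x)
    if closed:
        f += 0.5 * f_edge
        f += 0.5 * np.roll(f_edge, 1, axis=0)
    else:
        f[:-1] += 0.5 * f_edge
        f[1:] += 0.5 * f_edge
    return f


class _Model:
    """Assembled problem: elements, loads, constraints, contacts."""

    def __init__(self, mesh, materials, loading, contacts, config):
        self.mesh = mesh
        self.loading = loading
        self.config = config
        self.block = _ElementBlock(mesh, materials, config.bulk_factor)
        self.ndof = 2 * mesh.n_nodes

        h = mesh.target_h or float(np.sqrt(np.median(np.abs(mesh.element_areas()))))
        self.kn = config.penalty_contact_stiffness or 100.0 * self.block.max_mu / h
        self.kt = self.kn
        self.du_cap = config.max_du if config.max_du is not None else max(h, 0.05)

        # Dirichlet constraints
        fixed = np.zeros(self.ndof, dtype=bool)
        values = np.zeros(self.ndof)
        if loading.auto_symmetry:
            if mesh.quarter:
                fixed[2 * mesh.node_sets["symmetry_x"] + 1] = True
                fixed[2 * mesh.node_sets["symmetry_y"]] = True
            else:
                self._fix_rigid_modes(fixed)
        for ids, comp in loading.fixed:
            fixed[2 * np.asarray(ids, dtype=np.int64) + comp] = True
        self.dirichlet = []
        for ids, comp, vals in loading.dirichlet:
            ids = np.asarray(ids, dtype=np.int64)
            dofs = 2 * ids + comp
            fixed[dofs] = True
            self.dirichlet.append((dofs, np.asarray(vals, dtype=float)))
        self.fixed = fixed
        self.free = ~fixed

        # pressure loads
        self.pressure_loads = []
        for pl in loading.pressures:
            if pl.loop not in mesh.loops:
                raise ConfigurationError(f"mesh has no boundary loop {pl.loop!r}")
            loop = mesh.loops[pl.loop]
            self.pressure_loads.append((loop, pl.pressure, pl.side))

        # contacts
        self.contacts = []
        for pair in contacts or []:
            if pair.surface not in mesh.loops:
                raise ConfigurationError(f"mesh has no boundary loop {pair.surface!r}")
            loop = mesh.loops[pair.surface]
            trib = mesh.tributary_lengths(pair.surface)
            if pair.kind == "self_lumen":
                mu_f = (config.friction_lumen_self if pair.friction is None
                        else pair.friction)
                if mesh.quarter:
                    # mirror symmetry: self-contact reduces to frictionless
                    # unilateral contact with the symmetry plane y = 0
                    obj = PlaneContact(loop, normal=(0.0, 1.0),
                                       point_fn=np.zeros(2), mu_f=0.0,
                                       kn=self.kn, kt=self.kt, trib=trib,
                                       g_tol=config.g_tol)
                else:
                    obj = LumenSelfContact(loop, kn=self.kn, trib=trib,
                                           g_tol=config.g_tol)
            else:
                mu_f = (config.friction_device_tissue if pair.friction is None
                        else pair.friction)
                obj = RigidCircleContact(loop, pair.circles_fn, mu_f=mu_f,
                                         kn=self.kn, kt=self.kt, trib=trib,
                                         g_tol=config.g_tol)
            self.contacts.append(obj)

    def _fix_rigid_modes(self, fixed):
        outer = self.mesh.loops["outer_boundary"]
        xy = self.mesh.nodes[outer]
        fixed[2 * outer[int(np.argmax(xy[:, 0]))] + 1] = True
        fixed[2 * outer[int(np.argmin(xy[:, 0]))] + 1] = True
        fixed[2 * outer[int(np.argmax(xy[:, 1]))]] = True

    # ------------------------------------------------------------------
    def prescribed(self, lf: float) -> np.ndarray:
        vals = np.zeros(self.ndof)
        for dofs, v in self.dirichlet:
            vals[dofs] = lf * v
        return vals

    def residual(self, u: np.ndarray, lf: float, want_fields: bool = False,
                 refresh_pairing: bool = True):
        """Global residual f_int - f_ext - f_contact and its pieces.

        ``refresh_pairing=False`` keeps the current self-contact pairing
        (used to polish Newton iterates: re-pairing at every evaluation can
        cycle between two equivalent assignments below discretisation
        accuracy)."""

        mesh = self.mesh
        ue = u.reshape(-1, 2)[mesh.elems]
        fe, fields = self.block.forces(ue, want_fields=want_fields)
        fint = np.zeros(self.ndof)
        np.add.at(fint, self.block.edofs.ravel(), fe.reshape(fe.shape[0], -1).ravel())

        coords = mesh.nodes + u.reshape(-1, 2)
        fext = np.zeros(self.ndof)
        for loop, p, side in self.pressure_loads:
            f = apply_pressure_load(coords[loop], lf * p, side=side,
                                    closed=not mesh.quarter)
            np.add.at(fext, 2 * loop, f[:, 0])
            np.add.at(fext, 2 * loop + 1, f[:, 1])

        fc = np.zeros(self.ndof)
        infos = []
        for c in self.contacts:
            if isinstance(c, LumenSelfContact):
                f, info = c.forces(coords[c.node_ids], lf,
                                   refresh=refresh_pairing)
            else:
                f, info = c.forces(coords[c.node_ids], lf)
            np.add.at(fc, 2 * c.node_ids, f[:, 0])
            np.add.at(fc, 2 * c.node_ids + 1, f[:, 1])
            infos.append(info)

        r = fint - fext - fc
        data = {
            "fint": fint, "fext": fext, "fc": fc,
            "fields": fields, "contact_infos": infos,
        }
        return r, data

    def tangent(self, u: np.ndarray, lf: float) -> sp.csr_matrix:
        """FD element tangent + analytic load stiffness + FD contact tangent."""

        mesh = self.mesh
        ue0 = u.reshape(-1, 2)[mesh.elems]
        f0, _ = self.block.forces(ue0)
        m = ue0.shape[0]
        h = _FD_STEP
        batch = np.broadcast_to(ue0, (8,) + ue0.shape).copy()
        for j in range(8):
            batch[j, :, j // 2, j % 2] += h
        fb, _ = self.block.forces(batch)  # (8, m, 4, 2)
        # column j of the element tangent from perturbation j
        Ke = (fb - f0).reshape(8, m, 8).transpose(1, 2, 0) / h
        # Ke[:, i, j] = d f_i / d u_j; rows repeat i (slow), cols tile j (fast)
        rows = np.repeat(self.block.edofs, 8, axis=1).ravel()
        cols = np.tile(self.block.edofs, (1, 8)).ravel()
        vals = Ke.reshape(m, 64).ravel()

        all_rows = [rows]
        all_cols = [cols]
        all_vals = [vals]

        coords = mesh.nodes + u.reshape(-1, 2)
        # analytic follower-load stiffness: subtract d f_ext / du
        R90 = np.array([[0.0, 1.0], [-1.0, 0.0]])
        for loop, p, side in self.pressure_loads:
            sgn = 1.0 if side == "inside" else -1.0
            edges = (np.column_stack([loop, np.roll(loop, -1)])
                     if not mesh.quarter else np.column_stack([loop[:-1], loop[1:]]))
            B = sgn * (lf * p) * R90  # d f_edge / d x_b = B ; d/d x_a = -B
            for a, b in edges:
                for na in (a, b):  # each end node receives f_edge / 2
                    for nb, sb in ((a, -0.5), (b, 0.5)):
                        blk = sb * B
                        r0 = np.repeat([2 * na, 2 * na + 1], 2)
                        c0 = np.tile([2 * nb, 2 * nb + 1], 2)
                        all_rows.append(r0)
                        all_cols.append(c0)
                        # K = d(fint - fext)/du -> minus load stiffness
                        all_vals.append(-blk.ravel())

        # contact tangents by finite differences on involved nodes
        for c in self.contacts:
            ids = c.node_ids
            xn0 = coords[ids]
            if isinstance(c, LumenSelfContact):
                f0c, _ = c.forces(xn0, lf, refresh=False)
                local_sets = c.involved_locals()
                involved = sorted({i for trip in local_sets for i in trip})
                for iloc in involved:
                    for comp in range(2):
                        xp = xn0.copy()
                        xp[iloc, comp] += h
                        fp, _ = c.forces(xp, lf, refresh=False)
                        dcol = (fp - f0c) / h
                        nz = np.nonzero(np.abs(dcol).sum(axis=1))[0]
                        for jloc in nz:
                            r0 = np.array([2 * ids[jloc], 2 * ids[jloc] + 1])
                            c0 = np.full(2, 2 * ids[iloc] + comp)
                            all_rows.append(r0)
                            all_cols.append(c0)
                            all_vals.append(-dcol[jloc])
            else:
                f0c, _ = c.forces(xn0, lf)
                for comp in range(2):
                    xp = xn0.copy()
                    xp[:, comp] += h
                    fp, _ = c.forces(xp, lf)
                    dcol = (fp - f0c) / h  # (k, 2): d f_k / d x_k,comp
                    r0 = np.column_stack([2 * ids, 2 * ids + 1]).ravel()
                    c0 = np.repeat(2 * ids + comp, 2)
                    all_rows.append(r0)
                    all_cols.append(c0)
                    all_vals.append(-dcol.ravel())

        K = sp.coo_matrix(
            (np.concatenate([np.asarray(v).ravel() for v in all_vals]),
             (np.concatenate(all_rows), np.concatenate(all_cols))),
            shape=(self.ndof, self.ndof),
        ).tocsr()
        return K


def _max_penetration(data) -> float:
    infos = data.get("contact_infos") or []
    return max((i.get("max_penetration", 0.0) for i in infos), default=0.0)


def _ref_scale(data, free):
    # reference on the full vectors: in pure-Dirichlet problems the free
    # part of f_int vanishes at equilibrium while the reactions set the
    # physically meaningful force scale
    return max(
        float(np.linalg.norm(data["fext"])),
        float(np.linalg.norm(data["fint"])),
        float(np.linalg.norm(data["fc"])),
        1e-12,
    )


def _newton(model: _Model, u: np.ndarray, lf: float):
    cfg = model.config
    u = u.copy()
    presc = model.prescribed(lf)
    u[model.fixed] = presc[model.fixed]
    free = model.free

    bad = 0
    rn = np.inf
    refresh = True
    for it in range(cfg.max_newton_iter):
        try:
            r, data = model.residual(u, lf, refresh_pairing=refresh)
        except _InversionError:
            return u, False, np.inf, it
        rn = float(np.linalg.norm(r[free]))
        ref = _ref_scale(data, free)
        if rn <= cfg.newton_tol * ref:
            return u, True, rn, it
        # freeze self-contact pairing once the iterate is close: pairing
        # updates below discretisation accuracy can cycle between two
        # equivalent assignments and stall the polish phase
        refresh = rn > 1e-3 * ref
        K = model.tangent(u, lf)
        Kff = K[free][:, free]
        try:
            du = spla.spsolve(Kff.tocsc(), -r[free])
        except Exception:
            return u, False, rn, it
        if not np.all(np.isfinite(du)):
            return u, False, rn, it
        # cap the increment so contacting faces cannot tunnel through
        # each other between two pairing updates
        du_max = float(np.abs(du).max())
        if du_max > model.du_cap:
            du *= model.du_cap / du_max

        # Backtracking line search.  A full Newton step under follower
        # loads or fresh contact often raises the residual transiently
        # before quadratic convergence sets in, so a bounded increase at
        # full step length is tolerated (counted and capped).  Trial
        # iterates that drive contact penetration far beyond its current
        # depth are rejected: the penalty linearisation is useless there.
        pen_now = _max_penetration(data)
        pen_limit = max(10.0 * cfg.g_tol, 0.1 * model.du_cap, 1.5 * pen_now)
        alpha = 1.0
        accepted = False
        while alpha >= 1.0 / 32.0:
            u_try = u.copy()
            u_try[free] += alpha * du
            try:
                r_try, data_try = model.residual(u_try, lf,
                                                 refresh_pairing=refresh)
            except _InversionError:
                alpha *= 0.5
                continue
            rn_try = float(np.linalg.norm(r_try[free]))
            if _max_penetration(data_try) > pen_limit and alpha > 1.0 / 32.0:
                alpha *= 0.5
                continue
            if (rn_try < 0.99 * rn
                    or (alpha == 1.0 and rn_try < 1e4 * rn)
                    or alpha <= 1.0 / 32.0):
                accepted = True
                break
            alpha *= 0.5
        if not accepted:
            return u, False, rn, it
        if rn_try >= rn:
            bad += 1
            if bad >= 4:
                return u, False, rn_try, it
        else:
            bad = 0
        u = u_try
    return u, False, rn, cfg.max_newton_iter


def _advance(model, u, lf0, lf1, depth=0):
    """March from load factor lf0 to lf1 with adaptive halving/regrowth.

    The increment halves on Newton failure and regrows by 1.5x after a
    success, with a floor a few halvings below ``max_cutbacks`` relative to
    the target interval (contact engagement on soft tissue can demand very
    small local increments while the rest of the ramp runs at full step).
    """

    dlf_base = lf1 - lf0
    dlf_min = max(1e-6, dlf_base * 0.5 ** (model.config.max_cutbacks + 3))
    lf = lf0
    dlf = dlf_base
    rn, it = np.inf, 0
    while lf < lf1 - 1e-12:
        trial = min(lf + dlf, lf1)
        u1, ok, rn, it = _newton(model, u, trial)
        if ok:
            u = u1
            lf = trial
            if lf < lf1 - 1e-12:
                coords = model.mesh.nodes + u.reshape(-1, 2)
                for c in model.contacts:
                    c.update_anchors(coords[c.node_ids], lf)
            dlf = min(dlf * 1.5, dlf_base)
        else:
            dlf *= 0.5
            if dlf < dlf_min:
                return u, False, rn, it
    return u, True, rn, it


def solve(mesh: Mesh, materials: dict, loading: LoadScenario,
          contacts=(), config: SolverConfig | None = None,
          log=None) -> list[SolutionState]:
    """Quasi-static incremental solution of the loaded cross-section.

    Returns one converged :class:`SolutionState` per entry of the loading
    ramp, ordered by load factor.  Raises :class:`DivergenceError` (with
    the partial state list attached) if an increment cannot be converged
    after all adaptive cutbacks.
    """

    config = config or SolverConfig()
    model = _Model(mesh, materials, loading, contacts, config)
    u = np.zeros(model.ndof)
    states: list[SolutionState] = []
    lf_prev = 0.0
    for lf in loading.ramp:
        u, ok, rn, it = _advance(model, u, lf_prev, float(lf), depth=0)
        if not ok:
            raise DivergenceError(
                f"no convergence at load factor {lf:.4g} (residual {rn:.3g})",
                states=states,
            )
        r, data = model.residual(u, float(lf), want_fields=True)
        coords = mesh.nodes + u.reshape(-1, 2)
        for c in model.contacts:
            c.update_anchors(coords[c.node_ids], float(lf))
        fields = data["fields"]
        state = SolutionState(
            u=u.reshape(-1, 2).copy(),
            load_factor=float(lf),
            F=fields["F"],
            J=fields["J"],
            J_bar=fields["J_bar"],
            stress=fields["stress"],
            gp_weight=model.block.detJ.copy(),
            residual_norm=float(np.linalg.norm(r[model.free])),
            n_iter=it,
            contact_info={"per_contact": data["contact_infos"]},
        )
        states.append(state)
        if log is not None:
            log.append((float(lf), it, state.residual_norm))
        lf_prev = float(lf)
    return states
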