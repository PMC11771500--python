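"""Penalty contact for the cross-section simulations.

Normal contact is "hard" in the model sense — enforced by a stiff penalty
on penetration (default stiffness 100 x max tissue modulus / element size,
giving penetrations of the order of the 1e-3 mm gap tolerance at the
working contact pressures).  Tangential response is a penalty-regularised
Coulomb law: an elastic stick stiffness resists slip measured from an
anchor point, capped at ``mu_f`` times the normal force; anchors are
return-mapped after each converged load step, so friction is treated
incrementally per step.

Three contact conditions appear in the scenarios:

* ``RigidCircleContact`` — tissue nodes against a union of rigid circles
  (the intraluminal device body and its expanding arm tips), with friction.
* ``PlaneContact`` — tissue nodes against a fixed or moving rigid plane;
  used both for elementary verification (flat punch) and as the
  quarter-symmetry reduction of lumen self-contact, where mirror symmetry
  makes the contact plane the symmetry plane and relative slip vanishes.
* ``LumenSelfContact`` — node-to-segment contact of the lumen boundary
  against itself in full-model mode.  The tangential term is neglected
  here: the prescribed self-friction coefficient (0.02) caps tangential
  tractions at 2% of the normal ones and the closing motion is nearly
  slip-free, so the omission is well below discretisation error.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "ContactInstabilityError",
    "RigidCircleContact",
    "PlaneContact",
    "LumenSelfContact",
]


class ContactInstabilityError(RuntimeError):
    """Penetration exceeded 10x the gap tolerance at a converged state;
    suggests a stiffer penalty or smaller load steps."""


def _wrap_angle(a: np.ndarray) -> np.ndarray:
    return (a + np.pi) % (2.0 * np.pi) - np.pi


def _penalty_force(penetration, kn_trib, g_tol):
    """C1-smooth penalty magnitude: quadratic up to ``g_tol``, linear beyond.

    Smooth activation avoids the derivative jump at first touch that
    otherwise destabilises Newton when many nodes engage simultaneously.
    """

    p = np.maximum(penetration, 0.0)
    return kn_trib * np.where(p <= g_tol, 0.5 * p * p / g_tol, p - 0.5 * g_tol)


def _coulomb(trial: np.ndarray, cap: np.ndarray) -> np.ndarray:
    """Smoothly saturated Coulomb friction force.

    ``trial`` is the elastic stick force ``kt * trib * slip``; the result
    matches it for small slip and saturates to ``cap = mu_f * N`` through a
    tanh regularisation, keeping the residual smooth for Newton.
    """

    safe = np.maximum(cap, 1e-30)
    return np.where(cap > 0.0, safe * np.tanh(trial / safe), 0.0)


class RigidCircleContact:
    """Tissue nodes against a rigid union of circles following the load factor.

    ``circles_fn(load_factor)`` returns an (c, 3) array of (cx, cy, R).
    The gap to the union of circles is smoothed with a log-sum-exp softmin
    (width ``smooth`` mm) and the contact normal is the matching blend of
    the individual circle normals, so the residual stays smooth where
    circles meet or overlap (the arm tips are internally tangent to the
    device body when they start to deploy).  Friction uses spatial anchor
    points return-mapped after each converged load step.
    """

    def __init__(self, node_ids, circles_fn, mu_f, kn, kt, trib, g_tol=1e-3,
                 smooth=5e-3):
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        self.circles_fn = circles_fn
        self.mu_f = float(mu_f)
        self.kn = float(kn)
        self.kt = float(kt)
        self.trib = np.asarray(trib, dtype=float)
        self.g_tol = float(g_tol)
        self.smooth = float(smooth)
        self.anchor = np.full((self.node_ids.size, 2), np.nan)

    def _gap_normal(self, xn, load_factor):
        circles = np.atleast_2d(np.asarray(self.circles_fn(load_factor), dtype=float))
        d = xn[:, None, :] - circles[None, :, :2]
        dist = np.maximum(np.linalg.norm(d, axis=2), 1e-12)
        gaps = dist - circles[None, :, 2]
        w = self.smooth
        a = -gaps / w
        amax = a.max(axis=1, keepdims=True)
        e = np.exp(a - amax)
        g = -w * (np.log(e.sum(axis=1)) + amax[:, 0])
        wts = e / e.sum(axis=1, keepdims=True)
        n = (wts[:, :, None] * d / dist[:, :, None]).sum(axis=1)
        n /= np.maximum(np.linalg.norm(n, axis=1, keepdims=True), 1e-12)
        return g, n

    def forces(self, xn: np.ndarray, load_factor: float):
        """Nodal forces (k, 2) on the contact nodes plus diagnostics."""

        g, n = self._gap_normal(xn, load_factor)
        active = g < 0.0
        fn_mag = _penalty_force(-g, self.kn * self.trib, self.g_tol)
        f = fn_mag[:, None] * n

        if self.mu_f > 0.0:
            t = np.column_stack([-n[:, 1], n[:, 0]])
            rel = xn - np.where(np.isnan(self.anchor), xn, self.anchor)
            s = np.einsum("ki,ki->k", rel, t)
            ft = -_coulomb(self.kt * self.trib * s, self.mu_f * fn_mag)
            f = f + np.where(active, ft, 0.0)[:, None] * t

        info = {
            "active": active,
            "normal_force": fn_mag,
            "max_penetration": float(max(0.0, -g.min())) if g.size else 0.0,
        }
        return f, info

    def update_anchors(self, xn: np.ndarray, load_factor: float) -> None:
        """Return-map friction anchors after a converged step and check
        the penetration against the instability bound."""

        g, n = self._gap_normal(xn, load_factor)
        max_pen = float(max(0.0, -g.min())) if g.size else 0.0
        if max_pen > 10.0 * self.g_tol:
            raise ContactInstabilityError(
                f"penetration {max_pen:.3g} mm exceeds {10 * self.g_tol:.3g} mm; "
                "use a stiffer penalty or smaller steps"
            )
        active = g < 0.0
        t = np.column_stack([-n[:, 1], n[:, 0]])
        fn_mag = _penalty_force(-g, self.kn * self.trib, self.g_tol)
        with np.errstate(invalid="ignore", divide="ignore"):
            s_max = self.mu_f * fn_mag / np.maximum(self.kt * self.trib, 1e-30)
        rel = xn - np.where(np.isnan(self.anchor), xn, self.anchor)
        s = np.clip(np.einsum("ki,ki->k", rel, t), -s_max, s_max)
        # anchor keeps only the bounded tangential offset; normal drift is
        # discarded so the stick force tracks the moving rigid surface
        self.anchor[active] = xn[active] - s[active, None] * t[active]
        self.anchor[~active] = np.nan


class PlaneContact:
    """Tissue nodes against a rigid half-space ``dot(x - point, normal) >= 0``.

    ``point_fn(load_factor)`` positions the plane; ``normal`` points from
    the surface into the admissible half-space.  ``mu_f = 0`` gives the
    frictionless case (symmetry-plane self-contact, frictionless punch).
    """

    def __init__(self, node_ids, normal, point_fn, mu_f, kn, kt, trib, g_tol=1e-3):
        self.node_ids = np.asarray(node_ids, dtype=np.int64)
        normal = np.asarray(normal, dtype=float)
        self.normal = normal / np.linalg.norm(normal)
        self.tangent = np.array([-self.normal[1], self.normal[0]])
        self.point_fn = point_fn if callable(point_fn) else (lambda lf, p=point_fn: p)
        self.mu_f = float(mu_f)
        self.kn = float(kn)
        self.kt = float(kt)
        self.trib = np.asarray(trib, dtype=float)
        self.g_tol = float(g_tol)
        self.anchor_s = np.full(self.node_ids.size, np.nan)

    def forces(self, xn: np.ndarray, load_factor: float):
        point = np.asarray(self.point_fn(load_factor), dtype=float)
        g = (xn - point) @ self.normal
        active = g < 0.0
        fn_mag = _penalty_force(-g, self.kn * self.trib, self.g_tol)
        f = fn_mag[:, None] * self.normal[None, :]
        if self.mu_f > 0.0:
            s_now = xn @ self.tangent
            s0 = np.where(np.isnan(self.anchor_s), s_now, self.anchor_s)
            ft = -_coulomb(self.kt * self.trib * (s_now - s0), self.mu_f * fn_mag)
            f = f + np.where(active, ft, 0.0)[:, None] * self.tangent[None, :]
        info = {
            "active": active,
            "normal_force": fn_mag,
            "max_penetration": float(max(0.0, -g.min())) if g.size else 0.0,
        }
        return f, info

    def update_anchors(self, xn: np.ndarray, load_factor: float) -> None:
        f, info = self.forces(xn, load_factor)
        if info["max_penetration"] > 10.0 * self.g_tol:
            raise ContactInstabilityError(
                f"penetration {info['max_penetration']:.3g} mm exceeds "
                f"{10 * self.g_tol:.3g} mm; use a stiffer penalty or smaller steps"
            )
        active = info["active"]
        s_now = xn @ self.tangent
        newly = active & np.isnan(self.anchor_s)
        self.anchor_s[newly] = s_now[newly]
        with np.errstate(invalid="ignore", divide="ignore"):
            s_max = self.mu_f * info["normal_force"] / np.maximum(self.kt * self.trib, 1e-30)
        s = s_now - self.anchor_s
        slid = active & ~np.isnan(self.anchor_s) & (np.abs(s) > s_max)
        self.anchor_s[slid] = s_now[slid] - np.sign(s[slid]) * s_max[slid]
        self.anchor_s[~active] = np.nan


class LumenSelfContact:
    """Node-to-segment self-contact of the (closed, CCW) lumen boundary.

    Pairing is refreshed at the start of every Newton iteration and frozen
    during residual/tangent evaluation for smoothness.  A node is paired
    with the nearest non-neighbouring segment within the search radius; the
    gap is the signed distance along the segment's cavity-side normal and
    penetration (negative gap) is penalised, pushing the opposing faces
    apart.  Normal-only (see module docstring).
    """

    def __init__(self, loop_ids, kn, trib, g_tol=1e-3, exclude=2, search_radius=None):
        self.loop = np.asarray(loop_ids, dtype=np.int64)
        self.kn = float(kn)
        self.trib = np.asarray(trib, dtype=float)
        self.g_tol = float(g_tol)
        self.exclude = int(exclude)
        self.search_radius = search_radius
        self.pairs: np.ndarray = np.empty((0, 2), dtype=np.int64)  # (slave local, seg idx)

    @property
    def node_ids(self):
        return self.loop

    def _segments(self):
        n = self.loop.size
        return np.column_stack([np.arange(n), (np.arange(n) + 1) % n])

    def update_pairing(self, xn: np.ndarray) -> None:
        """Refresh slave-node/master-segment assignments from positions ``xn``
        of the loop nodes (local ordering)."""

        n = self.loop.size
        segs = self._segments()
        a = xn[segs[:, 0]]
        b = xn[segs[:, 1]]
        ab = b - a
        seg_len = np.linalg.norm(ab, axis=1)
        r_search = self.search_radius or 3.0 * max(seg_len.max(), 1e-6)
        L2 = np.maximum(np.sum(ab * ab, axis=1), 1e-24)

        diff = xn[:, None, :] - a[None, :, :]                    # (n, s, 2)
        xi = np.clip(np.einsum("nsj,sj->ns", diff, ab) / L2, 0.0, 1.0)
        proj = a[None] + xi[..., None] * ab[None]
        dd = np.linalg.norm(xn[:, None, :] - proj, axis=2)       # (n, s)

        idx = np.arange(n)
        d0 = np.abs((segs[:, 0][None, :] - idx[:, None] + n // 2) % n - n // 2)
        d1 = np.abs((segs[:, 1][None, :] - idx[:, None] + n // 2) % n - n // 2)
        dd[(d0 <= self.exclude) | (d1 <= self.exclude) | (dd >= r_search)] = np.inf

        best = np.argmin(dd, axis=1)
        has = np.isfinite(dd[idx, best])
        self.pairs = np.column_stack([idx[has], best[has]]).astype(np.int64)

    def forces(self, xn: np.ndarray, load_factor: float, refresh: bool = True):
        """Forces on the loop nodes (local ordering).

        By default the pairing is refreshed from the supplied positions, so
        the penalty always acts against the current nearest opposing
        segment even when an iterate moves by a large fraction of the
        element size; ``refresh=False`` keeps the existing pairing (used
        for finite-difference perturbations of the tangent).
        """

        if refresh:
            self.update_pairing(xn)
        f = np.zeros_like(xn)
        max_pen = 0.0
        n_active = 0
        segs = self._segments()
        for i, k in self.pairs:
            ia, ib = segs[k]
            a, b_ = xn[ia], xn[ib]
            ab = b_ - a
            L = np.linalg.norm(ab)
            if L < 1e-12:
                continue
            t = ab / L
            n_cav = np.array([-t[1], t[0]])  # cavity side of a CCW loop
            xi = float(np.clip((xn[i] - a) @ ab / (L * L), 0.0, 1.0))
            g = float((xn[i] - (a + xi * ab)) @ n_cav)
            if g >= 0.0:
                continue
            fN = float(_penalty_force(-g, self.kn * self.trib[i], self.g_tol))
            f[i] += fN * n_cav
            f[ia] -= (1.0 - xi) * fN * n_cav
            f[ib] -= xi * fN * n_cav
            max_pen = max(max_pen, -g)
            n_active += 1
        info = {"max_penetration": max_pen, "n_active": n_active}
        return f, info

    def update_anchors(self, xn: np.ndarray, load_factor: float) -> None:
        _, info = self.forces(xn, load_factor)
        if info["max_penetration"] > 10.0 * self.g_tol:
            raise ContactInstabilityError(
                f"self-contact penetration {info['max_penetration']:.3g} mm exceeds "
                f"{10 * self.g_tol:.3g} mm; use a stiffer penalty or smaller steps"
            )

    def involved_locals(self):
        """Local node indices whose dofs a pair's forces depend on."""

        segs = self._segments()
        out = []
        for i, k in self.pairs:
            out.append((i, segs[k, 0], segs[k, 1]))
        return out
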