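"""Cross-section meshing of the two-layer urethral wall.

The urethra is idealised as a circular cylinder (outer radius 5 mm) with an
elliptical lumen (full axes 1.6 mm and 8 mm, i.e. semi-axes 0.8 and 4 mm)
lined by a 0.14 mm thick band of dense connective tissue; the remaining
wall is spongiosum.  The cross-section is meshed with a structured O-grid
of 4-node quadrilaterals: the lumen ellipse is sampled uniformly in arc
length, the lining is extruded as a conforming band of at least two element
layers along the local ellipse normal, and the spongiosum fills the gap to
the outer circle along straight rays.  A concentric two-layer annulus mesh
is provided for verification against the semi-analytic tube solution, and a
rectangular block mesh for elementary solver checks.

Axis lengths given for the lumen are full axes: halving them is required
for the lumen to fit inside the 5 mm outer radius.  Coordinates are in mm,
node indices 0-based.  Quarter-symmetry meshes cover the first quadrant
with nodes exactly on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CrossSectionSpec",
    "Mesh",
    "build_cross_section",
    "build_annulus",
    "build_block",
    "save_mesh",
    "load_mesh",
]

REGION_LINING = "lining"
REGION_SPONGIOSUM = "spongiosum"


@dataclass(frozen=True)
class CrossSectionSpec:
    """Printed urethral cross-section dimensions (mm).

    ``lumen_axis_min``/``lumen_axis_max`` are full ellipse axes; ``length``
    is the cylinder length, kept as reporting metadata only (the analysis
    is plane strain).
    """

    outer_radius: float = 5.0
    lumen_axis_min: float = 1.6
    lumen_axis_max: float = 8.0
    lining_thickness: float = 0.14
    length: float = 50.0

    def __post_init__(self) -> None:
        if not (0.0 < self.lumen_axis_min <= self.lumen_axis_max):
            raise ValueError("need 0 < lumen_axis_min <= lumen_axis_max")
        if self.lining_thickness <= 0.0:
            raise ValueError("lining_thickness must be positive")
        if self.lumen_axis_max / 2.0 + self.lining_thickness >= self.outer_radius:
            raise ValueError("lumen plus lining does not fit inside the outer radius")
        # the normal offset of the lining must stay below the smallest
        # curvature radius of the ellipse or the band folds onto itself
        rho_min = (self.lumen_axis_min / 2.0) ** 2 / (self.lumen_axis_max / 2.0)
        if self.lining_thickness >= rho_min:
            raise ValueError(
                f"lining thickness {self.lining_thickness} exceeds the minimum "
                f"ellipse curvature radius {rho_min:.4g}; offset band would fold"
            )

    @property
    def semi_axis_x(self) -> float:
        return self.lumen_axis_max / 2.0

    @property
    def semi_axis_y(self) -> float:
        return self.lumen_axis_min / 2.0


@dataclass
class Mesh:
    """Quadrilateral cross-section mesh with labelled regions and boundaries.

    ``loops`` are boundary node chains ordered counter-clockwise; in
    quarter-symmetry mode they are open polylines running from the +x axis
    to the +y axis, otherwise closed loops (first node not repeated).
    """

    nodes: np.ndarray
    elems: np.ndarray
    regions: np.ndarray
    node_sets: dict
    loops: dict
    quarter: bool
    target_h: float = 0.0

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def element_areas(self) -> np.ndarray:
        p = self.nodes[self.elems]  # (m, 4, 2)
        x, y = p[..., 0], p[..., 1]
        xn, yn = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.sum(x * yn - xn * y, axis=1)

    def region_area(self, region: str) -> float:
        return float(self.element_areas()[self.regions == region].sum())

    def total_area(self) -> float:
        return float(self.element_areas().sum())

    def validate(self) -> None:
        """Raise if any element corner Jacobian is non-positive or sets invalid."""

        p = self.nodes[self.elems]
        for k in range(4):
            a = p[:, (k + 1) % 4] - p[:, k]
            b = p[:, (k - 1) % 4] - p[:, k]
            cross = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
            if np.any(cross <= 0.0):
                bad = int(np.argmin(cross))
                raise ValueError(f"non-positive corner Jacobian in element {bad}")
        if self.elems.min() < 0 or self.elems.max() >= self.n_nodes:
            raise ValueError("element connectivity index out of range")
        for name, ids in self.node_sets.items():
            if len(ids) and (ids.min() < 0 or ids.max() >= self.n_nodes):
                raise ValueError(f"node set {name} out of range")

    def loop_edges(self, name: str) -> np.ndarray:
        """Boundary edges (pairs of node ids) along a named loop."""

        loop = self.loops[name]
        if self.quarter:
            return np.column_stack([loop[:-1], loop[1:]])
        return np.column_stack([loop, np.roll(loop, -1)])

    def tributary_lengths(self, name: str, coords: np.ndarray | None = None) -> np.ndarray:
        """Per-node tributary length (half the adjacent edge lengths) on a loop."""

        coords = self.nodes if coords is None else coords
        loop = self.loops[name]
        edges = self.loop_edges(name)
        L = np.linalg.norm(coords[edges[:, 1]] - coords[edges[:, 0]], axis=1)
        trib = np.zeros(loop.size)
        pos = {n: i for i, n in enumerate(loop)}
        for (a, b), length in zip(edges, L):
            trib[pos[a]] += 0.5 * length
            trib[pos[b]] += 0.5 * length
        return trib

    def lumen_polygon_area(self, displacements: np.ndarray | None = None) -> float:
        """Shoelace area of the (possibly deformed) lumen cavity.

        In quarter mode the open lumen polyline is closed through the
        origin, giving the area of the quarter cavity.
        """

        coords = self.nodes if displacements is None else self.nodes + displacements
        pts = coords[self.loops["lumen_boundary"]]
        if self.quarter:
            pts = np.vstack([pts, [0.0, 0.0]])
        x, y = pts[:, 0], pts[:, 1]
        return float(0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)))


def _snap_axes(pts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    pts = pts.copy()
    pts[np.abs(pts) < tol] = 0.0
    return pts


def _grid_mesh(rows, wrap: bool, region_rows, quarter: bool, target_h: float) -> Mesh:
    """Assemble a structured mesh from ordered point rows (inner to outer).

    ``rows`` is a list of (ncols, 2) arrays sharing ncols; ``region_rows``
    gives the region label of each element band between consecutive rows.
    """

    nrows = len(rows)
    ncols = rows[0].shape[0]
    nodes = _snap_axes(np.vstack(rows))

    def nid(r, c):
        return r * ncols + (c % ncols if wrap else c)

    ncol_e = ncols if wrap else ncols - 1
    elems = np.empty(((nrows - 1) * ncol_e, 4), dtype=np.int64)
    regions = np.empty((nrows - 1) * ncol_e, dtype="<U16")
    k = 0
    for r in range(nrows - 1):
        for c in range(ncol_e):
            elems[k] = (nid(r, c), nid(r + 1, c), nid(r + 1, c + 1), nid(r, c + 1))
            regions[k] = region_rows[r]
            k += 1

    row_ids = [np.arange(r * ncols, (r + 1) * ncols, dtype=np.int64) for r in range(nrows)]
    tol = 1e-9
    on_x = np.where(np.abs(nodes[:, 1]) < tol)[0]
    on_y = np.where(np.abs(nodes[:, 0]) < tol)[0]
    node_sets = {
        "lumen_boundary": row_ids[0].copy(),
        "outer_boundary": row_ids[-1].copy(),
        "symmetry_x": on_x,
        "symmetry_y": on_y,
    }
    loops = {"lumen_boundary": row_ids[0].copy(), "outer_boundary": row_ids[-1].copy()}
    mesh = Mesh(
        nodes=nodes,
        elems=elems,
        regions=regions,
        node_sets=node_sets,
        loops=loops,
        quarter=quarter,
        target_h=target_h,
    )
    mesh.validate()
    return mesh


def _quarter_ellipse_params(a: float, b: float, n_theta: int) -> np.ndarray:
    """Parameters t on [0, pi/2] spaced uniformly in ellipse arc length."""

    t_dense = np.linspace(0.0, np.pi / 2.0, 4001)
    dx = -a * np.sin(t_dense)
    dy = b * np.cos(t_dense)
    ds = np.hypot(dx, dy)
    s = np.concatenate([[0.0], np.cumsum(0.5 * (ds[1:] + ds[:-1]) * np.diff(t_dense))])
    s_targets = np.linspace(0.0, s[-1], n_theta + 1)
    return np.interp(s_targets, s, t_dense)


def _expand_full(row_q: np.ndarray) -> np.ndarray:
    """Expand a quarter row (theta 0..pi/2 inclusive) to a full closed row."""

    q1 = row_q[:-1]                                   # theta in [0, pi/2)
    q2 = row_q[:0:-1] * np.array([-1.0, 1.0])         # [pi/2, pi)
    q3 = row_q[:-1] * np.array([-1.0, -1.0])          # [pi, 3pi/2)
    q4 = row_q[:0:-1] * np.array([1.0, -1.0])         # [3pi/2, 2pi)
    return np.vstack([q1, q2, q3, q4])


def build_cross_section(
    spec: CrossSectionSpec,
    target_element_size: float = 0.2,
    quarter_symmetry: bool = True,
    n_lining_layers: int | None = None,
) -> Mesh:
    """Mesh the two-layer urethral cross-section.

    The lining band always gets at least two element layers through its
    thickness; the spongiosum ray length varies strongly around the
    ellipse, so its radial divisions follow the mean ray length.
    """

    h = float(target_element_size)
    if not (0.0 < h <= spec.lining_thickness * 4.0):
        raise ValueError(
            f"target_element_size must lie in (0, {spec.lining_thickness * 4.0}]"
        )
    a, b, T = spec.semi_axis_x, spec.semi_axis_y, spec.lining_thickness

    quarter_arc = _arc_length(a, b)
    n_theta = max(8, int(np.ceil(quarter_arc / h)))
    t = _quarter_ellipse_params(a, b, n_theta)
    ex, ey = a * np.cos(t), b * np.sin(t)
    nx, ny = b * np.cos(t), a * np.sin(t)
    nn = np.hypot(nx, ny)
    nx, ny = nx / nn, ny / nn

    n_lin = n_lining_layers or max(2, int(round(T / h)))
    rows_q = []
    for k in range(n_lin + 1):
        off = T * k / n_lin
        rows_q.append(np.column_stack([ex + off * nx, ey + off * ny]))

    q = rows_q[-1]
    u = q / np.linalg.norm(q, axis=1, keepdims=True)
    outer = spec.outer_radius * u
    ray = np.linalg.norm(outer - q, axis=1)
    n_rad = max(2, int(round(ray.mean() / h)))
    for k in range(1, n_rad + 1):
        f = k / n_rad
        rows_q.append(q + f * (outer - q))

    region_rows = [REGION_LINING] * n_lin + [REGION_SPONGIOSUM] * n_rad
    if quarter_symmetry:
        return _grid_mesh(rows_q, wrap=False, region_rows=region_rows, quarter=True,
                          target_h=h)
    rows = [_expand_full(r) for r in rows_q]
    return _grid_mesh(rows, wrap=True, region_rows=region_rows, quarter=False,
                      target_h=h)


def _arc_length(a: float, b: float) -> float:
    t = np.linspace(0.0, np.pi / 2.0, 4001)
    ds = np.hypot(-a * np.sin(t), b * np.cos(t))
    return float(np.trapezoid(ds, t))


def build_annulus(
    inner_radius: float,
    interface_radius: float,
    outer_radius: float,
    target_element_size: float,
    quarter_symmetry: bool = True,
) -> Mesh:
    """Mesh a two-layer concentric annulus (inner band labelled lining)."""

    if not (0.0 < inner_radius < interface_radius < outer_radius):
        raise ValueError("radii must satisfy 0 < inner < interface < outer")
    h = float(target_element_size)
    if h <= 0.0:
        raise ValueError("target_element_size must be positive")

    n1 = max(1, int(round((interface_radius - inner_radius) / h)))
    n2 = max(2, int(round((outer_radius - interface_radius) / h)))
    radii = np.concatenate([
        np.linspace(inner_radius, interface_radius, n1 + 1),
        np.linspace(interface_radius, outer_radius, n2 + 1)[1:],
    ])
    r_mid = 0.5 * (inner_radius + outer_radius)
    arc = (np.pi / 2.0 if quarter_symmetry else 2.0 * np.pi) * r_mid
    n_theta = max(8, int(np.ceil(arc / h)))
    if quarter_symmetry:
        theta = np.linspace(0.0, np.pi / 2.0, n_theta + 1)
        wrap = False
    else:
        n_theta = 4 * int(np.ceil(n_theta / 4))
        theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
        wrap = True
    rows = [r * np.column_stack([np.cos(theta), np.sin(theta)]) for r in radii]
    region_rows = [REGION_LINING] * n1 + [REGION_SPONGIOSUM] * n2
    return _grid_mesh(rows, wrap=wrap, region_rows=region_rows,
                      quarter=quarter_symmetry, target_h=h)


def save_mesh(mesh: Mesh, path) -> None:
    """Write the mesh as deterministic plain text (nodes, elements, sets).

    The format is bit-stable for a given spec and element size: fixed
    17-significant-digit coordinates, sorted set names, newline-terminated.
    """

    lines = [f"# aussim mesh quarter={int(mesh.quarter)} target_h={mesh.target_h!r}"]
    lines.append(f"nodes {mesh.n_nodes}")
    for x, y in mesh.nodes:
        lines.append(f"{float(x)!r} {float(y)!r}")
    lines.append(f"elements {mesh.n_elems}")
    for quad, region in zip(mesh.elems, mesh.regions):
        lines.append(" ".join(str(int(i)) for i in quad) + f" {region}")
    for name in sorted(mesh.node_sets):
        ids = mesh.node_sets[name]
        lines.append(f"set {name} " + " ".join(str(int(i)) for i in ids))
    for name in sorted(mesh.loops):
        ids = mesh.loops[name]
        lines.append(f"loop {name} " + " ".join(str(int(i)) for i in ids))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_mesh(path) -> Mesh:
    """Read a mesh written by :func:`save_mesh`."""

    with open(path) as fh:
        lines = fh.read().splitlines()
    header = dict(p.split("=") for p in lines[0].split() if "=" in p)
    quarter = bool(int(header["quarter"]))
    target_h = float(header["target_h"])
    i = 1
    n_nodes = int(lines[i].split()[1]); i += 1
    nodes = np.array([[float(v) for v in lines[i + k].split()]
                      for k in range(n_nodes)])
    i += n_nodes
    n_elems = int(lines[i].split()[1]); i += 1
    elems = np.empty((n_elems, 4), dtype=np.int64)
    regions = np.empty(n_elems, dtype="<U16")
    for k in range(n_elems):
        parts = lines[i + k].split()
        elems[k] = [int(v) for v in parts[:4]]
        regions[k] = parts[4]
    i += n_elems
    node_sets, loops = {}, {}
    for line in lines[i:]:
        if not line.strip():
            continue
        parts = line.split()
        ids = np.array([int(v) for v in parts[2:]], dtype=np.int64)
        (node_sets if parts[0] == "set" else loops)[parts[1]] = ids
    mesh = Mesh(nodes=nodes, elems=elems, regions=regions, node_sets=node_sets,
                loops=loops, quarter=quarter, target_h=target_h)
    mesh.validate()
    return mesh


def build_block(lx: float, ly: float, nx: int, ny: int,
                region: str = REGION_SPONGIOSUM) -> Mesh:
    """Rectangular block mesh [0, lx] x [0, ly] for elementary solver checks.

    The ``lumen_boundary`` loop is the x = 0 edge and ``outer_boundary``
    the x = lx edge; the axis node sets mark the y = 0 and x = 0 edges.
    """

    xs = np.linspace(0.0, lx, nx + 1)
    ys = np.linspace(0.0, ly, ny + 1)
    # rows advance along +x so that (row, col) orientation is right-handed
    rows = [np.column_stack([np.full_like(ys, x), ys]) for x in xs]
    return _grid_mesh(rows, wrap=False, region_rows=[region] * nx, quarter=False,
                      target_h=min(lx / nx, ly / ny))
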