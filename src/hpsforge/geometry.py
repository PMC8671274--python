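"""Idealized biventricular geometry with analytic ventricular coordinates.

The synthetic anatomy is two truncated thick-walled ellipsoidal shells: a
left ventricle (LV) centred at the origin with its long axis along z (apex
down, base up, truncated by a basal plane), and a thinner right ventricle
(RV) shell offset laterally that wraps the LV epicardium, so the shared
wall between the RV cavity and the LV is the septum.  The mesh is produced
by sampling structured point shells on the analytic surfaces, Delaunay
tetrahedralization, and retention of tetrahedra whose centroid lies inside
the two-wall solid.

Every node carries universal ventricular coordinates (UVC):

* ``z``    apicobasal, 0 at the apex of the wall's endocardial shell, 1 at
  the basal plane;
* ``rho``  transmural, 0 on the endocardium, 1 on the epicardium of the
  owning wall (the septum uses LV coordinates, so its RV-facing surface has
  rho = 1);
* ``phi``  rotational, 0 toward mid-septum (+x), increasing counter-
  clockwise viewed from the base, in (-pi, pi];
* ``nu``   ventricular, -1 for LV + septum, +1 for the RV free wall.

A per-node normalized endocardial depth ``d_endo`` (0 on any endocardial
surface, 1 on the epicardium/base) supports all sub-endocardial-layer
logic, because under the septal convention raw rho is 1 on the RV-facing
septal endocardium.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.integrate import quad
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay, cKDTree

from ._geom3d import SurfaceMesh

# surface tags
LV_ENDO, RV_ENDO, EPI, BASE = 1, 2, 3, 4
SURFACE_NAMES = {LV_ENDO: "LV_ENDO", RV_ENDO: "RV_ENDO", EPI: "EPI", BASE: "BASE"}
# element regions
LV_WALL, RV_WALL, SEPTUM = 1, 2, 3
REGION_NAMES = {LV_WALL: "LV_WALL", RV_WALL: "RV_WALL", SEPTUM: "SEPTUM"}

_GOLDEN = np.pi * (3 - np.sqrt(5.0))


class UVCCoord(NamedTuple):
    """One universal ventricular coordinate (z, rho, phi, nu)."""

    z: float
    rho: float
    phi: float
    nu: int

    def validate(self):
        if not (0 <= self.z <= 1 and 0 <= self.rho <= 1):
            raise ValueError(f"z and rho must lie in [0, 1]: {self}")
        if self.nu not in (-1, 1):
            raise ValueError(f"nu must be -1 or +1: {self}")


def wrap_phi(phi):
    """Wrap angles to (-pi, pi]."""
    w = np.mod(np.asarray(phi) + np.pi, 2 * np.pi) - np.pi
    return np.where(w == -np.pi, np.pi, w)


@dataclass(frozen=True)
class GeometryParams:
    """Dimensions of the synthetic biventricular anatomy (mm)."""

    lv_long_axis: float = 45.0       # LV endocardial long semi-axis
    lv_endo_radius: float = 22.0     # LV endocardial short semi-axis
    lv_wall_thickness: float = 9.0
    rv_offset: float = 24.0          # lateral (+x) offset of the RV centre
    rv_long_axis: float = 40.0       # RV endocardial long semi-axis
    rv_endo_radius: float = 24.0     # RV endocardial short semi-axis
    rv_wall_thickness: float = 4.0
    base_fraction: float = 0.3       # basal plane at z = base_fraction * lv_long_axis
    target_edge_length: float = 4.0

    @property
    def z_base(self) -> float:
        return self.base_fraction * self.lv_long_axis

    def validate(self) -> None:
        lengths = (
            self.lv_long_axis, self.lv_endo_radius, self.lv_wall_thickness,
            self.rv_long_axis, self.rv_endo_radius, self.rv_wall_thickness,
            self.target_edge_length,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all lengths of GeometryParams must be positive")
        if self.target_edge_length > min(self.lv_wall_thickness, self.rv_wall_thickness):
            raise ValueError(
                "target_edge_length must not exceed the smallest wall thickness"
            )
        b_epi = self.lv_endo_radius + self.lv_wall_thickness
        # the RV endocardial shell must swallow part of the LV epicardium
        # (that part becomes the RV-facing septal face) ...
        if ((b_epi - self.rv_offset) / self.rv_endo_radius) ** 2 >= 1.0:
            raise ValueError("RV cavity does not intersect the LV epicardium")
        # ... and the RV free wall must reach beyond the LV epicardium
        if self.rv_offset + self.rv_endo_radius + self.rv_wall_thickness <= b_epi:
            raise ValueError("RV shell is entirely inside the LV epicardium")


# --------------------------------------------------------------------------- mesh


@dataclass
class BivMesh:
    """Labelled tetrahedral biventricular mesh.

    ``surface_triangles`` are wound so right-hand normals point out of the
    solid; ``surface_tags`` holds one of the four surface labels per
    triangle and ``element_region`` one wall label per tetrahedron.
    """

    nodes: np.ndarray            # (N, 3) mm
    elements: np.ndarray         # (M, 4) int
    surface_triangles: np.ndarray  # (K, 3) int, outward winding
    surface_tags: np.ndarray     # (K,) int
    element_region: np.ndarray   # (M,) int
    params: GeometryParams | None = None
    _surface_cache: dict = field(default_factory=dict, repr=False)

    @property
    def target_edge_length(self) -> float:
        return self.params.target_edge_length if self.params else 1.0

    def surface(self, tags) -> SurfaceMesh:
        """SurfaceMesh of all boundary triangles carrying one of ``tags``."""
        key = tuple(sorted(np.atleast_1d(tags).tolist()))
        if key not in self._surface_cache:
            mask = np.isin(self.surface_tags, list(key))
            sm = SurfaceMesh(self.nodes, self.surface_triangles[mask])
            sm.tags = self.surface_tags[mask]
            self._surface_cache[key] = sm
        return self._surface_cache[key]

    def node_normals(self, tags) -> tuple[np.ndarray, np.ndarray]:
        """Area-weighted outward node normals over the tagged surface.

        Returns (node_indices, unit_normals); only nodes incident to at
        least one tagged triangle appear.
        """
        key = ("nn",) + tuple(sorted(np.atleast_1d(tags).tolist()))
        if key not in self._surface_cache:
            mask = np.isin(self.surface_tags, np.atleast_1d(tags))
            tris = self.surface_triangles[mask]
            v = self.nodes
            cr = np.cross(v[tris[:, 1]] - v[tris[:, 0]], v[tris[:, 2]] - v[tris[:, 0]])
            acc = np.zeros_like(v)
            for c in range(3):
                np.add.at(acc, tris[:, c], cr)
            idx = np.unique(tris)
            n = acc[idx]
            n /= np.linalg.norm(n, axis=1, keepdims=True)
            self._surface_cache[key] = (idx, n)
        return self._surface_cache[key]

    def surface_nodes(self, tags) -> np.ndarray:
        mask = np.isin(self.surface_tags, np.atleast_1d(tags))
        return np.unique(self.surface_triangles[mask])


# ------------------------------------------------------------------- UVC frame


class MappedPoint(NamedTuple):
    coord: UVCCoord
    node: int
    distance: float
    flagged: bool


@dataclass
class UVCFrame:
    """Per-node UVC values plus bidirectional nearest-node mapping."""

    nodes: np.ndarray
    z: np.ndarray
    rho: np.ndarray
    phi: np.ndarray
    nu: np.ndarray
    d_endo: np.ndarray
    target_edge_length: float
    l_ab: dict          # apicobasal endocardial arc length per nu, mm
    _tree: cKDTree | None = field(default=None, repr=False)

    def __post_init__(self):
        if self._tree is None and len(self.nodes):
            self._tree = cKDTree(self.nodes)

    def __len__(self):
        return len(self.nodes)

    def coord(self, i: int) -> UVCCoord:
        return UVCCoord(float(self.z[i]), float(self.rho[i]), float(self.phi[i]), int(self.nu[i]))

    def uvc_distance2(self, b: UVCCoord) -> np.ndarray:
        """Squared frame-metric distance of every stored node to ``b``.

        nu acts lexicographically (mismatching nodes get +inf); the metric
        over the rest is Euclidean in (z, rho, phi/pi) with circular phi.
        """
        dphi = np.abs(wrap_phi(self.phi - b.phi))
        d2 = (self.z - b.z) ** 2 + (self.rho - b.rho) ** 2 + (dphi / np.pi) ** 2
        return np.where(self.nu == b.nu, d2, np.inf)


def uvc_to_cartesian(frame: UVCFrame, b: UVCCoord) -> tuple[int, np.ndarray]:
    """Mesh node (index, position) whose stored UVC is nearest to ``b``.

    Ties break to the lowest node index.
    """
    if len(frame) == 0:
        raise ValueError("empty UVC frame")
    b = UVCCoord(*b)
    b.validate()
    d2 = frame.uvc_distance2(b)
    i = int(np.argmin(d2))
    if not np.isfinite(d2[i]):
        raise ValueError(f"no node with nu={b.nu} in frame")
    return i, frame.nodes[i].copy()


def cartesian_to_uvc(frame: UVCFrame, x) -> MappedPoint:
    """UVC of the Euclidean-nearest mesh node to point ``x``.

    The result is flagged when the query point is farther than twice the
    target edge length from the mesh (likely outside the myocardium).
    """
    if len(frame) == 0:
        raise ValueError("empty UVC frame")
    d, i = frame._tree.query(np.asarray(x, dtype=float))
    i = int(i)
    return MappedPoint(frame.coord(i), i, float(d), bool(d > 2 * frame.target_edge_length))


# ---------------------------------------------------------------- construction


class _Ellipsoid:
    """Axisymmetric ellipsoid: short radius b in xy, long semi-axis a in z."""

    def __init__(self, center, a, b):
        self.c = np.asarray(center, dtype=float)
        self.a = float(a)
        self.b = float(b)

    def level(self, x):
        """<0 inside, 0 on, >0 outside."""
        d = np.atleast_2d(x) - self.c
        return (d[:, 0] ** 2 + d[:, 1] ** 2) / self.b**2 + d[:, 2] ** 2 / self.a**2 - 1.0

    def radial_distance(self, x):
        """Approximate signed distance along the ray from the centre."""
        d = np.atleast_2d(x) - self.c
        r = np.linalg.norm(d, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            u = d / r[:, None]
        u = np.nan_to_num(u)
        rs = 1.0 / np.sqrt(
            (u[:, 0] ** 2 + u[:, 1] ** 2) / self.b**2 + u[:, 2] ** 2 / self.a**2
        )
        return r - rs

    def sample_truncated(self, z_base, h, phase=0.0):
        """Points on the shell below the basal plane, spaced ~h along arcs."""
        cz = self.c[2]
        cos_max = (cz - z_base) / self.a
        theta_max = np.pi if cos_max <= -1 else float(np.arccos(np.clip(cos_max, -1, 1)))
        pts = [self.c + [0, 0, -self.a]]  # apex
        thetas = []
        th = 0.0
        while True:
            dl = np.hypot(self.a * np.sin(th), self.b * np.cos(th))
            th = th + h / max(dl, 1e-9)
            if th >= theta_max:
                break
            thetas.append(th)
        if not thetas or theta_max - thetas[-1] > 0.3 * h / max(
            np.hypot(self.a * np.sin(theta_max), self.b * np.cos(theta_max)), 1e-9
        ):
            thetas.append(theta_max)
        else:
            thetas[-1] = theta_max
        for k, th in enumerate(thetas):
            r = self.b * np.sin(th)
            z = cz - self.a * np.cos(th)
            nphi = max(6, int(round(2 * np.pi * r / h)))
            ang = phase + _GOLDEN * k + 2 * np.pi * np.arange(nphi) / nphi
            ring = np.column_stack(
                [self.c[0] + r * np.cos(ang), self.c[1] + r * np.sin(ang), np.full(nphi, z)]
            )
            pts.append(ring)
        return np.vstack([np.atleast_2d(p) for p in pts])

    def arc_length_apex_base(self, z_base):
        """Arc length along a meridian from the apex to the basal plane."""
        cz = self.c[2]
        cos_max = (cz - z_base) / self.a
        theta_max = np.pi if cos_max <= -1 else float(np.arccos(np.clip(cos_max, -1, 1)))
        val, _ = quad(lambda t: np.hypot(self.a * np.sin(t), self.b * np.cos(t)), 0, theta_max)
        return float(val)


def _shells(params: GeometryParams):
    p = params
    lv_endo = _Ellipsoid((0, 0, 0), p.lv_long_axis, p.lv_endo_radius)
    lv_epi = _Ellipsoid(
        (0, 0, 0), p.lv_long_axis + p.lv_wall_thickness, p.lv_endo_radius + p.lv_wall_thickness
    )
    rv_endo = _Ellipsoid((p.rv_offset, 0, 0), p.rv_long_axis, p.rv_endo_radius)
    rv_epi = _Ellipsoid(
        (p.rv_offset, 0, 0), p.rv_long_axis + p.rv_wall_thickness,
        p.rv_endo_radius + p.rv_wall_thickness,
    )
    return lv_endo, lv_epi, rv_endo, rv_epi


def generate_ideal_biv(params: GeometryParams | None = None, seed: int = 0):
    """Build the synthetic labelled biventricular mesh and its UVC frame.

    The construction is deterministic; ``seed`` is accepted for interface
    uniformity with the stochastic stages and currently unused.
    """
    params = params or GeometryParams()
    params.validate()
    lv_endo, lv_epi, rv_endo, rv_epi = _shells(params)
    h, zb = params.target_edge_length, params.z_base

    # ---- point cloud: structured shell levels
    pts = []
    n_lv = max(2, int(round(params.lv_wall_thickness / h))) + 1
    for i, s in enumerate(np.linspace(0, 1, n_lv)):
        sh = _Ellipsoid(
            (0, 0, 0),
            params.lv_long_axis + s * params.lv_wall_thickness,
            params.lv_endo_radius + s * params.lv_wall_thickness,
        )
        pts.append(sh.sample_truncated(zb, h, phase=0.7 * i))
    n_rv = max(2, int(round(params.rv_wall_thickness / h))) + 1
    for i, s in enumerate(np.linspace(0, 1, n_rv)):
        sh = _Ellipsoid(
            (params.rv_offset, 0, 0),
            params.rv_long_axis + s * params.rv_wall_thickness,
            params.rv_endo_radius + s * params.rv_wall_thickness,
        )
        cand = sh.sample_truncated(zb, h, phase=0.4 + 0.7 * i)
        keep = lv_epi.level(cand) > 0.03  # only the part outside the LV epicardium
        pts.append(cand[keep])
    points = np.vstack(pts)

    # ---- Delaunay + characteristic-function filtering
    tri = Delaunay(points)
    tets = tri.simplices
    a, b, c, d = (points[tets[:, k]] for k in range(4))
    vol = np.abs(np.einsum("ij,ij->i", np.cross(b - a, c - a), d - a)) / 6.0
    cent = (a + b + c + d) / 4.0
    in_lv = (lv_endo.level(cent) >= 0) & (lv_epi.level(cent) <= 0)
    in_rv = (rv_endo.level(cent) >= 0) & (rv_epi.level(cent) <= 0) & (lv_epi.level(cent) >= 0)
    keep = (in_lv | in_rv) & (vol > 1e-4 * h**3)
    tets, cent, in_rv = tets[keep], cent[keep], in_rv[keep]
    if len(tets) == 0:
        raise ValueError("degenerate parameters: no interior tetrahedra")

    # ---- largest connected component (node-sharing)
    edges = np.vstack([tets[:, [i, j]] for i in range(4) for j in range(i + 1, 4)])
    n_pts = len(points)
    adj = coo_matrix(
        (np.ones(len(edges)), (edges[:, 0], edges[:, 1])), shape=(n_pts, n_pts)
    )
    ncomp, labels = connected_components(adj + adj.T, directed=False)
    used = np.unique(tets)
    if ncomp > 1:
        counts = np.bincount(labels[used], minlength=ncomp)
        main = int(np.argmax(counts))
        keep = np.all(labels[tets] == main, axis=1)
        tets, cent, in_rv = tets[keep], cent[keep], in_rv[keep]
        used = np.unique(tets)

    # ---- compact node indexing
    remap = -np.ones(n_pts, dtype=np.intp)
    remap[used] = np.arange(len(used))
    nodes = points[used]
    elements = remap[tets]

    # ---- boundary faces with outward winding
    faces = np.vstack(
        [elements[:, [1, 2, 3]], elements[:, [0, 3, 2]],
         elements[:, [0, 1, 3]], elements[:, [0, 2, 1]]]
    )
    opposite = np.concatenate([elements[:, 0], elements[:, 1], elements[:, 2], elements[:, 3]])
    key = np.sort(faces, axis=1)
    _, first, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    bidx = first[counts == 1]
    btris, bopp = faces[bidx], opposite[bidx]
    fc = nodes[btris].mean(axis=1)
    nrm = np.cross(nodes[btris[:, 1]] - nodes[btris[:, 0]], nodes[btris[:, 2]] - nodes[btris[:, 0]])
    flip = np.einsum("ij,ij->i", nrm, fc - nodes[bopp]) < 0
    btris[flip] = btris[flip][:, [0, 2, 1]]

    # ---- surface tagging by nearest analytic surface
    dist = np.column_stack(
        [
            np.abs(lv_endo.radial_distance(fc)),
            np.abs(lv_epi.radial_distance(fc)),
            np.abs(rv_endo.radial_distance(fc)),
            np.abs(rv_epi.radial_distance(fc)),
            np.abs(fc[:, 2] - zb),
        ]
    )
    which = np.argmin(dist, axis=1)
    tags = np.empty(len(btris), dtype=np.intp)
    tags[which == 0] = LV_ENDO
    tags[which == 2] = RV_ENDO
    tags[which == 3] = EPI
    tags[which == 4] = BASE
    # LV epicardial faces inside the RV cavity are the RV-facing septal face
    m = which == 1
    tags[m] = np.where(rv_endo.level(fc[m]) < 0, RV_ENDO, EPI)

    # ---- element regions
    region = np.full(len(elements), LV_WALL, dtype=np.intp)
    region[in_rv] = RV_WALL
    lvm = ~in_rv
    region[lvm & (rv_endo.level(cent) < 0)] = SEPTUM

    mesh = BivMesh(nodes, elements, btris, tags, region, params)

    # ---- analytic UVC
    nu = np.where(lv_epi.level(nodes) > 1e-6, 1, -1).astype(np.intp)
    z = np.empty(len(nodes))
    rho = np.empty(len(nodes))
    for side, endo, epi, thick, a_e in (
        (-1, lv_endo, lv_epi, params.lv_wall_thickness, params.lv_long_axis),
        (1, rv_endo, rv_epi, params.rv_wall_thickness, params.rv_long_axis),
    ):
        m = nu == side
        if not m.any():
            continue
        de = endo.radial_distance(nodes[m])
        dp = epi.radial_distance(nodes[m])
        r = np.clip(de / np.maximum(de - dp, 1e-12), 0, 1)
        rho[m] = r
        a_rho = a_e + r * thick
        z[m] = np.clip((nodes[m, 2] - endo.c[2] + a_rho) / (zb - endo.c[2] + a_rho), 0, 1)
    phi = wrap_phi(np.arctan2(nodes[:, 1], nodes[:, 0]))

    # ---- normalized endocardial depth
    endo_surf = mesh.surface([LV_ENDO, RV_ENDO])
    outer_surf = mesh.surface([EPI, BASE])
    _, d1, _ = endo_surf.closest_point(nodes)
    _, d2, _ = outer_surf.closest_point(nodes)
    d_endo = d1 / np.maximum(d1 + d2, 1e-12)
    d_endo[mesh.surface_nodes([LV_ENDO, RV_ENDO])] = 0.0
    only_outer = np.setdiff1d(mesh.surface_nodes([EPI, BASE]), mesh.surface_nodes([LV_ENDO, RV_ENDO]))
    d_endo[only_outer] = 1.0

    l_ab = {
        -1: lv_endo.arc_length_apex_base(zb),
        1: rv_endo.arc_length_apex_base(zb),
    }
    frame = UVCFrame(nodes, z, rho, phi, nu, d_endo, params.target_edge_length, l_ab)
    return mesh, frame


# ------------------------------------------------------------------- ray pairs


def surface_ray_pair(mesh: BivMesh, pvj_point, surface_from: int):
    """First wall crossing from an endocardial point along the inward normal.

    ``surface_from`` names the endocardial surface the point sits on; the
    ray direction is the inward area-weighted normal of the nearest node of
    that surface, and the hit is the first intersection with any *other*
    boundary surface.  Returns (intersection_point, distance_mm).
    """
    pvj_point = np.asarray(pvj_point, dtype=float)
    idx, normals = mesh.node_normals(surface_from)
    tree_key = ("nodetree", surface_from)
    if tree_key not in mesh._surface_cache:
        mesh._surface_cache[tree_key] = cKDTree(mesh.nodes[idx])
    d, k = mesh._surface_cache[tree_key].query(pvj_point)
    if d > 2 * mesh.target_edge_length:
        raise ValueError(
            f"PVJ point {pvj_point} is {d:.2f} mm from surface "
            f"{SURFACE_NAMES[surface_from]}; expected on or near it"
        )
    direction = -normals[k]  # outward -> into the wall
    others = [t for t in (LV_ENDO, RV_ENDO, EPI, BASE) if t != surface_from]
    target = mesh.surface(others)
    hit, t, f = target.ray_hits(pvj_point[None], direction[None], min_t=1e-6)
    if not np.isfinite(t[0]):
        raise ValueError(f"no transmural intersection found for PVJ at {pvj_point}")
    return hit[0], float(t[0])


def surface_ray_pairs(mesh: BivMesh, points, surface_from: int):
    """Vectorized :func:`surface_ray_pair` over many points.

    Returns (hit_points, distances, ok_mask); failed rays get distance inf
    instead of raising, so callers can drop and count them.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    idx, normals = mesh.node_normals(surface_from)
    tree = cKDTree(mesh.nodes[idx])
    _, k = tree.query(points)
    dirs = -normals[k]
    others = [t for t in (LV_ENDO, RV_ENDO, EPI, BASE) if t != surface_from]
    target = mesh.surface(others)
    hit, t, f = target.ray_hits(points, dirs, min_t=1e-6)
    ok = np.isfinite(t)
    return hit, t, ok
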