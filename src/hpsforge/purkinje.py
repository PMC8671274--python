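"""Topologically realistic Purkinje network construction.

Four stages build the network:

1. a His bundle laid out between bifurcation points given in UVC space,
   snapped to the sub-endocardial (SE) layer and discretized at the cable
   resolution;
2. five independent recombinant fractal networks, one per fascicle, grown
   generation by generation on the endocardial surface.  Each active tip
   spawns up to two branches at +/- psi about its heading; branch lengths
   are Gaussian; a repulsion term pushes growth away from existing cable;
   branches may collide into existing nodes of the same network (degree
   caps: two parents, two offspring per node); growth stops when the
   network covers a fraction ``delta_cov`` of the ventricle's SE territory
   or a generation cap is hit;
3. stochastic Purkinje-ventricular junction (PVJ) placement by a renewal
   process with hazard min(1, lambda*d), lambda = delta_cov/mu, along a
   depth-first traversal of each network;
4. ray-traced transmural extension of each PVJ stem to a fraction ``s_rho``
   of the local paired wall distance, with Gaussian length heterogeneity.

All randomness flows through named per-fascicle substreams of a master
seed, so a fixed seed reproduces the network bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._geom3d import SurfaceMesh
from .config import EASConfig, FASCICLE_ORDER, PurkinjeConfig
from .fascicle import SELayer
from .geometry import (
    BivMesh,
    LV_ENDO,
    RV_ENDO,
    UVCCoord,
    UVCFrame,
    uvc_to_cartesian,
)

# node roles
HIS, BRANCH, PVJ_STEM, PVJ = 0, 1, 2, 3
ROLE_NAMES = {HIS: "HIS", BRANCH: "BRANCH", PVJ_STEM: "PVJ_STEM", PVJ: "PVJ"}


class PurkinjeNetwork:
    """Directed graph of 1-D cable segments with fascicle labels.

    Nodes carry Cartesian positions (mm), a role, and the outward surface
    normal captured when they were created (used to orient PVJ stems into
    the wall).  Segments are parent->child with lengths in micrometres.
    """

    def __init__(self):
        self._pos: list[np.ndarray] = []
        self._normal: list[np.ndarray] = []
        self._role: list[int] = []
        self.seg_parent: list[int] = []
        self.seg_child: list[int] = []
        self.seg_length: list[float] = []   # um
        self.seg_label: list[str] = []
        self._children: list[list[int]] = []  # node -> outgoing segment ids
        self._parents: list[list[int]] = []   # node -> incoming segment ids
        self.root: int | None = None          # b_h0 node
        self.fascicle_roots: dict[str, int] = {}
        self.pvj_couplings: list[tuple[int, int]] = []
        self.pvj_dropped: int = 0

    # ------------------------------------------------------------- mutation
    def add_node(self, pos, role, normal=None) -> int:
        self._pos.append(np.asarray(pos, dtype=float))
        self._normal.append(
            np.full(3, np.nan) if normal is None else np.asarray(normal, dtype=float)
        )
        self._role.append(role)
        self._children.append([])
        self._parents.append([])
        return len(self._pos) - 1

    def add_segment(self, parent, child, label, length_um=None) -> int:
        if length_um is None:
            length_um = 1000.0 * float(
                np.linalg.norm(self._pos[parent] - self._pos[child])
            )
        sid = len(self.seg_parent)
        self.seg_parent.append(parent)
        self.seg_child.append(child)
        self.seg_length.append(float(length_um))
        self.seg_label.append(label)
        self._children[parent].append(sid)
        self._parents[child].append(sid)
        return sid

    # -------------------------------------------------------------- queries
    def __len__(self):
        return len(self._pos)

    @property
    def n_segments(self):
        return len(self.seg_parent)

    @property
    def positions(self) -> np.ndarray:
        return np.asarray(self._pos) if self._pos else np.zeros((0, 3))

    @property
    def normals(self) -> np.ndarray:
        return np.asarray(self._normal) if self._normal else np.zeros((0, 3))

    @property
    def roles(self) -> np.ndarray:
        return np.asarray(self._role, dtype=np.intp)

    def n_children(self, node) -> int:
        return len(self._children[node])

    def n_parents(self, node) -> int:
        return len(self._parents[node])

    def child_segments(self, node) -> list[int]:
        return self._children[node]

    def node_position(self, node) -> np.ndarray:
        return self._pos[node]

    def nodes_of_label(self, label) -> np.ndarray:
        mask = np.asarray([lb == label for lb in self.seg_label])
        if not mask.any():
            return np.array([], dtype=np.intp)
        sp = np.asarray(self.seg_parent)[mask]
        sc = np.asarray(self.seg_child)[mask]
        return np.unique(np.concatenate([sp, sc]))

    def cable_length(self, labels=None) -> float:
        """Total cable length in um over the given labels (default: non-HIS)."""
        total = 0.0
        for length, lb in zip(self.seg_length, self.seg_label):
            if labels is None:
                if lb != "his":
                    total += length
            elif lb in labels:
                total += length
        return total

    def pvj_nodes(self) -> np.ndarray:
        return np.flatnonzero(self.roles == PVJ)


# --------------------------------------------------------------------- His


def _descend_free_slot(net: PurkinjeNetwork, node: int) -> int:
    """Walk forward along the latest outgoing path until < 2 children.

    Fascicular branch points may fan out to three paths; offspring caps are
    honoured by cascading the extra departure one node downstream.
    """
    while net.n_children(node) >= 2:
        node = net.seg_child[net._children[node][-1]]
    return node


def build_his_bundle(
    frame: UVCFrame, purk: PurkinjeConfig, eas: EASConfig, layer: SELayer | None = None
) -> PurkinjeNetwork:
    """Construct the His bundle polylines between UVC bifurcation points.

    Paths: b_h0 -> b_h1; b_h1 -> b_h_lv -> {lv_sf, lv_af, lv_pf};
    b_h1 -> b_h_rv -> b_h_rv_mid -> {rv_sf, rv_mod}.  Each leg walks from
    waypoint to waypoint in edge-length steps, snapping every intermediate
    sample to the nearest SE-layer node (the mapped waypoint endpoints
    themselves stay put); the polyline is then discretized at
    ``segment_resolution``.
    """
    for name in ("b_h0", "b_h1", "b_h_lv", "b_h_rv", "b_h_rv_mid"):
        UVCCoord(*getattr(purk, name)).validate()
    if layer is not None:
        se_nodes = layer.node_indices
        edge = layer.mesh.target_edge_length
    else:
        member = (
            (frame.z >= eas.s_z_min)
            & (frame.z <= eas.s_z_max)
            & (frame.d_endo <= eas.s_rho)
        )
        se_nodes = np.flatnonzero(member)
        edge = frame.target_edge_length
    if len(se_nodes) == 0:
        raise ValueError("SE layer is empty; cannot snap the His bundle")
    se_tree = cKDTree(frame.nodes[se_nodes])

    way = {}
    for name in ("b_h0", "b_h1", "b_h_lv", "b_h_rv", "b_h_rv_mid"):
        i, x = uvc_to_cartesian(frame, getattr(purk, name))
        way[name] = x
    for fascicle, b in eas.roots.items():
        i, x = uvc_to_cartesian(frame, b)
        way[fascicle] = x

    res_mm = purk.segment_resolution / 1000.0
    net = PurkinjeNetwork()
    node_of = {"b_h0": net.add_node(way["b_h0"], HIS)}
    net.root = node_of["b_h0"]

    paths = [
        ("b_h0", "b_h1"),
        ("b_h1", "b_h_lv"),
        ("b_h_lv", "lv_sf"),
        ("b_h_lv", "lv_af"),
        ("b_h_lv", "lv_pf"),
        ("b_h1", "b_h_rv"),
        ("b_h_rv", "b_h_rv_mid"),
        ("b_h_rv_mid", "rv_sf"),
        ("b_h_rv_mid", "rv_mod"),
    ]
    for src, dst in paths:
        start_node = _descend_free_slot(net, node_of[src])
        p0 = net.node_position(start_node)
        p1 = way[dst]
        # walk toward the endpoint one edge length at a time, snapping each
        # sample to the nearest SE node, so the path hugs the endocardium
        # instead of chording through the cavity
        poly = [p0]
        cur = p0
        max_steps = 50 + int(10 * np.linalg.norm(p1 - p0) / edge)
        for _ in range(max_steps):
            vec = p1 - cur
            dist = float(np.linalg.norm(vec))
            if dist <= edge:
                break
            q = cur + edge * vec / dist
            d, k = se_tree.query(q)
            if d > 2 * edge:
                raise ValueError(
                    f"His path {src}->{dst}: sample at {q} has no SE node "
                    f"within 2 edge lengths ({d:.2f} mm > {2 * edge:.2f} mm)"
                )
            snapped = frame.nodes[se_nodes[k]]
            recent = poly[-2:]
            if any(np.linalg.norm(snapped - r) < 1e-9 for r in recent):
                cur = q  # same node again: keep advancing off-surface
            else:
                cur = snapped
            poly.append(cur)
        else:
            raise ValueError(f"His path {src}->{dst} failed to reach its endpoint")
        poly.append(p1)
        # drop consecutive duplicates from snapping
        clean = [poly[0]]
        for q in poly[1:]:
            if np.linalg.norm(q - clean[-1]) > 1e-9:
                clean.append(q)
        prev = start_node
        for a, b in zip(clean[:-1], clean[1:]):
            leg = float(np.linalg.norm(b - a))
            pieces = max(1, int(math.ceil(leg / res_mm - 1e-9)))
            for j in range(1, pieces + 1):
                q = a + (b - a) * j / pieces
                nid = net.add_node(q, HIS)
                net.add_segment(prev, nid, "his")
                prev = nid
        node_of[dst] = prev
        if dst in FASCICLE_ORDER:
            net.fascicle_roots[dst] = prev
    return net


# ------------------------------------------------------------------ growth


class GrowthSurface:
    """Substrate for fractal growth: projection, bounds and territory.

    The production implementation wraps one endocardial surface of the
    biventricular mesh; tests may substitute flat sheets.
    """

    def project(self, points):
        """Return (points_on_surface, outward_unit_normals)."""
        raise NotImplementedError

    def in_bounds(self, points):
        """Boolean array: inside the SE apicobasal band."""
        raise NotImplementedError

    def territory(self):
        """(P, 3) coordinates whose coverage defines the stopping rule."""
        raise NotImplementedError


class EndocardialSurface(GrowthSurface):
    """One tagged endocardial surface of the mesh, bounded by the SE z-band."""

    def __init__(self, mesh: BivMesh, frame: UVCFrame, layer: SELayer, tag: int):
        self.surf: SurfaceMesh = mesh.surface(tag)
        self.frame = frame
        self.layer = layer
        self.tag = tag
        self._territory = frame.nodes[layer.territory_nodes(tag)]
        self._node_tree = cKDTree(frame.nodes)

    def project(self, points):
        q, _, f = self.surf.closest_point(points)
        return q, self.surf.face_normals[f]

    def in_bounds(self, points):
        _, idx = self._node_tree.query(np.atleast_2d(points))
        z = self.frame.z[idx]
        eas = self.layer.eas
        return (z >= eas.s_z_min) & (z <= eas.s_z_max)

    def territory(self):
        return self._territory


class PlanarSheet(GrowthSurface):
    """Flat rectangular test sheet in the z=0 plane."""

    def __init__(self, x_range=(-100.0, 100.0), y_range=(-100.0, 100.0), spacing=2.0):
        self.x_range, self.y_range = x_range, y_range
        xs = np.arange(x_range[0], x_range[1] + spacing / 2, spacing)
        ys = np.arange(y_range[0], y_range[1] + spacing / 2, spacing)
        gx, gy = np.meshgrid(xs, ys)
        self._territory = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(gx.size)])

    def project(self, points):
        p = np.atleast_2d(points).copy()
        p[:, 2] = 0.0
        n = np.zeros_like(p)
        n[:, 2] = 1.0
        return p, n

    def in_bounds(self, points):
        p = np.atleast_2d(points)
        return (
            (p[:, 0] >= self.x_range[0]) & (p[:, 0] <= self.x_range[1])
            & (p[:, 1] >= self.y_range[0]) & (p[:, 1] <= self.y_range[1])
        )

    def territory(self):
        return self._territory


@dataclass
class GrowthState:
    """Book-keeping for one fascicle's growth loop."""

    tips: list = field(default_factory=list)   # (node, unit heading)
    generation: int = 0
    coverage: float = 0.0


def _rotate_about(v, axis, angle_rad):
    """Rodrigues rotation of v about unit axis."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    cross = np.array(
        [axis[1] * v[2] - axis[2] * v[1],
         axis[2] * v[0] - axis[0] * v[2],
         axis[0] * v[1] - axis[1] * v[0]]
    )
    return v * c + cross * s + axis * np.dot(axis, v) * (1 - c)


def _truncated_normal(rng, mean, sd, lo, hi):
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(64):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def _coverage(net_positions, territory, radius_mm):
    if len(territory) == 0:
        return 1.0
    d, _ = cKDTree(net_positions).query(territory)
    return float(np.mean(d <= radius_mm))


def grow_fascicle_network(
    frame: UVCFrame,
    layer: SELayer,
    root: UVCCoord | int,
    purk: PurkinjeConfig,
    seed,
    *,
    net: PurkinjeNetwork | None = None,
    start_node: int | None = None,
    label: str = "network",
    surface: GrowthSurface | None = None,
    collision_radius: float | None = None,
    initial_direction=None,
) -> PurkinjeNetwork:
    """Grow one fascicle's recombinant fractal network on the SE surface.

    ``root`` is a UVC coordinate (mapped to a mesh node) or a mesh node
    index.  ``seed`` feeds a dedicated Generator, so equal seeds give
    bit-identical networks.  When ``net``/``start_node`` are given the
    growth extends an existing network (the His bundle) from that node.
    """
    rng = np.random.default_rng(seed)
    if surface is None:
        if net is not None and start_node is not None:
            # extending an existing network from one of its nodes
            root_pos = net.node_position(start_node)
            if label.startswith("lv"):
                tag = LV_ENDO
            elif label.startswith("rv"):
                tag = RV_ENDO
            else:
                _, d_lv, _ = layer.mesh.surface(LV_ENDO).closest_point(root_pos[None])
                _, d_rv, _ = layer.mesh.surface(RV_ENDO).closest_point(root_pos[None])
                tag = LV_ENDO if d_lv[0] <= d_rv[0] else RV_ENDO
        else:
            if isinstance(root, (int, np.integer)):
                root_idx = int(root)
            else:
                root_idx, _ = uvc_to_cartesian(frame, UVCCoord(*root))
            if not layer.is_member([root_idx])[0]:
                raise ValueError(f"fascicle root node {root_idx} lies outside the SE layer")
            on_lv = root_idx in layer.mesh.surface_nodes(LV_ENDO)
            tag = LV_ENDO if on_lv else RV_ENDO
            root_pos = frame.nodes[root_idx]
        surface = EndocardialSurface(layer.mesh, frame, layer, tag)
    else:
        root_pos = (
            net.node_position(start_node)
            if net is not None and start_node is not None
            else np.asarray(root, dtype=float)
        )

    res_mm = purk.segment_resolution / 1000.0
    mu_mm = purk.mu / 1000.0
    col_r = 0.5 * res_mm if collision_radius is None else collision_radius
    psi = math.radians(purk.psi)

    if net is None:
        net = PurkinjeNetwork()
    if start_node is None:
        p, n = surface.project(root_pos[None])
        start_node = net.add_node(p[0], BRANCH, n[0])
        if net.root is None:
            net.root = start_node
    own_first = start_node
    _, start_normal = surface.project(net.node_position(start_node)[None])
    start_normal = start_normal[0]
    net._normal[start_node] = start_normal

    if purk.delta_cov <= 0:
        return net

    if initial_direction is None:
        # head apexward: project -z onto the tangent plane at the root
        d0 = np.array([0.0, 0.0, -1.0])
        d0 = d0 - np.dot(d0, start_normal) * start_normal
        if np.linalg.norm(d0) < 1e-9:
            d0 = np.cross(start_normal, [1.0, 0.0, 0.0])
    else:
        d0 = np.asarray(initial_direction, dtype=float)
    d0 = d0 / np.linalg.norm(d0)

    territory = surface.territory()
    terr_tree = cKDTree(territory) if len(territory) else None
    covered = np.zeros(max(1, len(territory)), dtype=bool)

    state = GrowthState(tips=[(start_node, d0)])
    # nodes of *this* fascicle in a growing position buffer for spatial queries
    own_nodes = [start_node]
    buf_cap = 1024
    pos_buf = np.empty((buf_cap, 3))
    n_own = 1
    pos_buf[0] = net.node_position(start_node)

    def _mark_covered(new_pts):
        if terr_tree is None:
            return
        for idx in terr_tree.query_ball_point(np.atleast_2d(new_pts), mu_mm):
            covered[idx] = True

    _mark_covered(pos_buf[:1])
    state.coverage = float(covered.mean()) if len(territory) else 1.0
    stop = state.coverage >= purk.delta_cov
    while state.tips and not stop and state.generation < purk.generation_cap:
        state.generation += 1
        tip_pts = np.array([net.node_position(t) for t, _ in state.tips])
        _, tip_nrm = surface.project(tip_pts)
        branches = []
        for (t, h), nrm in zip(state.tips, tip_nrm):
            cap = max(0, 2 - net.n_children(t))
            for sign in (1.0, -1.0)[:cap]:
                d = _rotate_about(h, nrm, sign * psi)
                branches.append((t, d / np.linalg.norm(d)))
        if not branches:
            break
        nb = len(branches)
        cur = np.array([b[0] for b in branches], dtype=np.intp)
        bdir = np.array([b[1] for b in branches])
        bpos = np.array([net.node_position(c) for c in cur])
        if purk.sigma > 0:
            sd = purk.sigma * mu_mm
            lengths = rng.normal(mu_mm, sd, size=nb)
            bad = (lengths < 0.25 * mu_mm) | (lengths > 4 * mu_mm)
            for _ in range(64):
                if not bad.any():
                    break
                lengths[bad] = rng.normal(mu_mm, sd, size=int(bad.sum()))
                bad = (lengths < 0.25 * mu_mm) | (lengths > 4 * mu_mm)
            lengths = np.clip(lengths, 0.25 * mu_mm, 4 * mu_mm)
        else:
            lengths = np.full(nb, mu_mm)
        remaining = lengths.copy()
        alive = np.ones(nb, dtype=bool)
        recent = np.full((nb, 3), -1, dtype=np.intp)
        recent[:, 2] = cur
        new_tips = []
        # ---- all branches of the generation advance one sub-step at a time;
        #      collision/repulsion see a k-d-tree snapshot taken per sub-step
        while alive.any():
            pos_arr = pos_buf[:n_own]
            ids_arr = np.asarray(own_nodes)
            tree = cKDTree(pos_arr)
            sub_start = n_own
            ai = np.flatnonzero(alive)
            step = np.minimum(res_mm, remaining[ai])
            d_sub = bdir[ai].copy()
            if purk.r > 0 and tree.n > 1:
                k = min(4, tree.n)
                dd, ii = tree.query(bpos[ai], k=k)
                dd = dd.reshape(len(ai), -1)
                ii = ii.reshape(len(ai), -1)
                cand_ids = ids_arr[ii]
                excl = (cand_ids[:, :, None] == recent[ai][:, None, :]).any(axis=2)
                dd = np.where(excl, np.inf, dd)
                jj = np.argmin(dd, axis=1)
                rows = np.arange(len(ai))
                ok = np.isfinite(dd[rows, jj]) & (dd[rows, jj] > 1e-9)
                rep = bpos[ai] - pos_arr[ii[rows, jj]]
                nn = np.linalg.norm(rep, axis=1, keepdims=True)
                rep = np.where(nn > 1e-12, rep / np.maximum(nn, 1e-12), 0.0)
                d_sub = np.where(
                    ok[:, None], (1 - purk.r) * d_sub + purk.r * rep, d_sub
                )
                d_sub /= np.linalg.norm(d_sub, axis=1, keepdims=True)
            proj, nrm = surface.project(bpos[ai] + step[:, None] * d_sub)
            move = proj - bpos[ai]
            mlen = np.linalg.norm(move, axis=1)
            inb = surface.in_bounds(proj)
            if col_r > 0 and tree.n:
                kc = min(6, tree.n)
                cd, ci = tree.query(proj, k=kc)
                cd = cd.reshape(len(ai), -1)
                ci = ci.reshape(len(ai), -1)
                cids = ids_arr[ci]
            for row, b in enumerate(ai):
                if mlen[row] < 1e-9 or not inb[row]:
                    alive[b] = False  # truncated at the SE boundary
                    continue
                target = -1
                if col_r > 0 and tree.n:
                    for dd_, id_ in zip(cd[row], cids[row]):
                        if dd_ > col_r:
                            break
                        if id_ in recent[b]:
                            continue
                        if net.n_parents(int(id_)) < 2:
                            target = int(id_)
                            break
                if target >= 0:
                    net.add_segment(int(cur[b]), target, label)
                    alive[b] = False
                    continue
                nid = net.add_node(proj[row], BRANCH, nrm[row])
                net.add_segment(int(cur[b]), nid, label)
                own_nodes.append(nid)
                if n_own == buf_cap:
                    buf_cap *= 2
                    grown = np.empty((buf_cap, 3))
                    grown[:n_own] = pos_buf[:n_own]
                    pos_buf = grown
                pos_buf[n_own] = proj[row]
                n_own += 1
                recent[b] = (recent[b, 1], recent[b, 2], nid)
                cur[b] = nid
                bpos[b] = proj[row]
                bdir[b] = move[row] / mlen[row]
                remaining[b] -= mlen[row]
                if remaining[b] <= 1e-9:
                    alive[b] = False
                    new_tips.append((nid, bdir[b].copy()))
            if n_own > sub_start:
                _mark_covered(pos_buf[sub_start:n_own])
            if len(territory):
                state.coverage = float(covered.mean())
            if state.coverage >= purk.delta_cov:
                stop = True
                break
        state.tips = new_tips
    net.fascicle_roots.setdefault(label, own_first)
    return net


# --------------------------------------------------------------------- PVJs


def place_pvjs(net: PurkinjeNetwork, purk: PurkinjeConfig, seed) -> PurkinjeNetwork:
    """Stochastically seed PVJ stems along each fascicle network.

    Linear density lambda = delta_cov / mu (junctions per um).  A
    depth-first traversal from each fascicle root accumulates the arc
    distance d since the last junction; every node is accepted with
    probability min(1, lambda*d).  An accepted junction becomes a stem of
    one resolution length attached at the midpoint of the segment on which
    acceptance occurred, oriented into the wall; HIS segments are exempt.
    """
    rng = np.random.default_rng(seed)
    lam = purk.delta_cov / purk.mu  # per um
    if lam <= 0 or net.n_segments == 0:
        return net
    res_mm = purk.segment_resolution / 1000.0
    for name in sorted(net.fascicle_roots):
        root = net.fascicle_roots[name]
        visited = {root}
        stack = [(root, 0.0)]
        while stack:
            node, d = stack.pop()
            for sid in list(net.child_segments(node)):
                if net.seg_label[sid] == "his":
                    continue
                child = net.seg_child[sid]
                if child in visited:
                    continue
                visited.add(child)
                d_here = d + net.seg_length[sid]
                p = min(1.0, lam * d_here)
                if rng.random() < p:
                    _attach_stem(net, sid, res_mm)
                    d_here = 0.0
                stack.append((child, d_here))
    return net


def _attach_stem(net: PurkinjeNetwork, sid: int, res_mm: float):
    """Split segment ``sid`` at its midpoint and hang a transmural stem there."""
    parent, child = net.seg_parent[sid], net.seg_child[sid]
    label = net.seg_label[sid]
    half = net.seg_length[sid] / 2.0
    mid_pos = 0.5 * (net.node_position(parent) + net.node_position(child))
    normal = net._normal[child]
    if not np.all(np.isfinite(normal)):
        normal = net._normal[parent]
    mid = net.add_node(mid_pos, PVJ_STEM, normal)
    # rewire: parent -> mid -> child
    net.seg_child[sid] = mid
    net.seg_length[sid] = half
    net._parents[child].remove(sid)
    net._children[mid] = []
    net._parents[mid].append(sid)
    net.add_segment(mid, child, label, length_um=half)
    # stem into the wall
    inward = -normal if np.all(np.isfinite(normal)) else np.array([0.0, 0.0, -1.0])
    inward = inward / np.linalg.norm(inward)
    tip = net.add_node(mid_pos + res_mm * inward, PVJ, normal)
    net.add_segment(mid, tip, label, length_um=res_mm * 1000.0)


def extend_transmural(
    net: PurkinjeNetwork,
    mesh: BivMesh,
    eas: EASConfig,
    purk: PurkinjeConfig,
    seed,
) -> PurkinjeNetwork:
    """Ray-trace each PVJ stem through the wall and set tissue couplings.

    The stem base casts a ray along the inward endocardial normal; the
    paired distance D to the next boundary surface is scaled by s_rho and a
    Gaussian factor g ~ N(1, sigma):  l = clamp(s_rho*D*max(0.25, g), 0,
    0.95*D).  PVJs whose ray finds no pairing surface are dropped and
    counted.  Couplings attach each final PVJ to its nearest mesh node.
    """
    from .geometry import surface_ray_pairs

    rng = np.random.default_rng(seed)
    pvjs = net.pvj_nodes()
    if len(pvjs) == 0:
        net.pvj_couplings = []
        return net
    bases = np.array([net.seg_parent[net._parents[j][0]] for j in pvjs])
    base_pos = net.positions[bases]
    labels = np.array([net.seg_label[net._parents[j][0]] for j in pvjs])
    lv_tags = {f for f in FASCICLE_ORDER if f.startswith("lv")}

    lengths = np.zeros(len(pvjs))
    dirs = np.zeros((len(pvjs), 3))
    ok_all = np.zeros(len(pvjs), dtype=bool)
    for tag, is_lv in ((LV_ENDO, True), (RV_ENDO, False)):
        m = np.array([(lb in lv_tags) == is_lv for lb in labels])
        if not m.any():
            continue
        idx, normals = mesh.node_normals(tag)
        tree = cKDTree(mesh.nodes[idx])
        _, k = tree.query(base_pos[m])
        dtag = -normals[k]
        hit, t, ok = _cast(mesh, base_pos[m], dtag, tag)
        g = rng.normal(1.0, purk.sigma, size=int(m.sum())) if purk.sigma > 0 else np.ones(int(m.sum()))
        ell = np.clip(eas.s_rho * t * np.maximum(0.25, g), 0.0, 0.95 * t)
        lengths[m] = ell
        dirs[m] = dtag
        ok_all[m] = ok

    keep = ok_all & np.isfinite(lengths)
    net.pvj_dropped = int((~keep).sum())
    drop = [int(j) for j, k in zip(pvjs, keep) if not k]
    for j in drop:
        sid = net._parents[j][0]
        net.seg_length[sid] = 0.0  # orphaned stem marker; node pruned on export
        net._role[j] = PVJ_STEM    # no longer a junction
    tissue_tree = cKDTree(mesh.nodes)
    couplings = []
    for pos0, j, ell, d, k in zip(base_pos, pvjs, lengths, dirs, keep):
        if not k:
            continue
        new_pos = pos0 + ell * d
        net._pos[j] = new_pos
        sid = net._parents[j][0]
        net.seg_length[sid] = ell * 1000.0
        _, tn = tissue_tree.query(new_pos)
        couplings.append((int(j), int(tn)))
    net.pvj_couplings = couplings
    return net


def _cast(mesh, origins, dirs, tag):
    others = [t for t in (LV_ENDO, RV_ENDO, 3, 4) if t != tag]
    target = mesh.surface(others)
    hit, t, f = target.ray_hits(origins, dirs, min_t=1e-6)
    return hit, t, np.isfinite(t)


# ---------------------------------------------------------------- composite


def build_full_purkinje(
    mesh: BivMesh,
    frame: UVCFrame,
    layer: SELayer,
    eas: EASConfig,
    purk: PurkinjeConfig,
    seed: int,
    with_pvjs: bool = True,
) -> PurkinjeNetwork:
    """His bundle + five fascicle networks + PVJs + transmural extension.

    Each fascicle draws from a named substream of the master seed so the
    fascicles are independently reproducible.
    """
    net = build_his_bundle(frame, purk, eas, layer)
    master = np.random.SeedSequence(seed)
    streams = master.spawn(len(FASCICLE_ORDER) + 2)
    for name, ss in zip(FASCICLE_ORDER, streams):
        start = net.fascicle_roots[name]
        grow_fascicle_network(
            frame, layer, start, purk, ss, net=net, start_node=start, label=name
        )
    if with_pvjs and purk.delta_cov > 0:
        place_pvjs(net, purk, streams[-2])
        extend_transmural(net, mesh, eas, purk, streams[-1])
    return net
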