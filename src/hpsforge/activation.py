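"""Graph-eikonal activation over the coupled Purkinje + myocardium domain.

First-arrival activation times are computed by one multi-source Dijkstra
solve on a directed weighted graph.  Tissue vertices are the mesh nodes;
tissue edges are tetrahedral element edges augmented with 2-ring diagonals
(reducing the metrication error of graph distances relative to the true
eikonal solution), weighted by Euclidean length over conduction velocity.
In fascicle mode, edges lying entirely inside the fast sub-endocardial
layer conduct at the Purkinje velocity.  In Purkinje mode, the cable
network contributes its own vertices and bidirectional edges, and each
Purkinje-ventricular junction adds one anterograde (network->tissue) and
one retrograde (tissue->network) edge whose weights are the respective
coupling delays — a single shortest-path solve then captures orthodromic,
antidromic, anterograde and retrograde interplay simultaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra

from .config import FASCICLE_ORDER, SimulationConfig
from .fascicle import FascicleHPS, SELayer
from .geometry import BivMesh, UVCCoord, UVCFrame, uvc_to_cartesian
from .purkinje import PurkinjeNetwork

B_PACE = UVCCoord(0.3, 0.0, 0.0, 1)  # RV apical pacing site


@dataclass
class PropagationGraph:
    """Directed weighted graph over tissue (and optionally network) vertices.

    Vertices 0..n_tissue-1 are mesh nodes; network node i maps to vertex
    n_tissue + i.
    """

    weights: csr_matrix
    n_tissue: int
    n_network: int = 0
    mode: str = "tissue"

    @property
    def n_vertices(self):
        return self.n_tissue + self.n_network

    def network_vertex(self, net_node: int) -> int:
        return self.n_tissue + net_node


@dataclass
class ActivationMap:
    """Earliest arrival time (ms) per vertex; unreached vertices are NaN-free inf."""

    times: np.ndarray
    n_tissue: int
    source_description: str = ""

    @property
    def tissue_times(self) -> np.ndarray:
        return self.times[: self.n_tissue]

    @property
    def unreached(self) -> np.ndarray:
        return ~np.isfinite(self.times)


@dataclass
class PacingProtocol:
    """Scenario name plus explicit (vertex, time ms) sources."""

    scenario: str
    sources: list  # [(vertex, time_ms)]

    def __post_init__(self):
        if not self.sources:
            raise ValueError("pacing protocol needs at least one source")
        if any(t < 0 for _, t in self.sources):
            raise ValueError("source times must be >= 0")


def _tissue_edges(mesh: BivMesh):
    """Unique element edges plus 2-ring diagonals (vectorized)."""
    t = mesh.elements
    pairs = np.vstack([t[:, [i, j]] for i in range(4) for j in range(i + 1, 4)])
    pairs = np.unique(np.sort(pairs, axis=1), axis=0)
    n = len(mesh.nodes)
    a = coo_matrix((np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)).tocsr()
    a = a + a.T
    a.data[:] = 1.0
    two_ring = (a @ a).tocoo()
    mask = np.asarray(a[two_ring.row, two_ring.col]).ravel() == 0
    mask &= two_ring.row < two_ring.col
    extra = np.column_stack([two_ring.row[mask], two_ring.col[mask]])
    return np.vstack([pairs, extra])


def assemble_graph(
    mesh: BivMesh,
    layer: SELayer | None,
    net: PurkinjeNetwork | None,
    sim: SimulationConfig,
    frame: UVCFrame | None = None,
) -> PropagationGraph:
    """Build the propagation graph in fascicle or Purkinje mode.

    Exactly one of ``layer`` (fascicle mode: fast SE edges) and ``net``
    (Purkinje mode: cable vertices and PVJ coupling edges) must be given.
    ``frame`` is only needed for the optional transversely isotropic
    myocardium (``sim.anisotropy_ratio != 1``).
    """
    if (layer is None) == (net is None):
        raise ValueError("select exactly one mode: SE layer (fascicle) or network (Purkinje)")
    edges = _tissue_edges(mesh)
    p = mesh.nodes
    lengths = np.linalg.norm(p[edges[:, 0]] - p[edges[:, 1]], axis=1)
    cv = np.full(len(edges), sim.cv_myo)
    if sim.anisotropy_ratio != 1.0:
        if frame is None:
            raise ValueError("anisotropic conduction requires the UVC frame")
        cv = _anisotropic_cv(mesh, frame, edges, sim)
    w = lengths / cv  # mm / (mm/ms) = ms

    n_t = len(p)
    rows = np.concatenate([edges[:, 0], edges[:, 1]])
    cols = np.concatenate([edges[:, 1], edges[:, 0]])
    vals = np.concatenate([w, w])
    if layer is not None:
        # fast edges follow each endocardial *surface* (with its own 2-ring
        # augmentation) so the thin layer cannot tunnel through the septal
        # wall or jump between the two ventricles' endocardia
        fe = _fast_surface_edges(mesh, layer)
        fw = np.linalg.norm(p[fe[:, 0]] - p[fe[:, 1]], axis=1) / sim.cv_purk
        rows = np.concatenate([rows, fe[:, 0], fe[:, 1]])
        cols = np.concatenate([cols, fe[:, 1], fe[:, 0]])
        vals = np.concatenate([vals, fw, fw])

    n_net = 0
    if net is not None:
        n_net = len(net)
        sp = np.asarray(net.seg_parent) + n_t
        sc = np.asarray(net.seg_child) + n_t
        sw = np.asarray(net.seg_length) / 1000.0 / sim.cv_purk
        rows = np.concatenate([rows, sp, sc])
        cols = np.concatenate([cols, sc, sp])
        vals = np.concatenate([vals, sw, sw])
        if net.pvj_couplings:
            pv = np.asarray([c[0] for c in net.pvj_couplings]) + n_t
            tv = np.asarray([c[1] for c in net.pvj_couplings])
            rows = np.concatenate([rows, pv, tv])
            cols = np.concatenate([cols, tv, pv])
            vals = np.concatenate(
                [vals, np.full(len(pv), sim.delay_antero), np.full(len(pv), sim.delay_retro)]
            )
    n = n_t + n_net
    # duplicate (u, v) entries would sum in COO; keep the minimum instead
    wmat = _dedupe_min(rows, cols, vals, n)

    ncomp, _ = connected_components(wmat[:n_t, :n_t], directed=False)
    if ncomp > 1:
        raise ValueError(f"tissue graph is disconnected ({ncomp} components)")
    return PropagationGraph(wmat, n_t, n_net, "fascicle" if layer is not None else "purkinje")


def _fast_surface_edges(mesh: BivMesh, layer: SELayer) -> np.ndarray:
    """SE-layer fast-conduction vertex pairs, one endocardial surface at a time.

    For each endocardial tag, take the surface-triangle edges whose
    endpoints are both SE members and augment them with the surface graph's
    own 2-ring diagonals.
    """
    from .geometry import LV_ENDO, RV_ENDO

    out = []
    for tag in (LV_ENDO, RV_ENDO):
        tris = mesh.surface_triangles[mesh.surface_tags == tag]
        e = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
        e = e[layer.is_member(e).all(axis=1)]
        if len(e) == 0:
            continue
        e = np.unique(np.sort(e, axis=1), axis=0)
        n = len(mesh.nodes)
        a = coo_matrix((np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(n, n)).tocsr()
        a = a + a.T
        a.data[:] = 1.0
        two = (a @ a).tocoo()
        m = (np.asarray(a[two.row, two.col]).ravel() == 0) & (two.row < two.col)
        out.append(e)
        out.append(np.column_stack([two.row[m], two.col[m]]))
    return np.vstack(out)


def _dedupe_min(rows, cols, vals, n):
    order = np.lexsort((vals, cols, rows))
    r, c, v = rows[order], cols[order], vals[order]
    first = np.ones(len(r), dtype=bool)
    first[1:] = (r[1:] != r[:-1]) | (c[1:] != c[:-1])
    return csr_matrix((v[first], (r[first], c[first])), shape=(n, n))


def _anisotropic_cv(mesh, frame, edges, sim):
    """Edge-wise velocity for a rule-based transmural fiber rotation.

    Fibers run circumferentially, rotating linearly from +60 deg at the
    endocardium to -60 deg at the epicardium about the local radial
    direction; conduction is cv_myo along the fiber and cv_myo /
    anisotropy_ratio across it.
    """
    p = mesh.nodes
    mid = 0.5 * (p[edges[:, 0]] + p[edges[:, 1]])
    rho = 0.5 * (frame.rho[edges[:, 0]] + frame.rho[edges[:, 1]])
    radial = mid.copy()
    radial[:, 2] = 0
    nr = np.linalg.norm(radial, axis=1, keepdims=True)
    radial = np.where(nr > 1e-9, radial / np.maximum(nr, 1e-12), [[1.0, 0, 0]])
    circ = np.cross([0.0, 0.0, 1.0], radial)
    circ /= np.linalg.norm(circ, axis=1, keepdims=True)
    apex = np.cross(radial, circ)
    alpha = np.radians(60.0) * (1 - 2 * rho)
    fiber = circ * np.cos(alpha)[:, None] + apex * np.sin(alpha)[:, None]
    e = p[edges[:, 1]] - p[edges[:, 0]]
    e /= np.linalg.norm(e, axis=1, keepdims=True)
    cosang = np.abs(np.einsum("ij,ij->i", e, fiber))
    cv_t = sim.cv_myo / sim.anisotropy_ratio
    return np.sqrt((sim.cv_myo * cosang) ** 2 + (cv_t * np.sqrt(1 - cosang**2)) ** 2)


def solve_activation(g: PropagationGraph, protocol: PacingProtocol) -> ActivationMap:
    """Multi-source Dijkstra with per-source time offsets.

    A virtual super-source is linked to every pacing vertex with its
    prescribed time as the edge weight; one Dijkstra pass then yields the
    earliest arrival everywhere.  Unreached vertices stay +inf.

    Sources are Dirichlet data: after the solve each source vertex is reset
    to its prescribed time, even where propagation from another source
    arrives earlier (a timed stimulus fires when told to; tissue around it
    may still activate first).
    """
    if g.weights.data.size and g.weights.data.min() < 0:
        raise ValueError("negative edge weight in propagation graph")
    n = g.n_vertices
    rows = [n] * len(protocol.sources)
    cols = [v for v, _ in protocol.sources]
    vals = [t for _, t in protocol.sources]
    w = g.weights.tocoo()
    big = coo_matrix(
        (np.concatenate([w.data, vals]),
         (np.concatenate([w.row, rows]), np.concatenate([w.col, cols]))),
        shape=(n + 1, n + 1),
    ).tocsr()
    times = dijkstra(big, directed=True, indices=n)[:n]
    prescribed: dict[int, float] = {}
    for v, t in protocol.sources:
        prescribed[v] = min(prescribed.get(v, np.inf), t)
    for v, t in prescribed.items():
        times[v] = t
    return ActivationMap(times, g.n_tissue, protocol.scenario)


def run_scenario(
    mesh: BivMesh,
    frame: UVCFrame,
    hps,
    sim: SimulationConfig,
    scenario: str,
    layer: SELayer | None = None,
):
    """Run one pacing scenario for either HPS representation.

    ``hps`` is a FascicleHPS (fascicle mode) or PurkinjeNetwork (Purkinje
    mode; ``layer`` ignored).  Scenarios: 'sinus' fires the His root /
    timed discs; 'rv_apical' paces the mapped RV apical site at t = 0 —
    the fascicle model then keeps its fast SE layer but fires no timed
    sources, so retrograde activation re-enters the fast layer.

    Returns (ActivationMap, {fascicle: activation time at its root node}).
    """
    if scenario not in ("sinus", "rv_apical"):
        raise ValueError(f"unknown scenario {scenario!r}")
    if isinstance(hps, FascicleHPS):
        layer = hps.layer
        g = assemble_graph(mesh, layer, None, sim, frame)
        if scenario == "sinus":
            sources = [
                (int(v), hps.firing_times[name])
                for name in FASCICLE_ORDER
                for v in hps.disc_nodes[name]
            ]
        else:
            pace, _ = uvc_to_cartesian(frame, B_PACE)
            sources = [(pace, 0.0)]
        amap = solve_activation(g, PacingProtocol(scenario, sources))
        report = {name: float(amap.times[hps.root_nodes[name]]) for name in FASCICLE_ORDER}
    elif isinstance(hps, PurkinjeNetwork):
        g = assemble_graph(mesh, None, hps, sim, frame)
        if scenario == "sinus":
            sources = [(g.network_vertex(hps.root), 0.0)]
        else:
            pace, _ = uvc_to_cartesian(frame, B_PACE)
            sources = [(pace, 0.0)]
        amap = solve_activation(g, PacingProtocol(scenario, sources))
        report = {
            name: float(amap.times[g.network_vertex(hps.fascicle_roots[name])])
            for name in FASCICLE_ORDER
        }
    else:
        raise TypeError(f"unsupported HPS representation: {type(hps).__name__}")
    if not np.isfinite(amap.tissue_times).all():
        nbad = int((~np.isfinite(amap.tissue_times)).sum())
        if nbad == len(amap.tissue_times):
            raise ValueError("pacing source unreachable: no tissue activated")
    return amap, report
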