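"""Phenomenological fascicle-based His-Purkinje representation.

The fascicle model replaces the Purkinje network by (i) a thin
fast-conducting sub-endocardial (SE) layer bounded apicobasally, and (ii)
five disc-shaped earliest-activation-site (EAS) sources centred on the
fascicular root locations, fired at prescribed timings.  Discs are geodesic
neighbourhoods on the endocardial surface graph so they hug the curved
endocardium; their radius is ``delta_rad`` times the apicobasal endocardial
arc length of the owning ventricle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import dijkstra

from .config import EASConfig, FascicleConfig
from .geometry import BivMesh, LV_ENDO, RV_ENDO, UVCFrame, uvc_to_cartesian


@dataclass
class SELayer:
    """Sub-endocardial layer membership.

    ``node_indices`` are all mesh nodes with z in [s_z_min, s_z_max] and
    d_endo <= s_rho (both endocardia, including the RV-facing septal face).
    ``element_indices`` are tetrahedra with at least three member nodes
    (the layer is about one element deep, so the all-four rule would leave
    it empty on coarse meshes).  ``surface_graph`` is the endocardial
    surface triangulation restricted to member nodes, with Euclidean edge
    weights (mm), used for geodesic disc construction.
    """

    mesh: BivMesh
    frame: UVCFrame
    eas: EASConfig
    node_indices: np.ndarray
    element_indices: np.ndarray
    surface_graph: csr_matrix = field(repr=False)
    _member: np.ndarray = field(repr=False)

    def is_member(self, nodes) -> np.ndarray:
        return self._member[nodes]

    def territory_nodes(self, tag) -> np.ndarray:
        """Member nodes lying on the given endocardial surface."""
        on_surf = self.mesh.surface_nodes(tag)
        return on_surf[self._member[on_surf]]


def select_se_layer(frame: UVCFrame, eas: EASConfig, mesh: BivMesh) -> SELayer:
    """All nodes within the configured SE bounds, plus their surface graph."""
    member = (
        (frame.z >= eas.s_z_min)
        & (frame.z <= eas.s_z_max)
        & (frame.d_endo <= eas.s_rho)
    )
    node_indices = np.flatnonzero(member)
    if len(node_indices) == 0:
        raise ValueError("SE layer bounds exclude the entire mesh")
    in_count = member[mesh.elements].sum(axis=1)
    element_indices = np.flatnonzero(in_count >= 3)

    tris = mesh.surface_triangles[np.isin(mesh.surface_tags, [LV_ENDO, RV_ENDO])]
    all_edges = np.vstack([tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]])
    m = member[all_edges].all(axis=1)
    e = all_edges[m]
    w = np.linalg.norm(mesh.nodes[e[:, 0]] - mesh.nodes[e[:, 1]], axis=1)
    n = len(frame)
    g = coo_matrix((w, (e[:, 0], e[:, 1])), shape=(n, n)).tocsr()
    g = g.maximum(g.T)
    return SELayer(mesh, frame, eas, node_indices, element_indices, g, member)


@dataclass
class FascicleHPS:
    """Five timed EAS discs over a fast SE layer."""

    layer: SELayer
    disc_nodes: dict        # fascicle name -> np.ndarray of mesh node indices
    firing_times: dict      # fascicle name -> ms
    root_nodes: dict        # fascicle name -> mapped mesh node index


def build_fascicle_hps(
    frame: UVCFrame, layer: SELayer, eas: EASConfig, fasc: FascicleConfig
) -> FascicleHPS:
    """Collect each EAS disc as a geodesic neighbourhood of its mapped root.

    The disc of root b is every SE node within surface-graph distance
    ``delta_rad * L_ab`` of the node b maps to, where L_ab is the
    apicobasal endocardial arc length of the fascicle's ventricle.
    """
    discs, times, roots = {}, {}, {}
    for name, b in eas.roots.items():
        i, _ = uvc_to_cartesian(frame, b)
        if not layer.is_member([i])[0]:
            raise ValueError(f"root {name} maps to node {i} outside the SE layer")
        nu = -1 if name.startswith("lv") else 1
        radius = fasc.delta_rad * frame.l_ab[nu]
        dist = dijkstra(layer.surface_graph, directed=False, indices=i, limit=radius * 1.001)
        members = np.flatnonzero(np.isfinite(dist) & (dist <= radius))
        if i not in members:
            members = np.append(members, i)
        discs[name] = members
        times[name] = fasc.timings[name]
        roots[name] = i
    return FascicleHPS(layer, discs, times, roots)
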