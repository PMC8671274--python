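"""Readers and writers for all artifacts.

Formats
-------
* Tetrahedral meshes: ASCII VTK XML unstructured grid (``.vtu``) with UVC
  and tag arrays, and the CARP-style ``.pts``/``.elem``/``.lon`` text
  triplet (0-based node indices).
* Purkinje networks: ASCII VTK XML polydata (``.vtp``) with node roles and
  segment labels, and a plain-text cable format (node table + segment
  table) that round-trips the full network including couplings.
* Activation maps: one-value-per-line ``.dat`` (CARP convention) aligned
  with the mesh node order.
* ECGs: CSV with a time column and one column per lead.

Floats are written with ``repr`` precision so write-then-read round-trips
are lossless.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .ecg import ECG12, LEAD_ORDER
from .geometry import BivMesh, GeometryParams, UVCFrame
from .purkinje import PurkinjeNetwork, ROLE_NAMES


def _fmt(x):
    return repr(float(x))


# ----------------------------------------------------------------------- VTU


def write_vtu(path, mesh: BivMesh, frame: UVCFrame | None = None, point_data=None):
    """ASCII .vtu with element regions, surface tags folded to nodes, and UVC."""
    pd = dict(point_data or {})
    if frame is not None:
        pd.update(
            {"z": frame.z, "rho": frame.rho, "phi": frame.phi,
             "nu": frame.nu, "d_endo": frame.d_endo}
        )
    n, m = len(mesh.nodes), len(mesh.elements)
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">\n')
        f.write(f'<UnstructuredGrid><Piece NumberOfPoints="{n}" NumberOfCells="{m}">\n')
        f.write('<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        for p in mesh.nodes:
            f.write(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        f.write("</DataArray></Points>\n<Cells>\n")
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        for e in mesh.elements:
            f.write(f"{e[0]} {e[1]} {e[2]} {e[3]}\n")
        f.write('</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        f.write(" ".join(str(4 * (i + 1)) for i in range(m)) + "\n")
        f.write('</DataArray>\n<DataArray type="UInt8" Name="types" format="ascii">\n')
        f.write(" ".join("10" for _ in range(m)) + "\n")
        f.write("</DataArray>\n</Cells>\n")
        f.write("<PointData>\n")
        for name, arr in pd.items():
            f.write(f'<DataArray type="Float64" Name="{name}" format="ascii">\n')
            f.write(" ".join(_fmt(v) for v in np.asarray(arr, dtype=float)) + "\n")
            f.write("</DataArray>\n")
        f.write("</PointData>\n<CellData>\n")
        f.write('<DataArray type="Int64" Name="region" format="ascii">\n')
        f.write(" ".join(str(int(r)) for r in mesh.element_region) + "\n")
        f.write("</DataArray>\n</CellData>\n")
        f.write("</Piece></UnstructuredGrid></VTKFile>\n")


def read_vtu(path):
    """Read back a mesh written by :func:`write_vtu`.

    Returns (nodes, elements, region, point_data).  Surface triangles are
    not stored in .vtu; reconstruct them with the geometry module or read
    the CARP triplet for a full BivMesh.
    """
    root = ET.parse(path).getroot()
    piece = root.find(".//Piece")
    pts = piece.find("Points/DataArray")
    nodes = np.fromstring(" ".join(pts.text.split()), sep=" ").reshape(-1, 3)
    arrays = {a.get("Name"): a for a in piece.find("Cells")}
    conn = np.fromstring(arrays["connectivity"].text, sep=" ", dtype=int).reshape(-1, 4)
    point_data = {}
    for a in piece.find("PointData") or []:
        point_data[a.get("Name")] = np.fromstring(a.text, sep=" ")
    region = None
    cd = piece.find("CellData")
    if cd is not None:
        for a in cd:
            if a.get("Name") == "region":
                region = np.fromstring(a.text, sep=" ", dtype=int)
    return nodes, conn, region, point_data


# ----------------------------------------------------------------------- VTP


def write_vtp(path, net: PurkinjeNetwork):
    """ASCII .vtp polydata: nodes as points, segments as 2-point lines."""
    pos = net.positions
    labels = sorted(set(net.seg_label))
    lab_id = {lb: i for i, lb in enumerate(labels)}
    with open(path, "w") as f:
        f.write('<?xml version="1.0"?>\n')
        f.write('<VTKFile type="PolyData" version="0.1" byte_order="LittleEndian">\n')
        f.write(
            f'<PolyData><Piece NumberOfPoints="{len(pos)}" NumberOfLines="{net.n_segments}">\n'
        )
        f.write('<Points><DataArray type="Float64" NumberOfComponents="3" format="ascii">\n')
        for p in pos:
            f.write(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
        f.write("</DataArray></Points>\n")
        f.write("<Lines>\n")
        f.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        for a, b in zip(net.seg_parent, net.seg_child):
            f.write(f"{a} {b}\n")
        f.write('</DataArray>\n<DataArray type="Int64" Name="offsets" format="ascii">\n')
        f.write(" ".join(str(2 * (i + 1)) for i in range(net.n_segments)) + "\n")
        f.write("</DataArray>\n</Lines>\n")
        f.write('<PointData><DataArray type="Int64" Name="role" format="ascii">\n')
        f.write(" ".join(str(int(r)) for r in net.roles) + "\n")
        f.write("</DataArray></PointData>\n")
        f.write("<CellData>\n")
        f.write('<DataArray type="Int64" Name="fascicle" format="ascii">\n')
        f.write(" ".join(str(lab_id[lb]) for lb in net.seg_label) + "\n")
        f.write('</DataArray>\n<DataArray type="Float64" Name="length_um" format="ascii">\n')
        f.write(" ".join(_fmt(v) for v in net.seg_length) + "\n")
        f.write("</DataArray>\n</CellData>\n")
        f.write(f"<!-- labels: {json.dumps(labels)} -->\n")
        f.write("</Piece></PolyData></VTKFile>\n")


def read_vtp(path):
    """Read back a network written by :func:`write_vtp` (topology + roles)."""
    text = Path(path).read_text()
    root = ET.fromstring(text)
    piece = root.find(".//Piece")
    pos = np.fromstring(" ".join(piece.find("Points/DataArray").text.split()), sep=" ").reshape(-1, 3)
    lines = {a.get("Name"): a for a in piece.find("Lines")}
    conn = np.fromstring(lines["connectivity"].text, sep=" ", dtype=int).reshape(-1, 2)
    roles = np.fromstring(piece.find("PointData/DataArray").text, sep=" ", dtype=int)
    cd = {a.get("Name"): a for a in piece.find("CellData")}
    lab_idx = np.fromstring(cd["fascicle"].text, sep=" ", dtype=int)
    lengths = np.fromstring(cd["length_um"].text, sep=" ")
    labels = None
    for line in text.splitlines():
        if line.startswith("<!-- labels:"):
            labels = json.loads(line[len("<!-- labels:"): -len(" -->")])
    net = PurkinjeNetwork()
    for p, r in zip(pos, roles):
        net.add_node(p, int(r))
    for (a, b), li, lg in zip(conn, lab_idx, lengths):
        net.add_segment(int(a), int(b), labels[li], length_um=float(lg))
    return net


# ---------------------------------------------------------------- cable text


def write_cable(path, net: PurkinjeNetwork):
    """Plain-text cable format: full lossless network dump."""
    with open(path, "w") as f:
        f.write("# hpsforge purkinje cable v1\n")
        f.write(f"meta root={net.root}\n")
        f.write(f"meta dropped={net.pvj_dropped}\n")
        f.write(
            "meta fascicle_roots="
            + json.dumps({k: int(v) for k, v in net.fascicle_roots.items()})
            + "\n"
        )
        f.write(f"nodes {len(net)}\n")
        for i, (p, nrm, r) in enumerate(zip(net._pos, net._normal, net._role)):
            f.write(
                f"{i} {_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])} {r} "
                f"{_fmt(nrm[0])} {_fmt(nrm[1])} {_fmt(nrm[2])}\n"
            )
        f.write(f"segments {net.n_segments}\n")
        for i in range(net.n_segments):
            f.write(
                f"{i} {net.seg_parent[i]} {net.seg_child[i]} "
                f"{_fmt(net.seg_length[i])} {net.seg_label[i]}\n"
            )
        f.write(f"couplings {len(net.pvj_couplings)}\n")
        for a, b in net.pvj_couplings:
            f.write(f"{a} {b}\n")


def read_cable(path):
    lines = Path(path).read_text().splitlines()
    it = iter(lines)
    header = next(it)
    if "purkinje cable" not in header:
        raise ValueError(f"{path}: not a cable file (bad header {header!r})")
    net = PurkinjeNetwork()
    meta = {}
    line = next(it)
    while line.startswith("meta "):
        key, val = line[5:].split("=", 1)
        meta[key] = val
        line = next(it)
    kind, count = line.split()
    if kind != "nodes":
        raise ValueError(f"{path}: expected node table, got {line!r}")
    for _ in range(int(count)):
        parts = next(it).split()
        net.add_node(
            [float(parts[1]), float(parts[2]), float(parts[3])],
            int(parts[4]),
            [float(parts[5]), float(parts[6]), float(parts[7])],
        )
    kind, count = next(it).split()
    for k in range(int(count)):
        parts = next(it).split()
        net.add_segment(int(parts[1]), int(parts[2]), parts[4], length_um=float(parts[3]))
    kind, count = next(it).split()
    net.pvj_couplings = [tuple(map(int, next(it).split())) for _ in range(int(count))]
    net.root = None if meta.get("root") == "None" else int(meta["root"])
    net.pvj_dropped = int(meta.get("dropped", 0))
    net.fascicle_roots = {k: int(v) for k, v in json.loads(meta["fascicle_roots"]).items()}
    return net


def write_pvj_couplings(path, net: PurkinjeNetwork):
    """Two-column (network node, tissue node) index file."""
    with open(path, "w") as f:
        for a, b in net.pvj_couplings:
            f.write(f"{a} {b}\n")


# ---------------------------------------------------------------- CARP text


def write_carp(prefix, mesh: BivMesh, fibers=None):
    """CARP-style .pts/.elem/.lon triplet (plus .surf with tagged triangles)."""
    prefix = str(prefix)
    with open(prefix + ".pts", "w") as f:
        f.write(f"{len(mesh.nodes)}\n")
        for p in mesh.nodes:
            f.write(f"{_fmt(p[0])} {_fmt(p[1])} {_fmt(p[2])}\n")
    with open(prefix + ".elem", "w") as f:
        f.write(f"{len(mesh.elements)}\n")
        for e, r in zip(mesh.elements, mesh.element_region):
            f.write(f"Tt {e[0]} {e[1]} {e[2]} {e[3]} {int(r)}\n")
    with open(prefix + ".lon", "w") as f:
        f.write("1\n")
        if fibers is None:
            fibers = np.tile([1.0, 0.0, 0.0], (len(mesh.elements), 1))
        for v in fibers:
            f.write(f"{_fmt(v[0])} {_fmt(v[1])} {_fmt(v[2])}\n")
    with open(prefix + ".surf", "w") as f:
        f.write(f"{len(mesh.surface_triangles)}\n")
        for t, tag in zip(mesh.surface_triangles, mesh.surface_tags):
            f.write(f"Tr {t[0]} {t[1]} {t[2]} {int(tag)}\n")


def read_carp(prefix):
    """Read the triplet back: (nodes, elements, regions, triangles, tags)."""
    prefix = str(prefix)
    pts_lines = Path(prefix + ".pts").read_text().splitlines()
    n = int(pts_lines[0])
    nodes = np.array([[float(v) for v in ln.split()] for ln in pts_lines[1 : n + 1]])
    el_lines = Path(prefix + ".elem").read_text().splitlines()
    m = int(el_lines[0])
    elements, regions = [], []
    for ln in el_lines[1 : m + 1]:
        parts = ln.split()
        if parts[0] != "Tt":
            raise ValueError(f"{prefix}.elem: unsupported element {parts[0]!r}")
        elements.append([int(v) for v in parts[1:5]])
        regions.append(int(parts[5]))
    tris, tags = [], []
    surf = Path(prefix + ".surf")
    if surf.exists():
        s_lines = surf.read_text().splitlines()
        for ln in s_lines[1 : int(s_lines[0]) + 1]:
            parts = ln.split()
            tris.append([int(v) for v in parts[1:4]])
            tags.append(int(parts[4]))
    return (
        nodes,
        np.array(elements, dtype=np.intp),
        np.array(regions, dtype=np.intp),
        np.array(tris, dtype=np.intp),
        np.array(tags, dtype=np.intp),
    )


# ------------------------------------------------------------- maps and ECGs


def write_dat(path, values):
    with open(path, "w") as f:
        for v in np.asarray(values, dtype=float):
            f.write(_fmt(v) + "\n")


def read_dat(path):
    return np.array([float(x) for x in Path(path).read_text().split()])


def write_ecg_csv(path, ecg: ECG12):
    with open(path, "w") as f:
        f.write(f"# sample_rate_hz={_fmt(ecg.sample_rate)}\n")
        f.write("t_ms," + ",".join(LEAD_ORDER) + "\n")
        t = ecg.t_ms
        for j in range(ecg.leads.shape[1]):
            f.write(_fmt(t[j]) + "," + ",".join(_fmt(v) for v in ecg.leads[:, j]) + "\n")


def read_ecg_csv(path):
    lines = Path(path).read_text().splitlines()
    fs = float(lines[0].split("=")[1])
    rows = [[float(v) for v in ln.split(",")] for ln in lines[2:]]
    arr = np.array(rows)
    return ECG12(arr[:, 1:].T, fs)
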