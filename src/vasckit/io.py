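"""File I/O for spatial graphs and voxel volumes.

Two spatial-graph dialects are supported:

* ``amira_ascii`` — the AmiraMesh 3D ASCII SpatialGraph layout (``VERTEX``,
  ``EDGE``, ``POINT`` sections with ``VertexCoordinates``,
  ``EdgeConnectivity``, ``NumEdgePoints``, ``EdgePointCoordinates`` and
  ``thickness`` attributes).  The ``thickness`` attribute is interpreted as a
  radius by default; pass ``thickness_is_diameter=True`` to halve it on read.
* ``native_tabular`` — a plain-text format of two delimited tables (nodes;
  points) with ``#``-prefixed metadata lines; documented in
  :func:`write_spatial_graph`.

Voxel volumes travel as multi-page TIFF with the voxel size recorded in the
image description.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import tifffile

from .graph import ENDPOINT_TOL_UM, Node, Segment, SpatialGraph, VoxelVolume, validate_graph

__all__ = [
    "SpatialGraphParseError",
    "sniff_dialect",
    "read_spatial_graph",
    "write_spatial_graph",
    "read_volume",
    "write_volume",
]

AMIRA_HEADER = "# AmiraMesh 3D ASCII 2.0"
NATIVE_HEADER = "# vasckit spatial graph"


class SpatialGraphParseError(ValueError):
    """Malformed spatial-graph file; the message names the offending section."""


def sniff_dialect(path: str | Path) -> str:
    """Detect the dialect from the first line; raise if neither matches."""
    with open(path) as fh:
        first = fh.readline().strip()
    if first.startswith(AMIRA_HEADER.strip("# ").split()[0]) or first == AMIRA_HEADER:
        return "amira_ascii"
    if first.startswith(NATIVE_HEADER):
        return "native_tabular"
    raise SpatialGraphParseError(
        f"{path}: unrecognized spatial-graph header {first!r}; expected "
        f"{AMIRA_HEADER!r} or {NATIVE_HEADER!r}"
    )


def read_spatial_graph(
    path: str | Path,
    dialect: str = "auto",
    thickness_is_diameter: bool = False,
    endpoint_tol: float = ENDPOINT_TOL_UM,
) -> SpatialGraph:
    """Read a spatial graph, validating invariants after ingestion."""
    path = Path(path)
    if dialect == "auto":
        dialect = sniff_dialect(path)
    if dialect == "amira_ascii":
        g = _read_amira(path, thickness_is_diameter)
    elif dialect == "native_tabular":
        g = _read_native(path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    report = validate_graph(g, endpoint_tol=endpoint_tol)
    hard = [d for d in report.defects if d.kind in ("dangling reference", "endpoint mismatch")]
    if hard:
        raise SpatialGraphParseError(f"{path}: {hard[0].kind}: {hard[0].detail}")
    return g


def write_spatial_graph(g: SpatialGraph, path: str | Path, dialect: str = "native_tabular") -> None:
    """Write a spatial graph; the file round-trips to an equal graph."""
    for s in g.segments.values():
        if len(s.points) < 2:
            raise ValueError(f"segment {s.id} has fewer than 2 points")
    path = Path(path)
    if dialect == "amira_ascii":
        _write_amira(g, path)
    elif dialect == "native_tabular":
        _write_native(g, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# AmiraMesh ASCII
# ---------------------------------------------------------------------------

_DEFINE_RE = re.compile(r"^(?:define\s+|n)(\w+)\s+(\d+)")
_SECTION_RE = re.compile(r"^(\w+)\s*\{\s*(\w+)(?:\[(\d+)\])?\s+(\w+)\s*\}\s*=?\s*@(\d+)")


def _read_amira(path: Path, thickness_is_diameter: bool) -> SpatialGraph:
    text = path.read_text()
    if not text.lstrip().startswith("# AmiraMesh 3D ASCII"):
        raise SpatialGraphParseError(f"{path}: missing AmiraMesh ASCII header")

    counts: dict[str, int] = {}
    markers: dict[int, tuple[str, str, int, str]] = {}
    lines = text.splitlines()
    data_start = len(lines)
    for i, line in enumerate(lines):
        line = line.strip()
        m = _DEFINE_RE.match(line)
        if m:
            counts[m.group(1)] = int(m.group(2))
            continue
        m = _SECTION_RE.match(line)
        if m:
            section, dtype, width, name, marker = m.groups()
            markers[int(marker)] = (section, dtype, int(width or 1), name)
            continue
        if line.startswith("@"):
            data_start = i
            break

    for required in ("VERTEX", "EDGE", "POINT"):
        if required not in counts:
            raise SpatialGraphParseError(f"{path}: missing 'define {required}' count")

    # collect numeric blocks following each @N marker
    blocks: dict[int, list[list[float]]] = {}
    current: int | None = None
    for line in lines[data_start:]:
        line = line.strip()
        if not line:
            continue
        if line.startswith("@"):
            current = int(line[1:].split()[0])
            blocks[current] = []
            continue
        if current is not None:
            blocks[current].append([float(tok) for tok in line.replace(",", " ").split()])

    data: dict[tuple[str, str], np.ndarray] = {}
    for marker, (section, _dtype, width, name) in markers.items():
        if marker not in blocks:
            raise SpatialGraphParseError(f"{path}: data block @{marker} ({section}.{name}) missing")
        arr = np.asarray(blocks[marker], dtype=float)
        if arr.ndim == 2 and arr.shape[1] != width:
            raise SpatialGraphParseError(
                f"{path}: section {section}.{name} expects width {width}, got {arr.shape[1]}"
            )
        expected = counts[section]
        if len(arr) != expected:
            raise SpatialGraphParseError(
                f"{path}: section {section}.{name} has {len(arr)} rows, expected {expected}"
            )
        data[(section, name)] = arr

    try:
        vertices = data[("VERTEX", "VertexCoordinates")]
        connectivity = data[("EDGE", "EdgeConnectivity")].astype(int)
        n_edge_points = data[("EDGE", "NumEdgePoints")].astype(int).ravel()
        edge_points = data[("POINT", "EdgePointCoordinates")]
    except KeyError as exc:
        raise SpatialGraphParseError(f"{path}: missing required attribute {exc.args[0]}") from exc
    thickness_key = next((k for k in data if k[0] == "POINT" and k[1].lower() in ("thickness", "radius")), None)
    if thickness_key is None:
        raise SpatialGraphParseError(f"{path}: POINT section has no thickness/radius attribute")
    radii = data[thickness_key].ravel()
    if thickness_is_diameter:
        radii = radii / 2.0

    if n_edge_points.sum() != counts["POINT"]:
        raise SpatialGraphParseError(
            f"{path}: EDGE.NumEdgePoints sums to {n_edge_points.sum()}, POINT count is {counts['POINT']}"
        )
    if connectivity.size and connectivity.max() >= counts["VERTEX"]:
        raise SpatialGraphParseError(
            f"{path}: EDGE.EdgeConnectivity references vertex {connectivity.max()}, "
            f"only {counts['VERTEX']} defined"
        )

    nodes = [Node(id=i, position=vertices[i]) for i in range(counts["VERTEX"])]
    segments = []
    offset = 0
    for eid in range(counts["EDGE"]):
        npts = n_edge_points[eid]
        pts = edge_points[offset : offset + npts]
        rad = radii[offset : offset + npts]
        offset += npts
        segments.append(
            Segment(id=eid, start_node=int(connectivity[eid, 0]), end_node=int(connectivity[eid, 1]),
                    points=pts, radii=rad)
        )
    return SpatialGraph.build(nodes, segments, meta={"source": str(path), "dialect": "amira_ascii"})


def _write_amira(g: SpatialGraph, path: Path) -> None:
    node_ids = sorted(g.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    seg_ids = sorted(g.segments)
    n_points = sum(len(g.segments[s].points) for s in seg_ids)
    out = [
        AMIRA_HEADER,
        "",
        f"define VERTEX {len(node_ids)}",
        f"define EDGE {len(seg_ids)}",
        f"define POINT {n_points}",
        "",
        "Parameters {",
        '    ContentType "HxSpatialGraph"',
        "}",
        "",
        "VERTEX { float[3] VertexCoordinates } @1",
        "EDGE { int[2] EdgeConnectivity } @2",
        "EDGE { int NumEdgePoints } @3",
        "POINT { float[3] EdgePointCoordinates } @4",
        "POINT { float thickness } @5",
        "",
        "@1",
    ]
    fmt = "%.17g"
    for nid in node_ids:
        out.append(" ".join(fmt % v for v in g.nodes[nid].position))
    out += ["", "@2"]
    for sid in seg_ids:
        s = g.segments[sid]
        out.append(f"{index[s.start_node]} {index[s.end_node]}")
    out += ["", "@3"]
    for sid in seg_ids:
        out.append(str(len(g.segments[sid].points)))
    out += ["", "@4"]
    for sid in seg_ids:
        for p in g.segments[sid].points:
            out.append(" ".join(fmt % v for v in p))
    out += ["", "@5"]
    for sid in seg_ids:
        for r in g.segments[sid].radii:
            out.append(fmt % r)
    out.append("")
    path.write_text("\n".join(out))


# ---------------------------------------------------------------------------
# Native tabular dialect
# ---------------------------------------------------------------------------


def _write_native(g: SpatialGraph, path: Path) -> None:
    """Two tab-delimited tables with '#' metadata lines.

    Table 1 (``[nodes]``): node_id, x, y, z.
    Table 2 (``[points]``): segment_id, ordinal, x, y, z, radius,
    start_node, end_node (node ids repeated on every row of a segment).
    """
    fmt = "%.17g"
    out = [f"{NATIVE_HEADER} v1"]
    if g.meta:
        out.append("# meta " + json.dumps({k: v for k, v in g.meta.items() if isinstance(v, (str, int, float))}))
    out.append("# [nodes]")
    out.append("# node_id\tx\ty\tz")
    for nid in sorted(g.nodes):
        p = g.nodes[nid].position
        out.append(f"{nid}\t" + "\t".join(fmt % v for v in p))
    out.append("# [points]")
    out.append("# segment_id\tordinal\tx\ty\tz\tradius\tstart_node\tend_node")
    for sid in sorted(g.segments):
        s = g.segments[sid]
        for k, (p, r) in enumerate(zip(s.points, s.radii)):
            out.append(
                f"{sid}\t{k}\t" + "\t".join(fmt % v for v in p) + f"\t{fmt % r}\t{s.start_node}\t{s.end_node}"
            )
    out.append("")
    path.write_text("\n".join(out))


def _read_native(path: Path) -> SpatialGraph:
    meta: dict = {"source": str(path), "dialect": "native_tabular"}
    table = None
    nodes: list[Node] = []
    seg_rows: dict[int, list[tuple[int, float, float, float, float, int, int]]] = {}
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(NATIVE_HEADER):
            raise SpatialGraphParseError(f"{path}: missing native header")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("meta "):
                    meta.update(json.loads(body[5:]))
                elif body == "[nodes]":
                    table = "nodes"
                elif body == "[points]":
                    table = "points"
                continue
            toks = line.split("\t")
            if table == "nodes":
                if len(toks) != 4:
                    raise SpatialGraphParseError(f"{path}:{lineno}: nodes table expects 4 columns")
                nodes.append(Node(id=int(toks[0]), position=[float(t) for t in toks[1:4]]))
            elif table == "points":
                if len(toks) != 8:
                    raise SpatialGraphParseError(f"{path}:{lineno}: points table expects 8 columns")
                sid = int(toks[0])
                seg_rows.setdefault(sid, []).append(
                    (int(toks[1]), float(toks[2]), float(toks[3]), float(toks[4]), float(toks[5]),
                     int(toks[6]), int(toks[7]))
                )
            else:
                raise SpatialGraphParseError(f"{path}:{lineno}: data before any table header")
    segments = []
    for sid, rows in seg_rows.items():
        rows.sort(key=lambda r: r[0])
        if [r[0] for r in rows] != list(range(len(rows))):
            raise SpatialGraphParseError(f"{path}: segment {sid} has non-contiguous point ordinals")
        pts = np.array([[r[1], r[2], r[3]] for r in rows])
        rad = np.array([r[4] for r in rows])
        segments.append(Segment(id=sid, start_node=rows[0][5], end_node=rows[0][6], points=pts, radii=rad))
    return SpatialGraph.build(nodes, segments, meta=meta)


# ---------------------------------------------------------------------------
# Voxel volumes (multi-page TIFF)
# ---------------------------------------------------------------------------


def write_volume(vol: VoxelVolume, path: str | Path) -> None:
    desc = json.dumps({"voxel_size_um": vol.voxel_size, "origin_um": list(vol.origin)})
    tifffile.imwrite(str(path), vol.data, description=desc)


def read_volume(path: str | Path, voxel_size: float | None = None) -> VoxelVolume:
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    origin = np.zeros(3)
    if voxel_size is None:
        try:
            info = json.loads(desc)
            voxel_size = float(info["voxel_size_um"])
            origin = np.asarray(info.get("origin_um", [0, 0, 0]), dtype=float)
        except (ValueError, KeyError):
            raise ValueError(f"{path}: no voxel size metadata; pass voxel_size explicitly")
    if data.ndim == 2:
        data = data[None]
    return VoxelVolume(data=data, voxel_size=voxel_size, origin=origin)
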