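"""Spatial-graph data model for vessel centreline networks.

A vascular network is stored as an undirected *spatial graph*: nodes are
branching points or terminal ends, segments are the vessels running between
two nodes, and each segment carries an ordered polyline of centreline points
with a local radius at every point.  The interval between two consecutive
points is a *sub-segment*; all per-segment geometry (length, volume,
tortuosity) is accumulated over sub-segments.

Coordinates are world coordinates in micrometres.  Direction (parent/child)
is never stored; it is derived from a chosen root at analysis time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "ENDPOINT_TOL_UM",
    "Node",
    "Segment",
    "SpatialGraph",
    "VoxelVolume",
    "GraphDefect",
    "ValidationReport",
    "validate_graph",
    "find_root",
]

#: Default tolerance (μm) for segment endpoints coinciding with node positions.
ENDPOINT_TOL_UM = 1e-6


@dataclass(frozen=True)
class Node:
    """A junction or terminal end of the vessel network."""

    id: int
    position: np.ndarray  # (3,) world μm

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (3,):
            raise ValueError(f"node {self.id}: position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"node {self.id}: non-finite position")


@dataclass
class Segment:
    """A vessel between two nodes, as a radius-bearing centreline polyline.

    ``points`` is an (n, 3) array of world coordinates (n >= 2) whose first and
    last rows coincide with the start/end node positions; ``radii`` is the (n,)
    array of local radii in μm.  Sub-segment ``i`` is the interval between
    points ``i`` and ``i + 1``.
    """

    id: int
    start_node: int
    end_node: int
    points: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError(f"segment {self.id}: points must be (n, 3)")
        if len(self.points) < 2:
            raise ValueError(f"segment {self.id}: needs at least 2 points")
        if self.radii.shape != (len(self.points),):
            raise ValueError(f"segment {self.id}: radii/points length mismatch")

    @property
    def n_subsegments(self) -> int:
        return len(self.points) - 1

    def subsegment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    def subsegment_radii(self) -> np.ndarray:
        """Radius of each sub-segment: mean of its two endpoint radii."""
        return 0.5 * (self.radii[:-1] + self.radii[1:])

    def path_length(self) -> float:
        return float(self.subsegment_lengths().sum())

    def chord_length(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    def mean_radius(self) -> float:
        return float(self.subsegment_radii().mean())

    def reversed(self) -> "Segment":
        return Segment(
            id=self.id,
            start_node=self.end_node,
            end_node=self.start_node,
            points=self.points[::-1].copy(),
            radii=self.radii[::-1].copy(),
        )


@dataclass
class SpatialGraph:
    """Undirected vessel network: nodes, segments and metadata.

    ``meta`` carries provenance free-text plus optional ``voxel_size`` (μm)
    and ``origin`` entries describing the raster frame the graph came from.
    """

    nodes: dict[int, Node]
    segments: dict[int, Segment]
    meta: dict = field(default_factory=dict)

    @classmethod
    def build(
        cls,
        nodes: Iterable[Node],
        segments: Iterable[Segment],
        meta: Mapping | None = None,
    ) -> "SpatialGraph":
        node_map: dict[int, Node] = {}
        for n in nodes:
            if n.id in node_map:
                raise ValueError(f"duplicate node id {n.id}")
            node_map[n.id] = n
        seg_map: dict[int, Segment] = {}
        for s in segments:
            if s.id in seg_map:
                raise ValueError(f"duplicate segment id {s.id}")
            seg_map[s.id] = s
        return cls(nodes=node_map, segments=seg_map, meta=dict(meta or {}))

    # -- basic accessors -------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_points(self) -> int:
        return sum(len(s.points) for s in self.segments.values())

    def incident_segments(self, node_id: int) -> list[int]:
        return [
            s.id
            for s in self.segments.values()
            if node_id in (s.start_node, s.end_node)
        ]

    def degree(self, node_id: int) -> int:
        d = 0
        for s in self.segments.values():
            d += (s.start_node == node_id) + (s.end_node == node_id)
        return d

    def terminal_nodes(self) -> list[int]:
        deg: dict[int, int] = {nid: 0 for nid in self.nodes}
        for s in self.segments.values():
            deg[s.start_node] += 1
            deg[s.end_node] += 1
        return sorted(nid for nid, d in deg.items() if d == 1)

    def to_networkx(self) -> nx.MultiGraph:
        """Node/segment topology as a MultiGraph (edge key = segment id)."""
        g = nx.MultiGraph()
        g.add_nodes_from(self.nodes)
        for s in self.segments.values():
            g.add_edge(s.start_node, s.end_node, key=s.id)
        return g

    def n_components(self) -> int:
        if not self.nodes:
            return 0
        return nx.number_connected_components(self.to_networkx())

    def n_cycles(self) -> int:
        """Number of independent cycles: E - V + components."""
        if not self.nodes:
            return 0
        return self.n_segments - self.n_nodes + self.n_components()

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        pts = np.vstack([s.points for s in self.segments.values()]) if self.segments else np.vstack(
            [n.position for n in self.nodes.values()]
        )
        return pts.min(axis=0), pts.max(axis=0)

    def total_length(self) -> float:
        return float(sum(s.path_length() for s in self.segments.values()))

    def total_volume(self) -> float:
        """Total cylinder volume over all sub-segments, μm³."""
        return float(
            sum(
                (np.pi * s.subsegment_radii() ** 2 * s.subsegment_lengths()).sum()
                for s in self.segments.values()
            )
        )

    def copy(self) -> "SpatialGraph":
        return SpatialGraph(
            nodes=dict(self.nodes),
            segments={
                sid: replace(s, points=s.points.copy(), radii=s.radii.copy())
                for sid, s in self.segments.items()
            },
            meta=dict(self.meta),
        )


@dataclass
class VoxelVolume:
    """Isotropic 3D raster with world placement.

    ``data`` is indexed (z, y, x), 0-based; the world position of voxel
    ``(k, j, i)`` is ``origin + voxel_size * (i, j, k)`` (x, y, z order).
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("volume data must be a non-empty 3D array")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector (x, y, z)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """World μm -> fractional (z, y, x) index."""
        xyz = np.atleast_2d(np.asarray(xyz, dtype=float))
        ijk = (xyz - self.origin) / self.voxel_size  # (x, y, z) index order
        return ijk[:, ::-1]

    def index_to_world(self, zyx: np.ndarray) -> np.ndarray:
        zyx = np.atleast_2d(np.asarray(zyx, dtype=float))
        return zyx[:, ::-1] * self.voxel_size + self.origin


@dataclass(frozen=True)
class GraphDefect:
    kind: str
    detail: str
    node_id: int | None = None
    segment_id: int | None = None


@dataclass
class ValidationReport:
    defects: list[GraphDefect]
    n_components: int
    n_cycles: int

    @property
    def ok(self) -> bool:
        return not self.defects


def validate_graph(g: SpatialGraph, endpoint_tol: float = ENDPOINT_TOL_UM) -> ValidationReport:
    """Structural audit of a spatial graph.

    Reports orphan nodes (no incident segment), non-positive radii, segment
    endpoints that do not coincide with their node positions within
    ``endpoint_tol`` μm, dangling node references, duplicate centreline
    points, plus the component and independent-cycle counts.
    """
    defects: list[GraphDefect] = []
    incident: dict[int, int] = {nid: 0 for nid in g.nodes}
    for s in g.segments.values():
        for end, nid in (("start", s.start_node), ("end", s.end_node)):
            if nid not in g.nodes:
                defects.append(
                    GraphDefect("dangling reference", f"{end} node {nid} missing", segment_id=s.id)
                )
            else:
                incident[nid] += 1
                anchor = s.points[0] if end == "start" else s.points[-1]
                gap = float(np.linalg.norm(anchor - g.nodes[nid].position))
                if gap > endpoint_tol:
                    defects.append(
                        GraphDefect(
                            "endpoint mismatch",
                            f"{end} point is {gap:.3g} μm from node {nid}",
                            node_id=nid,
                            segment_id=s.id,
                        )
                    )
        if np.any(s.radii <= 0):
            defects.append(
                GraphDefect("non-positive radius", f"{int((s.radii <= 0).sum())} point(s)", segment_id=s.id)
            )
        steps = s.subsegment_lengths()
        if np.any(steps == 0):
            defects.append(
                GraphDefect("duplicate points", f"{int((steps == 0).sum())} zero-length sub-segment(s)", segment_id=s.id)
            )
    for nid, cnt in incident.items():
        if cnt == 0:
            defects.append(GraphDefect("orphan node", "no incident segment", node_id=nid))
    seen: dict[tuple, int] = {}
    for s in g.segments.values():
        key = tuple(sorted((s.start_node, s.end_node))) + (len(s.points),)
        if key in seen and np.allclose(
            g.segments[seen[key]].points, s.points
        ):
            defects.append(GraphDefect("duplicate segment", f"same geometry as segment {seen[key]}", segment_id=s.id))
        else:
            seen.setdefault(key, s.id)
    return ValidationReport(defects=defects, n_components=g.n_components(), n_cycles=g.n_cycles())


def find_root(
    g: SpatialGraph,
    strategy: str = "max_radius_terminal",
    node_id: int | None = None,
) -> int:
    """Choose the root node (the cut feeding-artery stub of the organ).

    ``max_radius_terminal`` picks the degree-1 node whose incident segment has
    the largest mean radius; ties break to the lowest node id.  ``explicit``
    returns ``node_id`` after checking it exists.
    """
    if strategy == "explicit":
        if node_id is None or node_id not in g.nodes:
            raise ValueError(f"explicit root {node_id!r} not in graph")
        return node_id
    if strategy != "max_radius_terminal":
        raise ValueError(f"unknown root strategy {strategy!r}")
    terminals = g.terminal_nodes()
    if not terminals:
        raise ValueError("graph has no terminal (degree-1) nodes; cannot pick a root")
    seg_by_node: dict[int, float] = {}
    for s in g.segments.values():
        r = s.mean_radius()
        for nid in (s.start_node, s.end_node):
            seg_by_node[nid] = max(seg_by_node.get(nid, -np.inf), r)
    # max radius first, then lowest id
    return min(terminals, key=lambda nid: (-seg_by_node[nid], nid))
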