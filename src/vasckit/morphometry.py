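"""Per-segment geometric metrics and network-level distance summaries.

Definitions (all lengths in μm):

* length — sum of sub-segment lengths along the centreline polyline.
* radius — mean of sub-segment radii, each the mean of its endpoint radii.
* tortuosity — path length / chord length (>= 1; a flag gives the inverse,
  chord/path, for compatibility with sources that define it that way).
* length_radius_ratio — length / radius (a diameter-based variant exists).
* volume — sum of per-sub-segment cylinders, pi * r^2 * l.
* midpoint inter-vessel distance — Euclidean distance from each segment's
  half-path-length point to the nearest other segment's midpoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .graph import SpatialGraph, VoxelVolume
from .ordering import OrderingResult, root_segment_tree
from .volume import distance_transform

__all__ = [
    "segment_metrics",
    "segment_midpoints",
    "branching_angles",
    "intervessel_midpoint_distance",
    "intervessel_voxel_distance",
    "cumulative_volume_by_order",
    "grouped_summary",
    "ZeroChordError",
]


class ZeroChordError(ValueError):
    """A segment's endpoints coincide; tortuosity is undefined."""


def _midpoint(points: np.ndarray) -> np.ndarray:
    """Point at half the cumulative path length (interpolated)."""
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half, side="right") - 1)
    i = min(i, len(steps) - 1)
    t = 0.0 if steps[i] == 0 else (half - cum[i]) / steps[i]
    return points[i] + t * (points[i + 1] - points[i])


def segment_midpoints(g: SpatialGraph) -> pd.DataFrame:
    rows = {sid: _midpoint(s.points) for sid, s in g.segments.items()}
    return pd.DataFrame.from_dict(rows, orient="index", columns=["x", "y", "z"]).sort_index()


def segment_metrics(g: SpatialGraph, literal_tortuosity: bool = False) -> pd.DataFrame:
    """Per-segment metric table indexed by segment id.

    Columns: length, radius, tortuosity, length_radius_ratio, volume,
    chord, mid_x/mid_y/mid_z.  ``literal_tortuosity`` reports chord/path
    (<= 1) instead of the default path/chord.
    """
    rows = []
    for sid in sorted(g.segments):
        s = g.segments[sid]
        lengths = s.subsegment_lengths()
        radii = s.subsegment_radii()
        length = float(lengths.sum())
        chord = s.chord_length()
        if chord == 0:
            raise ZeroChordError(f"segment {sid}: start and end nodes coincide")
        tort = chord / length if literal_tortuosity else length / chord
        radius = float(radii.mean())
        mid = _midpoint(s.points)
        rows.append(
            dict(segment_id=sid, length=length, radius=radius, tortuosity=tort,
                 length_radius_ratio=length / radius,
                 volume=float((np.pi * radii**2 * lengths).sum()),
                 chord=chord, mid_x=mid[0], mid_y=mid[1], mid_z=mid[2])
        )
    return pd.DataFrame(rows).set_index("segment_id")


def branching_angles(g: SpatialGraph, root: int) -> pd.DataFrame:
    """Chord-vector angles at every junction of the rooted tree.

    Each incident segment is represented by its chord pointing *away* from
    the junction (tortuosity ignored).  ``child_parent`` is the angle between
    a child's away-vector and the parent's away-vector, so a straight
    continuation scores 180 deg; ``child_child`` is reported for every
    unordered child pair (all pairs at junctions with > 2 children).
    Returns a table with columns node_id, kind ('child_parent' |
    'child_child'), segment_a, segment_b, angle_deg.
    """
    tree = root_segment_tree(g, root)
    rows = []

    def away_vector(sid: int, junction: int) -> np.ndarray:
        s = g.segments[sid]
        if s.start_node == junction:
            v = s.points[-1] - s.points[0]
        else:
            v = s.points[0] - s.points[-1]
        n = np.linalg.norm(v)
        if n == 0:
            raise ZeroChordError(f"segment {sid}: zero-length chord at junction {junction}")
        return v / n

    def angle(u: np.ndarray, v: np.ndarray) -> float:
        return float(np.degrees(np.arccos(np.clip(np.dot(u, v), -1.0, 1.0))))

    for parent_sid, kids in tree.children.items():
        if not kids:
            continue
        junction = tree.distal[parent_sid]
        vp = away_vector(parent_sid, junction)
        vecs = {k: away_vector(k, junction) for k in kids}
        for k in kids:
            rows.append(dict(node_id=junction, kind="child_parent", segment_a=k,
                             segment_b=parent_sid, angle_deg=angle(vecs[k], vp)))
        for i, a in enumerate(kids):
            for b in kids[i + 1:]:
                rows.append(dict(node_id=junction, kind="child_child", segment_a=a,
                                 segment_b=b, angle_deg=angle(vecs[a], vecs[b])))
    return pd.DataFrame(rows, columns=["node_id", "kind", "segment_a", "segment_b", "angle_deg"])


def intervessel_midpoint_distance(g: SpatialGraph, exclude_neighbours: bool = False) -> pd.Series:
    """Nearest-neighbour distance between segment midpoints, per segment.

    By default only the segment itself is excluded from its own search;
    ``exclude_neighbours`` additionally ignores segments sharing a node.
    """
    if g.n_segments < 2:
        raise ValueError("midpoint inter-vessel distance needs >= 2 segments")
    mids = segment_midpoints(g)
    ids = mids.index.to_numpy()
    pts = mids.to_numpy()
    if not exclude_neighbours:
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        return pd.Series(d[:, 1], index=ids, name="midpoint_ivd")
    adjacent: dict[int, set[int]] = {sid: set() for sid in ids}
    by_node: dict[int, list[int]] = {}
    for s in g.segments.values():
        for nid in (s.start_node, s.end_node):
            by_node.setdefault(nid, []).append(s.id)
    for sids in by_node.values():
        for a in sids:
            for b in sids:
                if a != b:
                    adjacent[a].add(b)
    pos = {sid: i for i, sid in enumerate(ids)}
    out = np.full(len(ids), np.inf)
    diff = pts[:, None, :] - pts[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    for i, sid in enumerate(ids):
        banned = [i] + [pos[b] for b in adjacent[sid]]
        row = dist[i].copy()
        row[banned] = np.inf
        out[i] = row.min()
    return pd.Series(out, index=ids, name="midpoint_ivd")


def intervessel_voxel_distance(
    mask: VoxelVolume, zone_labels: VoxelVolume | None = None
) -> tuple[VoxelVolume, pd.DataFrame | None]:
    """Distance of every non-vessel voxel to the nearest vessel voxel.

    Returns the distance field (μm) and, when a zone-label volume is given,
    a per-zone summary (mean, SD, max of the distances over that zone's
    voxels, vessel voxels included at distance 0).
    """
    field = distance_transform(mask)
    summary = None
    if zone_labels is not None:
        if zone_labels.data.shape != mask.data.shape:
            raise ValueError("zone label grid does not match the mask grid")
        rows = []
        for lab in np.unique(zone_labels.data):
            if lab == 0:
                continue
            vals = field.data[zone_labels.data == lab]
            rows.append(dict(zone=int(lab), n_voxels=int(vals.size),
                             mean=float(vals.mean()), sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                             max=float(vals.max())))
        summary = pd.DataFrame(rows).set_index("zone")
    return field, summary


def cumulative_volume_by_order(metrics: pd.DataFrame, ordering: OrderingResult) -> pd.Series:
    """Cumulative vascular volume fraction by ascending Strahler order."""
    missing = set(metrics.index) - set(ordering.strahler)
    if missing:
        raise ValueError(f"{len(missing)} segment(s) have no Strahler order")
    orders = pd.Series(ordering.strahler).reindex(metrics.index)
    per_order = metrics["volume"].groupby(orders).sum().sort_index()
    return per_order.cumsum() / per_order.sum()


def grouped_summary(
    metrics: pd.DataFrame,
    ordering: OrderingResult,
    angles: pd.DataFrame | None = None,
    ivd: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-Strahler-order mean ± SD summary of the branching metrics.

    One row per order with n and mean/SD pairs for radius, length,
    tortuosity, length:radius ratio and volume; child-parent branching
    angles (attributed to the child segment) and midpoint inter-vessel
    distances are appended when given.  SD is reported as 0 for n = 1.
    """
    df = metrics.copy()
    df["order"] = pd.Series(ordering.strahler).reindex(df.index)
    if df["order"].isna().any():
        raise ValueError("metrics table contains segments without an order")
    if angles is not None and len(angles):
        cp = angles[angles["kind"] == "child_parent"].set_index("segment_a")["angle_deg"]
        df["branching_angle"] = cp.reindex(df.index)
    if ivd is not None:
        df["midpoint_ivd"] = ivd.reindex(df.index)
    cols = [c for c in ["radius", "length", "tortuosity", "length_radius_ratio",
                        "volume", "branching_angle", "midpoint_ivd"] if c in df]
    grouped = df.groupby("order")
    out = pd.DataFrame({"n": grouped.size()})
    for c in cols:
        out[f"{c}_mean"] = grouped[c].mean()
        out[f"{c}_sd"] = grouped[c].std(ddof=1).fillna(0.0)
    return out.sort_index()
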