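import numpy as np
import pytest

from vasckit.graph import Node, Segment, SpatialGraph
from vasckit.synthetic import TreeSpec, generate_tree


@pytest.fixture
def binary_tree4() -> SpatialGraph:
    """Perfect binary tree with 4 Strahler orders, straight segments."""
    return generate_tree(TreeSpec(depth=4, branching_ratio=2.0, tortuosity_amp=0.0, seed=7))


@pytest.fixture
def medium_tree() -> SpatialGraph:
    """Organ-like tree at reduced depth (6 orders, branching ratio 2.9)."""
    return generate_tree(TreeSpec(depth=6, seed=11))


def straight_segment(sid=0, start=(0.0, 0.0, 0.0), end=(100.0, 0.0, 0.0), radius=10.0,
                     n_points=2, start_node=0, end_node=1) -> Segment:
    start = np.asarray(start, dtype=float)
    end = np.asarray(end, dtype=float)
    t = np.linspace(0.0, 1.0, n_points)
    pts = start[None, :] + t[:, None] * (end - start)[None, :]
    return Segment(id=sid, start_node=start_node, end_node=end_node,
                   points=pts, radii=np.full(n_points, float(radius)))


def graph_from_segments(segments) -> SpatialGraph:
    """Build a SpatialGraph deriving nodes from segment endpoints."""
    nodes = {}
    for s in segments:
        nodes.setdefault(s.start_node, Node(id=s.start_node, position=s.points[0]))
        nodes.setdefault(s.end_node, Node(id=s.end_node, position=s.points[-1]))
    return SpatialGraph.build(nodes.values(), segments)


@pytest.fixture
def y_tree() -> SpatialGraph:
    """Parent (radius 10) splitting into two thinner children (radius 5)."""
    parent = straight_segment(0, (0, 0, 0), (0, 0, 100), radius=10.0,
                              start_node=0, end_node=1)
    c1 = straight_segment(1, (0, 0, 100), (50, 0, 180), radius=5.0,
                          start_node=1, end_node=2)
    c2 = straight_segment(2, (0, 0, 100), (-50, 0, 180), radius=5.0,
                          start_node=1, end_node=3)
    return graph_from_segments([parent, c1, c2])
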