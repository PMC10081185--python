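"""Strahler (centripetal) and topological-generation (centrifugal) ordering.

Both schemes are defined on the tree obtained by rooting the undirected
spatial graph at a chosen node (the feeding-artery stub).  Terminal segments
carry Strahler order 1; where two children of equal order meet, the parent's
order is one greater, otherwise the larger child order propagates.  At
junctions with more than two children the standard generalization applies:
the parent order is max+1 when at least two children attain the max.
Generations count branching nodes outward from the root: the root-adjacent
segment is generation 1 and each junction with >= 2 children increments the
label.  Degree-2 passthrough nodes affect neither scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import SpatialGraph

__all__ = ["OrderingResult", "CycleError", "root_segment_tree", "strahler_order",
           "topological_generation", "compute_ordering", "order_counts"]


class CycleError(ValueError):
    """The component reachable from the root contains a cycle."""


@dataclass
class OrderingResult:
    """Per-segment Strahler order and topological generation for one root."""

    root: int
    strahler: dict[int, int] = field(default_factory=dict)
    generation: dict[int, int] = field(default_factory=dict)

    def max_strahler(self) -> int:
        return max(self.strahler.values(), default=0)

    def max_generation(self) -> int:
        return max(self.generation.values(), default=0)


@dataclass
class RootedTree:
    """Segment-level rooted view of the component containing ``root``."""

    root: int
    # per segment id: node nearer the root / node farther from the root
    proximal: dict[int, int]
    distal: dict[int, int]
    # per segment id: ids of segments hanging off its distal node
    children: dict[int, list[int]]
    # segments incident to the root node, in id order
    root_segments: list[int]


def root_segment_tree(g: SpatialGraph, root: int) -> RootedTree:
    """Orient the root's component away from ``root``; reject cycles."""
    if root not in g.nodes:
        raise ValueError(f"root node {root} not in graph")
    adj: dict[int, list[tuple[int, int]]] = {nid: [] for nid in g.nodes}
    for s in g.segments.values():
        adj[s.start_node].append((s.id, s.end_node))
        adj[s.end_node].append((s.id, s.start_node))
        if s.start_node == s.end_node:
            raise CycleError(f"segment {s.id} is a self-loop")

    proximal: dict[int, int] = {}
    distal: dict[int, int] = {}
    children: dict[int, list[int]] = {}
    visited_nodes = {root}
    root_segments = sorted(sid for sid, _ in adj[root])
    for sid, nbr in sorted(adj[root]):
        proximal[sid] = root
        distal[sid] = nbr
    stack: list[tuple[int, int]] = [(nbr, sid) for sid, nbr in sorted(adj[root])]
    while stack:
        node, via = stack.pop()
        if node in visited_nodes:
            raise CycleError(f"cycle reachable from root {root} at node {node}")
        visited_nodes.add(node)
        kids = []
        for sid, nbr in sorted(adj[node]):
            if sid == via:
                continue
            if sid in proximal:
                raise CycleError(f"cycle reachable from root {root} at segment {sid}")
            proximal[sid] = node
            distal[sid] = nbr
            kids.append(sid)
            stack.append((nbr, sid))
        children[via] = kids
    return RootedTree(root=root, proximal=proximal, distal=distal,
                      children=children, root_segments=root_segments)


def _strahler_from_tree(tree: RootedTree) -> dict[int, int]:
    order: dict[int, int] = {}
    # iterative post-order over segments
    stack: list[tuple[int, bool]] = [(sid, False) for sid in reversed(tree.root_segments)]
    while stack:
        sid, expanded = stack.pop()
        kids = tree.children.get(sid, [])
        if not expanded and kids:
            stack.append((sid, True))
            stack.extend((k, False) for k in kids)
            continue
        if not kids:
            order[sid] = 1
        else:
            vals = [order[k] for k in kids]
            top = max(vals)
            order[sid] = top + 1 if vals.count(top) >= 2 else top
    return order


def _generation_from_tree(tree: RootedTree) -> dict[int, int]:
    gen: dict[int, int] = {}
    stack = [(sid, 1) for sid in tree.root_segments]
    while stack:
        sid, g_val = stack.pop()
        gen[sid] = g_val
        kids = tree.children.get(sid, [])
        nxt = g_val + 1 if len(kids) >= 2 else g_val
        stack.extend((k, nxt) for k in kids)
    return gen


def compute_ordering(g: SpatialGraph, root: int) -> OrderingResult:
    """Both orderings for the component containing ``root``."""
    tree = root_segment_tree(g, root)
    return OrderingResult(root=root, strahler=_strahler_from_tree(tree),
                          generation=_generation_from_tree(tree))


def strahler_order(g: SpatialGraph, root: int) -> OrderingResult:
    tree = root_segment_tree(g, root)
    return OrderingResult(root=root, strahler=_strahler_from_tree(tree))


def topological_generation(g: SpatialGraph, root: int) -> OrderingResult:
    tree = root_segment_tree(g, root)
    return OrderingResult(root=root, generation=_generation_from_tree(tree))


def order_counts(ordering: OrderingResult) -> dict[int, int]:
    """Histogram of Strahler orders: {order: segment count}."""
    orders = np.array(list(ordering.strahler.values()), dtype=int)
    if orders.size == 0:
        return {}
    uniq, cnt = np.unique(orders, return_counts=True)
    return {int(o): int(c) for o, c in zip(uniq, cnt)}
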