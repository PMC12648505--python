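"""Skeletonization and conversion of the vessel mask into a network graph.

The skeleton is a one-voxel-thick, 26-connected, topology-preserving medial
axis (parallel thinning). Graph conversion finds node voxels (endpoints and
junctions), traces maximal degree-2 chains into edges with explicit voxel
paths, then iterates a simplification pass — prune short terminal spurs,
contract short interior edges, splice degree-2 nodes — until the
(node count, edge count) pair converges.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .types import Edge, NetworkGraph, Node, SegmentationMask

__all__ = [
    "SkeletonVoxels",
    "skeletonize",
    "skeleton_to_graph",
    "classify_edges",
    "apply_border_rules",
]

_OFFSETS = np.array(
    [o for o in product((-1, 0, 1), repeat=3) if o != (0, 0, 0)], dtype=np.int64
)


@dataclass
class SkeletonVoxels:
    """One-voxel-thick skeleton as a coordinate set."""

    coordinates: np.ndarray  # (n, 3) voxel indices (z, y, x)
    spacing_um: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.int64).reshape(-1, 3)

    def to_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, dtype=bool)
        if len(self.coordinates):
            m[tuple(self.coordinates.T)] = True
        return m


def skeletonize(mask: SegmentationMask) -> SkeletonVoxels:
    """Medial-axis thinning of a binary mask (Lee et al. parallel thinning).

    Guards against a thinning-order artifact where an object lying exactly in
    a diagonal voxel plane is eroded away entirely: if the skeleton comes back
    empty for a non-empty mask, the thinning is retried on a transposed grid.
    """
    skel = _sk_skeletonize(mask.data)
    if not skel.any() and mask.data.any():
        skel = _sk_skeletonize(
            np.ascontiguousarray(mask.data.transpose(1, 0, 2))
        ).transpose(1, 0, 2)
    coords = np.argwhere(skel)
    return SkeletonVoxels(coords, mask.spacing_um, mask.shape)


def _polyline_length_um(path_vox: np.ndarray, spacing: np.ndarray) -> float:
    if len(path_vox) < 2:
        return 0.0
    steps = np.diff(path_vox.astype(np.float64), axis=0) * spacing
    return float(np.sqrt((steps**2).sum(axis=1)).sum())


def _neighbor_map(coords: np.ndarray) -> tuple[dict, list[list[int]]]:
    """26-adjacency among skeleton voxels; returns voxel->index and neighbor lists."""
    index = {tuple(c): i for i, c in enumerate(coords)}
    nbrs: list[list[int]] = [[] for _ in range(len(coords))]
    for i, c in enumerate(coords):
        for off in _OFFSETS:
            j = index.get((c[0] + off[0], c[1] + off[1], c[2] + off[2]))
            if j is not None:
                nbrs[i].append(j)
    return index, nbrs


def _extract_graph(skel: SkeletonVoxels) -> NetworkGraph:
    """Initial skeleton-to-graph conversion (no simplification).

    Junction voxels (>=3 neighbours) that touch each other are clustered into
    a single node; endpoints and isolated voxels are nodes of their own.
    Pure cycles without any node voxel get one arbitrary (raster-first)
    anchor node carrying a self-loop.
    """
    coords = skel.coordinates
    spacing = np.asarray(skel.spacing_um)
    g = NetworkGraph(spacing_um=skel.spacing_um)
    n = len(coords)
    if n == 0:
        return g
    _, nbrs = _neighbor_map(coords)
    degree = np.array([len(v) for v in nbrs])

    node_of_voxel = np.full(n, -1, dtype=np.int64)
    next_node = 0

    # endpoints / isolated voxels
    for i in np.flatnonzero(degree != 2):
        if degree[i] >= 3:
            continue
        node_of_voxel[i] = next_node
        g.nodes[next_node] = Node(next_node, tuple(coords[i] * spacing))
        next_node += 1

    # junction clusters: connected sets of >=3-neighbour voxels become one node
    junction = np.flatnonzero(degree >= 3)
    seen = set()
    for start in junction:
        if start in seen:
            continue
        stack = [start]
        cluster = []
        seen.add(start)
        while stack:
            v = stack.pop()
            cluster.append(v)
            for w in nbrs[v]:
                if degree[w] >= 3 and w not in seen:
                    seen.add(w)
                    stack.append(w)
        for v in cluster:
            node_of_voxel[v] = next_node
        centroid = coords[cluster].mean(axis=0) * spacing
        g.nodes[next_node] = Node(next_node, tuple(centroid))
        next_node += 1

    next_edge = 0
    visited_chain = np.zeros(n, dtype=bool)  # degree-2 voxels consumed by a trace
    done_direct: set[tuple[int, int]] = set()

    def add_edge(u: int, v: int, path_idx: list[int]) -> None:
        nonlocal next_edge
        path = coords[path_idx]
        g.edges[next_edge] = Edge(
            next_edge, u, v, path, _polyline_length_um(path, spacing)
        )
        next_edge += 1

    node_voxels = np.flatnonzero(node_of_voxel >= 0)
    for i in node_voxels:
        for j in nbrs[i]:
            if node_of_voxel[j] >= 0:
                if node_of_voxel[j] == node_of_voxel[i]:
                    continue  # intra-cluster adjacency
                key = (min(i, j), max(i, j))
                if key in done_direct:
                    continue
                done_direct.add(key)
                add_edge(node_of_voxel[i], node_of_voxel[j], [i, j])
                continue
            if visited_chain[j]:
                continue
            # walk the degree-2 chain
            path = [i, j]
            visited_chain[j] = True
            prev, cur = i, j
            while node_of_voxel[cur] < 0:
                nxt = [w for w in nbrs[cur] if w != prev]
                if not nxt:
                    # dead-end voxel (degree 2 only via staircase adjacency):
                    # promote it to an endpoint node so the chain is kept
                    node_of_voxel[cur] = next_node
                    g.nodes[next_node] = Node(next_node, tuple(coords[cur] * spacing))
                    next_node += 1
                    break
                prev, cur = cur, nxt[0]
                path.append(cur)
                if node_of_voxel[cur] < 0:
                    visited_chain[cur] = True
            add_edge(node_of_voxel[i], node_of_voxel[cur], path)

    # pure cycles: remaining unvisited degree-2 voxels with no node anywhere
    for i in range(n):
        if degree[i] == 2 and not visited_chain[i] and node_of_voxel[i] < 0:
            anchor = next_node
            node_of_voxel[i] = anchor
            g.nodes[anchor] = Node(anchor, tuple(coords[i] * spacing))
            next_node += 1
            path = [i]
            prev, cur = i, nbrs[i][0]
            while cur != i:
                visited_chain[cur] = True
                path.append(cur)
                nxt = [w for w in nbrs[cur] if w != prev]
                prev, cur = cur, nxt[0]
            path.append(i)
            add_edge(anchor, anchor, path)
    return g


def _simplify_pass(g: NetworkGraph, min_len_um: float) -> NetworkGraph:
    """One pruning/contraction/splicing sweep; returns a new graph."""
    g = g.copy()
    spacing = np.asarray(g.spacing_um)

    incident: dict[int, list[int]] = {nid: [] for nid in g.nodes}
    for e in g.edges.values():
        incident[e.u].append(e.id)
        if e.v != e.u:
            incident[e.v].append(e.id)

    def deg(nid: int) -> int:
        d = 0
        for eid in incident[nid]:
            e = g.edges[eid]
            d += (e.u == nid) + (e.v == nid)
        return d

    # 1) prune short terminal spurs
    for eid in sorted(g.edges):
        e = g.edges.get(eid)
        if e is None or e.length_um >= min_len_um or e.u == e.v:
            continue
        du, dv = deg(e.u), deg(e.v)
        if du == 1 or dv == 1:
            del g.edges[eid]
            incident[e.u].remove(eid)
            incident[e.v].remove(eid)
            for nid, d in ((e.u, du), (e.v, dv)):
                if d == 1:  # spur tip vanishes with its edge
                    del g.nodes[nid]
                    del incident[nid]

    # 2) contract short interior edges (merge endpoints; reattached edge paths
    #    are extended through the contracted edge to stay geometrically closed)
    for eid in sorted(g.edges):
        e = g.edges.get(eid)
        if e is None or e.length_um >= min_len_um or e.u == e.v:
            continue
        if e.u not in g.nodes or e.v not in g.nodes:
            continue
        u, v = e.u, e.v
        del g.edges[eid]
        incident[u].remove(eid)
        incident[v].remove(eid)
        path_v_to_u = e.path_vox[::-1]  # oriented v -> u
        for fid in list(incident[v]):
            f = g.edges[fid]
            if f.u == v:
                f.path_vox = np.vstack([path_v_to_u[::-1], f.path_vox[1:]])
                f.u = u
            if f.v == v:
                f.path_vox = np.vstack([f.path_vox[:-1], path_v_to_u])
                f.v = u
            f.length_um = _polyline_length_um(f.path_vox, spacing)
            incident[u].append(fid)
        pu = np.asarray(g.nodes[u].pos_um)
        pv = np.asarray(g.nodes[v].pos_um)
        g.nodes[u] = Node(u, tuple((pu + pv) / 2))
        del g.nodes[v]
        del incident[v]

    # 3) splice degree-2 nodes
    for nid in sorted(g.nodes):
        if nid not in g.nodes:
            continue
        eids = incident[nid]
        if len(eids) != 2 or deg(nid) != 2:
            continue
        e1, e2 = g.edges[eids[0]], g.edges[eids[1]]
        if e1.u == e1.v or e2.u == e2.v:
            continue
        # orient e1 to end at nid, e2 to start at nid
        p1 = e1.path_vox if e1.v == nid else e1.path_vox[::-1]
        u_new = e1.u if e1.v == nid else e1.v
        p2 = e2.path_vox if e2.u == nid else e2.path_vox[::-1]
        v_new = e2.v if e2.u == nid else e2.u
        if (p1[-1] == p2[0]).all():
            path = np.vstack([p1, p2[1:]])
        else:  # cluster node: bridge between the two attachment voxels
            path = np.vstack([p1, p2])
        e1.u, e1.v = u_new, v_new
        e1.path_vox = path
        e1.length_um = _polyline_length_um(path, spacing)
        del g.edges[e2.id]
        incident[u_new] = [i for i in incident[u_new] if i != e2.id]
        if e1.id not in incident[u_new]:
            incident[u_new].append(e1.id)
        incident[v_new] = [i for i in incident[v_new] if i != e2.id]
        if e1.id not in incident[v_new]:
            incident[v_new].append(e1.id)
        del g.nodes[nid]
        del incident[nid]
    return g


def skeleton_to_graph(
    skel: SkeletonVoxels, min_edge_length_um: float = 10.0, max_iter: int = 100
) -> NetworkGraph:
    """Convert a skeleton to a simplified network graph.

    The simplification pass is repeated until the (node, edge) count pair
    converges (with a hard guard of ``max_iter`` sweeps).
    """
    g = _extract_graph(skel)
    for _ in range(max_iter):
        before = (g.n_nodes, g.n_edges)
        g = _simplify_pass(g, min_edge_length_um)
        if (g.n_nodes, g.n_edges) == before:
            break
    return g


def classify_edges(graph: NetworkGraph) -> NetworkGraph:
    """Label terminal ("exiting") edges as capillary branches, interior ones
    as precollector links. Exhaustive and exclusive."""
    g = graph.copy()
    for e in g.iter_edges():
        if e.u == e.v:
            e.cls = "precollector_link"
        elif g.degree(e.u) == 1 or g.degree(e.v) == 1:
            e.cls = "capillary_branch"
        else:
            e.cls = "precollector_link"
    return g


def apply_border_rules(
    graph: NetworkGraph,
    shape: tuple[int, int, int],
    capillary_max_um: float = 25.0,
    precollector_min_um: float = 300.0,
) -> NetworkGraph:
    """Reclassify edges whose path touches an ROI face.

    Cropped elements shorter than ``capillary_max_um`` are discarded; longer
    than ``precollector_min_um`` they are kept as cropped precollectors
    (density only). Lengths in between get the dedicated ``border_ambiguous``
    class: excluded from per-class statistics, retained for density.
    """
    g = graph.copy()
    hi = np.asarray(shape) - 1
    for e in g.iter_edges():
        p = e.path_vox
        on_border = bool(((p == 0) | (p == hi)).any())
        if not on_border:
            continue
        if e.length_um < capillary_max_um:
            e.cls = "discarded"
        elif e.length_um > precollector_min_um:
            e.cls = "cropped_precollector"
        else:
            e.cls = "border_ambiguous"
    return g


def skeleton_component_and_cycle_count(skel: SkeletonVoxels) -> tuple[int, int]:
    """(connected components, independent cycles) of the skeleton's 26-adjacency.

    Cycle count is the first Betti number b1 = E - V + C of the voxel
    adjacency graph. Useful as a topology oracle in tests.
    """
    coords = skel.coordinates
    n = len(coords)
    if n == 0:
        return 0, 0
    mask = skel.to_mask()
    _, n_comp = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
    _, nbrs = _neighbor_map(coords)
    n_adj = sum(len(v) for v in nbrs) // 2
    return n_comp, n_adj - n + n_comp
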