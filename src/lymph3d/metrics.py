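"""Morphometrics: densities, capillary statistics, orientation, valve layout."""

from __future__ import annotations

import warnings

import numpy as np

from .types import MetricsReport, NetworkGraph, SegmentationMask, Valve, Volume3D

__all__ = [
    "network_density",
    "capillary_stats",
    "capillary_orientation",
    "multipoint_length",
    "valves_per_layer",
    "intervalve_distances",
    "intensity_by_valve_position",
    "compute_metrics",
]

#: Edge classes contributing to density measurements.
DENSITY_CLASSES = (
    "capillary_branch",
    "precollector_link",
    "cropped_precollector",
    "border_ambiguous",
)


def network_density(
    mask: SegmentationMask, graph: NetworkGraph, sample_volume_um3: float
) -> tuple[float, float]:
    """(volume density, length density) of the network.

    Volume density is the unitless foreground fraction; length density is
    retained edge length over sample volume, reported in mm/mm³
    (1 μm/μm³ = 10⁶ mm/mm³).
    """
    if sample_volume_um3 <= 0:
        raise ValueError("sample volume must be > 0")
    vol_density = mask.foreground_volume_um3() / sample_volume_um3
    length_um = graph.total_length_um(DENSITY_CLASSES)
    length_density = length_um / sample_volume_um3 * 1e6
    return float(vol_density), float(length_density)


def capillary_stats(graph: NetworkGraph) -> list[tuple[float, float, float]]:
    """Per-capillary (length_um, z_min_um, z_max_um); discarded and
    border-ambiguous edges are excluded."""
    rows = []
    for e in graph.iter_edges():
        if e.cls != "capillary_branch":
            continue
        z = graph.path_um(e)[:, 0]
        rows.append((float(e.length_um), float(z.min()), float(z.max())))
    return rows


def capillary_orientation(
    path_um: np.ndarray,
) -> tuple[float, float, float]:
    """(roll, pitch, yaw) in degrees of a path's principal axis.

    The axis is the dominant eigenvector of the second-central-moment matrix
    of the path's physical coordinates, sign-fixed so its z component is
    non-negative. Angles are read looking at the origin along x, y and z:
    roll = atan2(v_y, v_z), pitch = atan2(v_x, v_z), yaw = atan2(v_y, v_x);
    a component pair that is identically zero yields 0 by convention.
    """
    p = np.asarray(path_um, dtype=np.float64).reshape(-1, 3)
    if len(p) < 2:
        raise ValueError("need at least 2 points for an orientation")
    centered = p - p.mean(axis=0)
    cov = centered.T @ centered / len(p)
    w, vecs = np.linalg.eigh(cov)
    v = vecs[:, np.argmax(w)]  # (z, y, x) components
    vz, vy, vx = v
    if vz < 0 or (vz == 0 and (vy < 0 or (vy == 0 and vx < 0))):
        vz, vy, vx = -vz, -vy, -vx

    def ang(a: float, b: float) -> float:
        if abs(a) < 1e-12 and abs(b) < 1e-12:
            return 0.0
        return float(np.degrees(np.arctan2(a, b)))

    return ang(vy, vz), ang(vx, vz), ang(vy, vx)


def multipoint_length(
    points_vox: np.ndarray, spacing_um: tuple[float, float, float]
) -> tuple[float, float]:
    """(cumulative length, range) of an ordered point annotation.

    Length is the sum of Euclidean distances between consecutive points and
    range the distance between first and last point, both scaled by the voxel
    spacing. A single point yields (0, 0).
    """
    p = np.asarray(points_vox, dtype=np.float64).reshape(-1, 3)
    if len(p) == 0:
        raise ValueError("empty point list")
    s = np.asarray(spacing_um, dtype=np.float64)
    if len(p) == 1:
        return 0.0, 0.0
    steps = np.diff(p, axis=0) * s
    length = float(np.linalg.norm(steps, axis=1).sum())
    rng = float(np.linalg.norm((p[-1] - p[0]) * s))
    return length, rng


def valves_per_layer(
    valves: list[Valve], graph: NetworkGraph, sample_volume_um3: float
) -> dict[int, dict[str, float]]:
    """Per-layer valve counts, layer edge length, count per length (per mm of
    network) and count per sample mm³."""
    out: dict[int, dict[str, float]] = {}
    sample_mm3 = sample_volume_um3 * 1e-9
    for layer in (1, 2, 3):
        count = sum(1 for v in valves if v.layer == layer)
        length_um = sum(
            e.length_um
            for e in graph.iter_edges()
            if e.layer == layer and e.cls in DENSITY_CLASSES
        )
        length_mm = length_um * 1e-3
        out[layer] = {
            "count": float(count),
            "length_um": float(length_um),
            "count_per_mm": float(count / length_mm) if length_mm > 0 else 0.0,
            "count_per_mm3": float(count / sample_mm3) if sample_mm3 > 0 else 0.0,
        }
    return out


def _smooth_path(p: np.ndarray, window: int = 7) -> np.ndarray:
    """Moving-average smoothing of a polyline (endpoints pinned).

    A 26-connected digital path zig-zags around the true centerline and
    overestimates arc length by several percent; a short moving average
    recovers an almost unbiased length estimate.
    """
    if len(p) <= 2 or window <= 1:
        return p
    from scipy.ndimage import uniform_filter1d

    sm = uniform_filter1d(p.astype(np.float64), window, axis=0, mode="nearest")
    sm[0], sm[-1] = p[0], p[-1]
    return sm


def _arc_position(graph: NetworkGraph, edge_id: int, point_um: np.ndarray) -> float:
    """Arc-length (along the smoothed path) of the vertex nearest a point."""
    e = graph.edges[edge_id]
    p = graph.path_um(e)
    if len(p) < 2:
        return 0.0
    d = np.linalg.norm(p - point_um, axis=1)
    k = int(np.argmin(d))
    sm = _smooth_path(p)
    steps = np.linalg.norm(np.diff(sm, axis=0), axis=1)
    return float(np.concatenate([[0.0], np.cumsum(steps)])[k])


def intervalve_distances(valves: list[Valve], graph: NetworkGraph) -> list[float]:
    """Along-skeleton distances between consecutive valves sharing an edge.

    Valves are projected to their assigned edge's path and ordered by
    arc-length; edges with fewer than two valves contribute nothing.
    """
    by_edge: dict[int, list[float]] = {}
    for v in valves:
        if v.edge_id is None or v.edge_id not in graph.edges:
            continue
        arc = _arc_position(graph, v.edge_id, np.asarray(v.centroid_um))
        by_edge.setdefault(v.edge_id, []).append(arc)
    dists: list[float] = []
    for arcs in by_edge.values():
        arcs.sort()
        dists.extend(float(b - a) for a, b in zip(arcs, arcs[1:]))
    return dists


def intensity_by_valve_position(
    channel2: Volume3D,
    graph: NetworkGraph,
    valves: list[Valve],
    window_um: float = 50.0,
) -> list[tuple[float, float]]:
    """For base-of-capillary valves: mean second-channel intensity along the
    capillary side (upstream) and the link side (downstream) of the junction.

    Means are taken over centerline path voxels within ``window_um``
    arc-length of the junction node. Valves without both sides are skipped.
    """
    spacing = np.asarray(channel2.spacing_um)
    results: list[tuple[float, float]] = []
    for v in valves:
        if v.position_class != "base_of_capillary":
            continue
        c = np.asarray(v.centroid_um)
        best_nid, best_d = None, np.inf
        for nid, node in graph.nodes.items():
            classes = {e.cls for e in graph.incident(nid)}
            if "capillary_branch" not in classes or not (
                classes & {"precollector_link", "cropped_precollector"}
            ):
                continue
            d = float(np.linalg.norm(np.asarray(node.pos_um) - c))
            if d < best_d:
                best_nid, best_d = nid, d
        if best_nid is None:
            continue
        node_pos = np.asarray(graph.nodes[best_nid].pos_um)

        def side_mean(classes: set[str]) -> float | None:
            samples = []
            for e in graph.incident(best_nid):
                if e.cls not in classes:
                    continue
                p = graph.path_um(e)
                if np.linalg.norm(p[0] - node_pos) > np.linalg.norm(p[-1] - node_pos):
                    p = p[::-1]
                    path_vox = e.path_vox[::-1]
                else:
                    path_vox = e.path_vox
                steps = np.linalg.norm(np.diff(p, axis=0), axis=1)
                arc = np.concatenate([[0.0], np.cumsum(steps)])
                sel = path_vox[arc <= window_um]
                if len(sel):
                    samples.append(channel2.data[tuple(sel.T)].astype(np.float64))
            if not samples:
                return None
            return float(np.concatenate(samples).mean())

        up = side_mean({"capillary_branch"})
        down = side_mean({"precollector_link", "cropped_precollector"})
        if up is None or down is None:
            warnings.warn("base valve lacks one junction side; skipped")
            continue
        results.append((up, down))
    return results


def compute_metrics(
    mask: SegmentationMask,
    graph: NetworkGraph,
    valves: list[Valve],
    sample_volume_um3: float,
    channel2: Volume3D | None = None,
) -> MetricsReport:
    """Assemble the full report from classified artifacts."""
    vol_d, len_d = network_density(mask, graph, sample_volume_um3)
    cap = capillary_stats(graph)
    total_len = graph.total_length_um(DENSITY_CLASSES)
    cap_len = sum(r[0] for r in cap)
    orientations = []
    for e in graph.iter_edges():
        if e.cls == "capillary_branch" and len(e.path_vox) >= 2:
            orientations.append(capillary_orientation(graph.path_um(e)))
    assigned = [v for v in valves if v.position_class != "unassigned"]
    fractions: dict[str, float] = {}
    if assigned:
        for cls in ("within_capillary", "base_of_capillary", "precollector", "collector"):
            fractions[cls] = sum(
                1 for v in assigned if v.position_class == cls
            ) / len(assigned)
    report = MetricsReport(
        volume_density=vol_d,
        length_density_mm_per_mm3=len_d,
        capillary_length_density_share=cap_len / total_len if total_len > 0 else 0.0,
        capillary_lengths_um=[r[0] for r in cap],
        capillary_z_range_um=[(r[1], r[2]) for r in cap],
        orientations_deg=orientations,
        valve_density_per_mm3=len(valves) / (sample_volume_um3 * 1e-9),
        valves_per_layer=valves_per_layer(valves, graph, sample_volume_um3),
        intervalve_distances_um=intervalve_distances(valves, graph),
        valve_position_fractions=fractions,
    )
    if channel2 is not None:
        report.intensity_by_valve_position = intensity_by_valve_position(
            channel2, graph, valves
        )
    return report
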