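"""Intraluminal valve detection inside the vessel-network mask.

Stages: white top-hat background attenuation with a spherical structuring
element (valves are small enough that the grayscale opening estimates the
vessel/background signal and the residue keeps them), Gaussian preblur,
local-mean adaptive binarization restricted to the mask, and a component
volume gate.

The flat grayscale erosion/dilation by a Euclidean ball is computed exactly
via a run-length decomposition of the ball footprint (one 1D min/max filter
per distinct chord length, then a min/max over the (dz, dy) shifts), which is
orders of magnitude faster than a dense footprint at 18 μm radii but agrees
voxel-for-voxel with direct morphology.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .segmentation import connectivity_structure
from .types import NetworkGraph, SegmentationMask, Valve, Volume3D

__all__ = [
    "attenuate_background",
    "detect_valve_blobs",
    "classify_valve_positions",
    "assign_layers",
]


def _ball_runs(radius_vox: int) -> list[tuple[int, int, int]]:
    """(dz, dy, half_chord) runs of the discrete ball dz²+dy²+dx² <= r²."""
    runs = []
    r = radius_vox
    for dz in range(-r, r + 1):
        for dy in range(-r, r + 1):
            rem = r * r - dz * dz - dy * dy
            if rem >= 0:
                runs.append((dz, dy, int(np.floor(np.sqrt(rem) + 1e-9))))
    return runs


def _flat_ball_filter(data: np.ndarray, radius_vox: int, op: str) -> np.ndarray:
    """Exact flat grey erosion/dilation by a Euclidean ball.

    Outside the image the signal is treated as +inf (erosion) / -inf
    (dilation), i.e. the structuring element only sees real data.
    """
    assert op in ("erosion", "dilation")
    sign = 1.0 if op == "erosion" else -1.0
    filt1d = ndimage.minimum_filter1d
    combine = np.minimum
    pad_val = np.inf
    work = data.astype(np.float32, copy=False)
    if op == "dilation":
        work = -work  # dilation = -erosion(-I)
    r = radius_vox
    nz, ny, nx = work.shape
    padded = np.pad(work, r, constant_values=pad_val)
    runs = _ball_runs(r)
    out = np.full(work.shape, pad_val, dtype=np.float32)
    lengths = sorted({2 * h + 1 for _, _, h in runs})
    for length in lengths:
        f = filt1d(padded, length, axis=2, mode="constant", cval=pad_val)
        for dz, dy, h in runs:
            if 2 * h + 1 != length:
                continue
            view = f[r + dz : r + dz + nz, r + dy : r + dy + ny, r : r + nx]
            combine(out, view, out=out)
        del f
    return out * sign


def ball_opening(data: np.ndarray, radius_vox: int) -> np.ndarray:
    """Grayscale opening by a Euclidean ball (exact, decomposed)."""
    return _flat_ball_filter(
        _flat_ball_filter(data, radius_vox, "erosion"), radius_vox, "dilation"
    )


def attenuate_background(
    volume: Volume3D, mask: SegmentationMask, radius_um: float = 18.0
) -> Volume3D:
    """White top-hat of the masked intensity: signal minus its ball opening.

    Structures too small to contain the ball (valves) keep their contrast;
    anything at the structuring scale or larger is suppressed. Voxels outside
    the mask are zeroed.
    """
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    radius_vox = int(radius_um / min(volume.spacing_um))
    if radius_vox < 1:
        raise ValueError("opening radius is smaller than one voxel")
    masked = np.where(mask.data, volume.data.astype(np.float32), 0.0)
    opened = ball_opening(masked, radius_vox)
    out = np.clip(masked - opened, 0.0, None)
    out[~mask.data] = 0.0
    return Volume3D(out, volume.spacing_um, volume.origin_um, volume.channel)


def detect_valve_blobs(
    enhanced: Volume3D,
    mask: SegmentationMask,
    sigma_vox: float = 2.0,
    sensitivity: float = 0.5,
    window_vox: int | None = None,
    vol_bounds_um3: tuple[float, float] = (1e3, 1e4),
    connectivity: int = 26,
    mask_erosion_vox: int = 5,
    margin: float = 0.3,
) -> list[Valve]:
    """Detect valve blobs in the background-attenuated image.

    Pipeline: Gaussian blur (sigma in voxels) -> local-mean adaptive
    binarization, foreground iff
    ``I >= mu_local * 2*(1 - sensitivity) * (1 + margin)``
    -> restrict to mask -> connected components -> volume gate (inclusive
    bounds).

    The Bradley-style ``margin`` keeps near-uniform regions (where intensity
    hovers at its own local mean) out of the foreground; without it, half the
    voxels of any flat plateau tie with the mean and percolate into large
    spurious components. At sensitivity 0.5 the threshold is
    ``(1 + margin) * mu_local``.

    The local mean is computed over in-mask voxels of a cubic window (box
    sums, the integral-image formulation), so the statistic reflects vessel
    signal rather than empty background. Zero-intensity voxels are never
    foreground. The detection region is the mask eroded by
    ``mask_erosion_vox`` (6-neighbourhood): the outermost voxel shell carries
    systematic top-hat residue where the discrete ball under-reconstructs
    the vessel surface, and would otherwise shed blob-sized artefacts.
    """
    if not 0.0 <= sensitivity <= 1.0:
        raise ValueError("sensitivity must be in [0, 1]")
    if enhanced.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    if window_vox is None:
        window_vox = 2 * int(18.0 / min(enhanced.spacing_um)) + 1
    if window_vox < 1 or window_vox % 2 == 0:
        raise ValueError("window_vox must be a positive odd integer")

    data = enhanced.data.astype(np.float32)
    blurred = ndimage.gaussian_filter(data, sigma_vox) if sigma_vox > 0 else data
    m = mask.data
    if mask_erosion_vox > 0:
        m = ndimage.binary_erosion(
            m,
            ndimage.generate_binary_structure(3, 1),
            iterations=mask_erosion_vox,
        )
    mf = m.astype(np.float32)
    local_sum = ndimage.uniform_filter(blurred * mf, size=window_vox)
    local_cnt = ndimage.uniform_filter(mf, size=window_vox)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = np.where(local_cnt > 0, local_sum / np.maximum(local_cnt, 1e-12), 0.0)
    factor = 2.0 * (1.0 - sensitivity) * (1.0 + margin)
    fg = (blurred >= mu * factor) & (blurred > 0) & m

    labels, n = ndimage.label(fg, structure=connectivity_structure(connectivity))
    valves: list[Valve] = []
    if n == 0:
        return valves
    voxel = enhanced.voxel_volume_um3
    spacing = np.asarray(enhanced.spacing_um)
    # volume is measured on the *unblurred* enhanced image at the same
    # threshold: the preblur exists to stabilise detection, but its halo
    # would inflate blob volumes severalfold
    sharp = (data >= mu * factor) & (data > 0)
    labels_sharp = np.where(sharp, labels, 0)
    counts = np.bincount(labels_sharp.ravel(), minlength=n + 1)
    lo, hi = vol_bounds_um3
    for lab in np.flatnonzero((counts * voxel >= lo) & (counts * voxel <= hi)):
        if lab == 0:
            continue
        idx = np.argwhere(labels_sharp == lab)
        w = data[tuple(idx.T)]
        if w.sum() <= 0:
            w = np.ones(len(idx))
        centroid = (idx * w[:, None]).sum(axis=0) / w.sum() * spacing
        valves.append(
            Valve(
                centroid_um=tuple(float(c) for c in centroid),
                volume_um3=float(counts[lab] * voxel),
                voxel_count=int(counts[lab]),
            )
        )
    valves.sort(key=lambda v: v.centroid_um)
    return valves


def _edge_point_cloud(graph: NetworkGraph) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All retained edge path points (μm) with edge ids and arc-lengths."""
    pts, ids, arcs = [], [], []
    for e in graph.iter_edges():
        p = graph.path_um(e)
        if len(p) == 0:
            continue
        steps = np.linalg.norm(np.diff(p, axis=0), axis=1) if len(p) > 1 else []
        arc = np.concatenate([[0.0], np.cumsum(steps)]) if len(p) > 1 else np.zeros(1)
        pts.append(p)
        ids.append(np.full(len(p), e.id))
        arcs.append(arc)
    if not pts:
        return np.empty((0, 3)), np.empty(0, dtype=int), np.empty(0)
    return np.vstack(pts), np.concatenate(ids).astype(int), np.concatenate(arcs)


def classify_valve_positions(
    valves: list[Valve], graph: NetworkGraph, junction_radius_um: float = 20.0
) -> list[Valve]:
    """Assign each valve to its nearest edge and a network position class.

    ``base_of_capillary`` wins when the valve sits within the junction radius
    of a node joining a capillary branch to a precollector link; otherwise the
    class follows the assigned edge (capillary -> within_capillary, layer-3
    edge -> collector, else precollector). Valves farther than twice the
    junction radius from every edge stay unassigned.
    """
    pts, eids, arcs = _edge_point_cloud(graph)
    base_nodes = []
    for nid in graph.nodes:
        classes = {e.cls for e in graph.incident(nid)}
        if "capillary_branch" in classes and (
            classes & {"precollector_link", "cropped_precollector"}
        ):
            base_nodes.append(np.asarray(graph.nodes[nid].pos_um))
    base_nodes = np.asarray(base_nodes) if base_nodes else np.empty((0, 3))

    out: list[Valve] = []
    for v in valves:
        v = Valve(**{**v.__dict__})
        c = np.asarray(v.centroid_um)
        if len(pts) == 0:
            v.position_class = "unassigned"
            out.append(v)
            continue
        d = np.linalg.norm(pts - c, axis=1)
        k = int(np.argmin(d))
        v.distance_to_edge_um = float(d[k])
        if d[k] > 2 * junction_radius_um:
            v.position_class = "unassigned"
            out.append(v)
            continue
        v.edge_id = int(eids[k])
        near_base = (
            len(base_nodes) > 0
            and np.linalg.norm(base_nodes - c, axis=1).min() <= junction_radius_um
        )
        edge = graph.edges[v.edge_id]
        if near_base:
            v.position_class = "base_of_capillary"
        elif edge.cls == "capillary_branch":
            v.position_class = "within_capillary"
        elif edge.layer == 3:
            v.position_class = "collector"
        else:
            v.position_class = "precollector"
        out.append(v)
    return out


def assign_layers(
    items: list[Valve] | NetworkGraph,
    z_bands_um: tuple[float, float] = (150.0, 210.0),
):
    """Label valves (by centroid depth) or edges (by median path depth) with
    their network layer: 1 below the first band, 2 between, 3 beyond.
    Bands are half-open: a depth exactly at a boundary goes to the deeper
    layer.
    """
    bands = tuple(float(b) for b in z_bands_um)
    if list(bands) != sorted(bands):
        raise ValueError("z bands must be sorted ascending")

    def layer_of(z: float) -> int:
        if z < bands[0]:
            return 1
        if z < bands[1]:
            return 2
        return 3

    if isinstance(items, NetworkGraph):
        g = items.copy()
        for e in g.iter_edges(include_discarded=True):
            z = float(np.median(g.path_um(e)[:, 0]))
            e.layer = layer_of(z)
        return g
    out = []
    for v in items:
        v = Valve(**{**v.__dict__})
        v.layer = layer_of(v.centroid_um[0])
        out.append(v)
    return out
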