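"""Reading and writing standard formats (TIFF volumes, graph and table exports)."""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import tifffile

from .types import NetworkGraph, SegmentationMask, Valve, Volume3D

__all__ = [
    "read_volume",
    "write_volume",
    "write_mask",
    "write_graph",
    "write_valves",
    "write_metrics",
]


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float] | None:
    """Extract (z, y, x) spacing in μm from ImageJ or OME metadata."""
    try:
        if tf.ome_metadata:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            for el in root.iter():
                if el.tag.endswith("Pixels"):
                    x = el.get("PhysicalSizeX")
                    y = el.get("PhysicalSizeY")
                    z = el.get("PhysicalSizeZ")
                    if x and y and z:
                        return float(z), float(y), float(x)
    except Exception:  # noqa: BLE001 - fall through to other sources
        pass
    meta = tf.imagej_metadata
    if meta and "spacing" in meta:
        page = tf.pages[0]
        try:
            xr = page.tags["XResolution"].value
            yr = page.tags["YResolution"].value
            sx = xr[1] / xr[0]
            sy = yr[1] / yr[0]
        except (KeyError, ZeroDivisionError):
            return None
        return float(meta["spacing"]), float(sy), float(sx)
    return None


def read_volume(
    path: str | Path,
    spacing_um: tuple[float, float, float] | None = None,
    channel: str = "",
) -> Volume3D:
    """Read a TIFF/OME-TIFF stack into a :class:`Volume3D`.

    Spacing is taken from OME or ImageJ metadata; ``spacing_um`` overrides
    both and is required if neither is present.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta_spacing = _spacing_from_tiff(tf)
    if data.ndim == 2:
        raise ValueError("3D stack required, got a single 2D page")
    if data.ndim != 3:
        raise ValueError(f"expected a 3D stack, got shape {data.shape}")
    spacing = spacing_um or meta_spacing
    if spacing is None:
        raise ValueError(
            f"{path}: no spacing metadata found; pass spacing_um explicitly"
        )
    return Volume3D(data, spacing, channel=channel)


def write_volume(volume: Volume3D, path: str | Path) -> None:
    """Write a volume as ImageJ-flavoured TIFF with spacing metadata."""
    sz, sy, sx = volume.spacing_um
    data = volume.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / sx, 1.0 / sy),
        metadata={"spacing": sz, "unit": "um", "axes": "ZYX"},
    )


def write_mask(mask: SegmentationMask, path: str | Path) -> None:
    write_volume(
        Volume3D(mask.data.astype(np.uint8) * 255, mask.spacing_um, mask.origin_um),
        path,
    )


def write_graph(graph: NetworkGraph, basepath: str | Path, meta: dict | None = None) -> None:
    """Export a network graph as CSV node/edge tables plus GraphML."""
    basepath = Path(basepath)
    nodes = pd.DataFrame(
        [
            {
                "id": n.id,
                "z_um": n.pos_um[0],
                "y_um": n.pos_um[1],
                "x_um": n.pos_um[2],
                "degree": graph.degree(n.id),
            }
            for n in graph.nodes.values()
        ]
    ).sort_values("id") if graph.nodes else pd.DataFrame(
        columns=["id", "z_um", "y_um", "x_um", "degree"]
    )
    edges = pd.DataFrame(
        [
            {
                "id": e.id,
                "u": e.u,
                "v": e.v,
                "length_um": e.length_um,
                "class": e.cls,
                "layer": e.layer if e.layer is not None else "",
                "n_path_voxels": len(e.path_vox),
            }
            for e in graph.edges.values()
        ]
    ).sort_values("id") if graph.edges else pd.DataFrame(
        columns=["id", "u", "v", "length_um", "class", "layer", "n_path_voxels"]
    )
    for key, value in (meta or {}).items():
        nodes[key] = value
        edges[key] = value
    nodes.to_csv(basepath.with_suffix(".nodes.csv"), index=False)
    edges.to_csv(basepath.with_suffix(".edges.csv"), index=False)

    gx = nx.MultiGraph()
    for n in graph.nodes.values():
        gx.add_node(n.id, z_um=n.pos_um[0], y_um=n.pos_um[1], x_um=n.pos_um[2])
    for e in graph.edges.values():
        gx.add_edge(e.u, e.v, key=e.id, length_um=e.length_um, cls=e.cls)
    nx.write_graphml(gx, basepath.with_suffix(".graphml"))


def write_valves(valves: list[Valve], path: str | Path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {
                "z_um": v.centroid_um[0],
                "y_um": v.centroid_um[1],
                "x_um": v.centroid_um[2],
                "volume_um3": v.volume_um3,
                "voxel_count": v.voxel_count,
                "position_class": v.position_class,
                "layer": v.layer if v.layer is not None else "",
                "edge_id": v.edge_id if v.edge_id is not None else "",
                "distance_to_edge_um": v.distance_to_edge_um,
            }
            for v in valves
        ]
    )
    if df.empty:
        df = pd.DataFrame(
            columns=[
                "z_um",
                "y_um",
                "x_um",
                "volume_um3",
                "voxel_count",
                "position_class",
                "layer",
                "edge_id",
                "distance_to_edge_um",
            ]
        )
    for key, value in (meta or {}).items():
        df[key] = value
    df.to_csv(path, index=False)


def write_metrics(report, path: str | Path, meta: dict | None = None) -> None:
    payload = report.to_dict()
    if meta:
        payload["provenance"] = dict(meta)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
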