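"""Shared domain types carried between pipeline stages.

Conventions used everywhere in this package:

* arrays are indexed ``(z, y, x)`` with z = depth below the skin surface,
  increasing into the tissue;
* all physical quantities are micrometres (lengths) or cubic micrometres
  (volumes) unless a name says otherwise;
* voxel indices are 0-based, voxel intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

__all__ = [
    "Volume3D",
    "SegmentationMask",
    "Node",
    "Edge",
    "NetworkGraph",
    "Valve",
    "MetricsReport",
    "EDGE_CLASSES",
    "VALVE_POSITION_CLASSES",
]

#: Exhaustive edge class labels.
EDGE_CLASSES = (
    "capillary_branch",
    "precollector_link",
    "cropped_precollector",
    "border_ambiguous",
    "discarded",
    "unclassified",
)

#: Exhaustive valve position labels.
VALVE_POSITION_CLASSES = (
    "within_capillary",
    "base_of_capillary",
    "precollector",
    "collector",
    "unassigned",
)


@dataclass
class Volume3D:
    """A 3D intensity grid with physical voxel spacing.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Non-negative intensities.
    spacing_um : tuple of float
        Voxel spacing ``(z, y, x)`` in micrometres.
    origin_um : tuple of float
        Physical offset of voxel ``(0, 0, 0)``; z measures depth below the
        epidermal surface.
    channel : str
        Free-text channel label.
    """

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    channel: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("Volume3D requires a non-empty 3D array")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if len(self.spacing_um) != 3 or any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be three positive lengths")
        self.origin_um = tuple(float(o) for o in self.origin_um)
        if np.issubdtype(self.data.dtype, np.floating) and not np.all(
            np.isfinite(self.data)
        ):
            raise ValueError("intensities must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    @property
    def extent_um(self) -> tuple[float, float, float]:
        """Physical size of the grid along (z, y, x)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing_um))

    def with_data(self, data: np.ndarray) -> "Volume3D":
        """Same geometry, different samples (shape must match)."""
        if data.shape != self.data.shape:
            raise ValueError("replacement data must keep the shape")
        return replace(self, data=data)


@dataclass
class SegmentationMask:
    """Binary foreground mask aligned with a source :class:`Volume3D`."""

    data: np.ndarray
    spacing_um: tuple[float, float, float]
    origin_um: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3 or self.data.size == 0:
            raise ValueError("SegmentationMask requires a non-empty 3D array")
        self.spacing_um = tuple(float(s) for s in self.spacing_um)
        if any(s <= 0 for s in self.spacing_um):
            raise ValueError("spacing_um must be positive")
        self.origin_um = tuple(float(o) for o in self.origin_um)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        return float(np.prod(self.spacing_um))

    def foreground_volume_um3(self) -> float:
        return float(self.data.sum()) * self.voxel_volume_um3


@dataclass
class Node:
    id: int
    pos_um: tuple[float, float, float]  # (z, y, x)


@dataclass
class Edge:
    id: int
    u: int
    v: int
    path_vox: np.ndarray  # (n, 3) ordered voxel indices, u -> v
    length_um: float
    cls: str = "unclassified"
    layer: int | None = None

    def __post_init__(self) -> None:
        self.path_vox = np.asarray(self.path_vox, dtype=np.int64).reshape(-1, 3)
        if self.cls not in EDGE_CLASSES:
            raise ValueError(f"unknown edge class {self.cls!r}")


class NetworkGraph:
    """Vessel network as nodes, edges (with voxel paths) and adjacency.

    A thin multigraph: parallel edges and self-loops are allowed (they arise
    from skeleton cycles). Edge lengths are polyline lengths in micrometres.
    """

    def __init__(
        self,
        nodes: dict[int, Node] | None = None,
        edges: dict[int, Edge] | None = None,
        spacing_um: tuple[float, float, float] = (1.0, 1.0, 1.0),
    ) -> None:
        self.nodes: dict[int, Node] = dict(nodes or {})
        self.edges: dict[int, Edge] = dict(edges or {})
        self.spacing_um = tuple(float(s) for s in spacing_um)

    # -- basic queries -----------------------------------------------------
    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def iter_edges(self, *, include_discarded: bool = False) -> Iterator[Edge]:
        for e in self.edges.values():
            if include_discarded or e.cls != "discarded":
                yield e

    def incident(self, node_id: int, *, include_discarded: bool = False) -> list[Edge]:
        return [
            e
            for e in self.iter_edges(include_discarded=include_discarded)
            if node_id in (e.u, e.v)
        ]

    def degree(self, node_id: int, *, include_discarded: bool = False) -> int:
        """Count of incident edge endpoints (self-loops count twice)."""
        d = 0
        for e in self.iter_edges(include_discarded=include_discarded):
            if e.u == node_id:
                d += 1
            if e.v == node_id:
                d += 1
        return d

    def adjacency(self) -> tuple[np.ndarray, list[int]]:
        """Symmetric node-by-node incidence count matrix.

        Returns the matrix and the node id ordering of its rows.
        """
        ids = sorted(self.nodes)
        index = {nid: i for i, nid in enumerate(ids)}
        a = np.zeros((len(ids), len(ids)), dtype=np.int64)
        for e in self.iter_edges():
            i, j = index[e.u], index[e.v]
            a[i, j] += 1
            if i != j:
                a[j, i] += 1
        return a, ids

    def total_length_um(self, classes: tuple[str, ...] | None = None) -> float:
        total = 0.0
        for e in self.iter_edges():
            if classes is None or e.cls in classes:
                total += e.length_um
        return total

    def n_components(self) -> int:
        """Connected components over retained edges (isolated nodes count)."""
        parent = {nid: nid for nid in self.nodes}

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for e in self.iter_edges():
            ru, rv = find(e.u), find(e.v)
            if ru != rv:
                parent[ru] = rv
        return len({find(n) for n in self.nodes})

    def cycle_count(self) -> int:
        """First Betti number b1 = E - V + C of the retained graph."""
        if not self.nodes:
            return 0
        n_edges = sum(1 for _ in self.iter_edges())
        return n_edges - self.n_nodes + self.n_components()

    def path_um(self, edge: Edge) -> np.ndarray:
        """Edge path in physical coordinates (n, 3) μm."""
        return edge.path_vox * np.asarray(self.spacing_um)

    def copy(self) -> "NetworkGraph":
        g = NetworkGraph(spacing_um=self.spacing_um)
        g.nodes = {i: Node(n.id, tuple(n.pos_um)) for i, n in self.nodes.items()}
        g.edges = {
            i: Edge(e.id, e.u, e.v, e.path_vox.copy(), e.length_um, e.cls, e.layer)
            for i, e in self.edges.items()
        }
        return g


@dataclass
class Valve:
    """A detected intraluminal valve blob."""

    centroid_um: tuple[float, float, float]  # (z, y, x)
    volume_um3: float
    voxel_count: int
    position_class: str = "unassigned"
    layer: int | None = None
    edge_id: int | None = None
    distance_to_edge_um: float = float("nan")

    def __post_init__(self) -> None:
        if self.position_class not in VALVE_POSITION_CLASSES:
            raise ValueError(f"unknown position class {self.position_class!r}")


@dataclass
class MetricsReport:
    """All quantitative outputs of a pipeline run."""

    volume_density: float = 0.0
    length_density_mm_per_mm3: float = 0.0
    capillary_length_density_share: float = 0.0
    capillary_lengths_um: list[float] = field(default_factory=list)
    capillary_z_range_um: list[tuple[float, float]] = field(default_factory=list)
    orientations_deg: list[tuple[float, float, float]] = field(default_factory=list)
    valve_density_per_mm3: float = 0.0
    valves_per_layer: dict[int, dict[str, float]] = field(default_factory=dict)
    intervalve_distances_um: list[float] = field(default_factory=list)
    valve_position_fractions: dict[str, float] = field(default_factory=dict)
    intensity_by_valve_position: list[tuple[float, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "volume_density": self.volume_density,
            "length_density_mm_per_mm3": self.length_density_mm_per_mm3,
            "capillary_length_density_share": self.capillary_length_density_share,
            "capillary_lengths_um": list(self.capillary_lengths_um),
            "capillary_z_range_um": [list(t) for t in self.capillary_z_range_um],
            "orientations_deg": [list(t) for t in self.orientations_deg],
            "valve_density_per_mm3": self.valve_density_per_mm3,
            "valves_per_layer": {
                str(k): dict(v) for k, v in sorted(self.valves_per_layer.items())
            },
            "intervalve_distances_um": list(self.intervalve_distances_um),
            "valve_position_fractions": dict(self.valve_position_fractions),
            "intensity_by_valve_position": [
                list(t) for t in self.intensity_by_valve_position
            ],
        }
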