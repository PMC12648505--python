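"""Binary vessel-network mask: dual-threshold 3D hysteresis + artefact filter."""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .types import SegmentationMask, Volume3D

__all__ = [
    "connectivity_structure",
    "hysteresis_segment",
    "filter_components",
    "auto_thresholds",
    "segment_network",
]


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 binary structure for a 6/18/26 neighbourhood."""
    order = {6: 1, 18: 2, 26: 3}
    if connectivity not in order:
        raise ValueError("connectivity must be 6, 18 or 26")
    return ndimage.generate_binary_structure(3, order[connectivity])


def auto_thresholds(
    volume: Volume3D, low_fraction: float = 0.5
) -> tuple[float, float]:
    """Data-driven hysteresis thresholds: t_high by Otsu, t_low a fraction of it."""
    t_high = float(threshold_otsu(np.asarray(volume.data)))
    return low_fraction * t_high, t_high


def hysteresis_segment(
    volume: Volume3D, t_low: float, t_high: float, connectivity: int = 26
) -> SegmentationMask:
    """Dual-threshold hysteresis segmentation.

    Foreground is the union of connected components of ``{I >= t_low}`` that
    contain at least one voxel with ``I >= t_high``.
    """
    if t_low > t_high:
        raise ValueError("t_low must be <= t_high")
    structure = connectivity_structure(connectivity)
    low = volume.data >= t_low
    labels, n = ndimage.label(low, structure=structure)
    if n == 0:
        out = np.zeros(volume.shape, dtype=bool)
    else:
        seeds = np.unique(labels[volume.data >= t_high])
        seeds = seeds[seeds > 0]
        keep = np.zeros(n + 1, dtype=bool)
        keep[seeds] = True
        out = keep[labels]
    return SegmentationMask(out, volume.spacing_um, volume.origin_um)


def filter_components(
    mask: SegmentationMask, min_volume_um3: float, connectivity: int = 26
) -> SegmentationMask:
    """Discard connected components with volume strictly below the threshold."""
    structure = connectivity_structure(connectivity)
    labels, n = ndimage.label(mask.data, structure=structure)
    if n == 0:
        return SegmentationMask(
            np.zeros(mask.shape, dtype=bool), mask.spacing_um, mask.origin_um
        )
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    voxel = mask.voxel_volume_um3
    keep = counts * voxel >= min_volume_um3  # strict-less-than is discarded
    keep[0] = False
    return SegmentationMask(keep[labels], mask.spacing_um, mask.origin_um)


def segment_network(
    volume: Volume3D,
    t_low: float | None = None,
    t_high: float | None = None,
    min_component_volume_um3: float = 5.832e6,
    connectivity: int = 26,
    otsu_low_fraction: float = 0.5,
) -> SegmentationMask:
    """Hysteresis segmentation followed by the small-component filter."""
    if t_high is None:
        auto_low, t_high = auto_thresholds(volume, otsu_low_fraction)
        if t_low is None:
            t_low = auto_low
    elif t_low is None:
        t_low = otsu_low_fraction * t_high
    mask = hysteresis_segment(volume, t_low, t_high, connectivity)
    return filter_components(mask, min_component_volume_um3, connectivity)
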