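"""Pipeline configuration: every tunable constant in one place.

All physical parameters are stored in micrometres so behaviour is independent
of voxel resolution; voxel equivalents are derived at run time. Two
exceptions follow the conventions of the methods they parameterize and are in
voxel units: ``preblur_sigma_vox`` (Gaussian blur before valve binarization)
and ``adaptive_window_vox`` (local-mean window edge length).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "load_config", "save_config", "config_hash"]


@dataclass
class PipelineConfig:
    #: Target isotropic voxel spacing after resampling (μm).
    iso_spacing_um: float = 1.8
    #: Hysteresis thresholds. ``None`` means data-driven: t_high from Otsu's
    #: method on the denoised volume, t_low = otsu_low_fraction * t_high.
    t_low: float | None = None
    t_high: float | None = None
    otsu_low_fraction: float = 0.5
    #: Connected components smaller than this are artefacts (strict <).
    min_component_volume_um3: float = 5.832e6
    #: Graph simplification: edges shorter than this are pruned/collapsed.
    min_edge_length_um: float = 10.0
    #: Border rules for ROI-cropped elements.
    border_capillary_max_um: float = 25.0
    border_precollector_min_um: float = 300.0
    #: Valve detection.
    opening_radius_um: float = 18.0
    preblur_sigma_vox: float = 2.0
    adaptive_sensitivity: float = 0.5
    #: Local-mean window edge (voxels, odd). ``None`` derives
    #: 2 * floor(opening_radius_um / voxel) + 1 at run time (matched to the
    #: structuring scale).
    adaptive_window_vox: int | None = None
    valve_volume_min_um3: float = 1e3
    valve_volume_max_um3: float = 1e4
    #: Erode the detection region by this many voxels (rim-artefact guard):
    #: the outermost shell of wide vessels carries systematic top-hat residue
    #: where the discrete ball under-reconstructs the vessel surface.
    valve_mask_erosion_vox: int = 5
    #: Bradley-style margin on the adaptive threshold; keeps flat plateaus
    #: (intensity at its own local mean) out of the foreground.
    adaptive_margin: float = 0.3
    junction_radius_um: float = 20.0
    #: Depth-band boundaries separating network layers 1/2/3 (μm).
    layer_z_bands_um: tuple[float, float] = (150.0, 210.0)
    #: Voxel neighbourhood order (6, 18 or 26).
    connectivity: int = 26
    #: Denoising stage: "nlm", "gaussian" or "none".
    denoise_method: str = "nlm"
    nlm_patch_radius_vox: int = 1
    nlm_search_radius_vox: int = 3
    #: NLM strength as multiple of the MAD-estimated noise sigma.
    nlm_h_factor: float = 0.8
    gaussian_denoise_sigma_vox: float = 1.0
    #: Flip the z axis on load (for stacks acquired epidermis-last).
    flip_z: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.layer_z_bands_um = tuple(float(b) for b in self.layer_z_bands_um)
        self.validate()

    def validate(self) -> None:
        if self.t_low is not None and self.t_high is not None:
            if self.t_low > self.t_high:
                raise ValueError("t_low must be <= t_high")
        if not self.valve_volume_min_um3 < self.valve_volume_max_um3:
            raise ValueError("valve_volume_min_um3 must be < valve_volume_max_um3")
        if not self.border_capillary_max_um < self.border_precollector_min_um:
            raise ValueError(
                "border_capillary_max_um must be < border_precollector_min_um"
            )
        for name in (
            "iso_spacing_um",
            "min_component_volume_um3",
            "min_edge_length_um",
            "border_capillary_max_um",
            "border_precollector_min_um",
            "opening_radius_um",
            "valve_volume_min_um3",
            "valve_volume_max_um3",
            "junction_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.adaptive_sensitivity <= 1.0:
            raise ValueError("adaptive_sensitivity must be in [0, 1]")
        if self.adaptive_window_vox is not None:
            if self.adaptive_window_vox < 1 or self.adaptive_window_vox % 2 == 0:
                raise ValueError("adaptive_window_vox must be a positive odd integer")
        if list(self.layer_z_bands_um) != sorted(self.layer_z_bands_um):
            raise ValueError("layer_z_bands_um must be sorted ascending")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if self.denoise_method not in ("nlm", "gaussian", "none"):
            raise ValueError("denoise_method must be 'nlm', 'gaussian' or 'none'")

    # -- derived voxel-space values ---------------------------------------
    def min_component_voxels(self, spacing_um: tuple[float, float, float]) -> float:
        """Component-volume threshold expressed in voxels at a given spacing."""
        voxel = float(spacing_um[0] * spacing_um[1] * spacing_um[2])
        return self.min_component_volume_um3 / voxel

    def window_vox(self, spacing_um: tuple[float, float, float]) -> int:
        if self.adaptive_window_vox is not None:
            return self.adaptive_window_vox
        vox = min(spacing_um)
        return 2 * int(self.opening_radius_um / vox) + 1

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["layer_z_bands_um"] = list(self.layer_z_bands_um)
        return d


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Load a YAML/JSON config file, applying defaults for absent keys.

    Unknown keys and invariant violations raise ``ValueError`` naming the
    offending field.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config file {path}: {exc}") from exc
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        data.update(loaded)
    data.update(overrides)
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=True))


def config_hash(cfg: PipelineConfig) -> str:
    """Short provenance hash carried into every output artifact."""
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
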