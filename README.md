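# lymph3d

3D quantification of dermal lymphatic networks from light-sheet volumes.

The pipeline segments the vessel network from a 3D reporter channel,
converts it to a graph of capillaries (terminal edges) and precollectors
(interior edges), detects intraluminal valves as bright compact blobs inside
the network mask, and computes morphometrics: volume/length density,
capillary lengths, depth ranges and orientations, per-layer valve counts,
and inter-valve distances. A synthetic phantom generator produces volumes
with exhaustive ground truth (per-voxel labels, true graph, true valves,
analytic metrics), so every stage is verifiable without raw microscopy data.

## Pipeline stages

1. **Preprocessing** — ROI crop, isotropic resampling (default 1.8 μm,
   trilinear), 3D non-local-means denoising (or a cheap Gaussian
   preconditioner).
2. **Segmentation** — dual-threshold 3D hysteresis (data-driven Otsu
   defaults), then removal of connected components smaller than
   5.832×10⁶ μm³ (10⁶ voxels at 1.8 μm).
3. **Skeleton graph** — parallel medial-axis thinning; skeleton→graph
   conversion iterated to convergence of the (node, edge) counts with a
   10 μm minimum edge length; terminal edges classified as capillary
   branches, interior edges as precollector links; ROI-border rules
   (<25 μm discarded, >300 μm kept as cropped precollectors, in between
   flagged `border_ambiguous`).
4. **Valve detection** — white top-hat with an 18 μm-radius spherical
   structuring element (exact flat morphology via run-length decomposition),
   Gaussian preblur (σ = 2 voxels), local-mean adaptive binarization
   restricted to the mask (sensitivity 0.5, Bradley-style margin), 26-connected
   components gated to volumes between 10³ and 10⁴ μm³; position classes
   (within capillary / base of capillary / precollector / collector) and
   depth layers (bands at 150 and 210 μm).
5. **Morphometrics** — densities, capillary statistics, principal-axis
   orientation (roll/pitch/yaw), per-layer valve counts and counts per
   network length, inter-valve distances along the skeleton, optional
   second-channel intensity up/downstream of base-of-capillary valves.

## CLI

```sh
# generate a synthetic phantom + ground-truth sidecars
lymph3d phantom phantom.tif --seed 1

# full pipeline on a TIFF stack (spacing from metadata or --spacing z y x)
lymph3d run phantom.tif outdir/ --denoise-method gaussian
lymph3d run input.tif outdir/ --config my_config.yaml --dry-run

# individual stages / reporting
lymph3d segment input.tif mask.tif --t-low 30 --t-high 60
lymph3d report outdir/metrics.json
```

Note: the artefact filter threshold (`--min-component-volume-um3`, default
5.832×10⁶ μm³ per the source protocol) is an absolute physical volume sized
for ~1 mm³ ROIs; scale it down when analysing small test volumes whose whole
network is below it.

Outputs: `mask.tif` (8-bit), `graph.nodes.csv` / `graph.edges.csv` /
`graph.graphml`, `valves.csv`, `metrics.json` — each carrying the config
hash for provenance. All exported coordinates are physical μm, z-first,
with z measuring depth below the epidermal surface.

## Configuration

All constants live in `PipelineConfig` (YAML-serializable; every CLI flag
maps to a field). Physical parameters are in μm so behaviour is
resolution-independent; `preblur_sigma_vox` and `adaptive_window_vox` are in
voxels, following the conventions of the underlying methods.
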