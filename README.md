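# scutegrow

Synthetic tessellated-shell phantoms, seed-based scute segmentation,
per-scute morphometrics, and allometric scaling fits — a reusable
pipeline for studying how a tiled, box-like armor grows.

The package covers four stages:

1. **synth** — superellipsoid "carapace" shells tiled into polygonal
   scutes by a Lloyd-relaxed surface Voronoi tessellation, rendered as
   labeled voxel volumes with configurable intensity "valleys" along
   scute boundaries, plus full ground truth and ontogenetic series
   (isometric, allometric, or table-only).
2. **segment** — threshold + multi-source best-first contour
   propagation from per-scute seed landmarks (plain intensity priority,
   or intensity divided by the distance to the seed landmark), region
   adjacency graph (RAG) construction, and batch split/merge editing.
3. **morpho** — per-scute statistics: neighbor count, voxel volume,
   plane-based area (PBA) from the triangle/quad fan around the scute's
   RAG node (sentinel −1000 for incomplete fans at carapace openings),
   enclosing-cuboid thickness/width, local Gaussian/mean curvature from
   a quadric fit, and size normalizations (volume/SA^3/2, PBA/SA,
   thickness & width/SA^1/2, K·SA, H·SA^1/2).
4. **allometry** — PCA carapace dimensions, log-log OLS scaling fits
   with t-based 95% CIs, Poisson GLM (log link) for scute counts with
   exponentiated Wald CIs, and series-level summaries.

## CLI

```sh
scutegrow generate --config cfg.yaml --out DIR          # phantoms + ground truth
scutegrow segment  --volume v.nrrd --seeds s.json --tau 100 \
                   --mode distance_modified --out DIR   # labels + RAG + surface
scutegrow measure  --labels labels.nrrd --out stats.csv # per-scute statistics
scutegrow scale    --stats-dir DIR --out fits.json      # scaling fits
scutegrow run      --config cfg.yaml --out DIR          # full pipeline
scutegrow report   DIR                                  # Markdown summary
```

A run config (YAML) mirrors `scutegrow.pipeline.RunConfig`:

```yaml
series:
  mode: isometric            # isometric | allometric | table_only
  scale_factors: [1.0, 1.5, 2.0, 2.5, 3.0]
  n_scutes: 370
  base_shell: {length_mm: 10.0, height_mm: 7.0, width_mm: 5.5,
               shell_thickness_mm: 0.6, n_scutes: 370, rng_seed: 3}
tau: 50.0
propagation_mode: distance_modified
voxel_spacing_mm: 0.2
valley_depth: 0.5
rng_seed: 3
```

Volumes are written as NRRD (raw-encoded) or multipage TIFF with a JSON
frame sidecar; meshes as ASCII PLY (with per-face scute labels) or OBJ;
graphs as GraphML + CSV edge lists; tables as CSV; fits and the run
manifest as JSON.  Voxel convention: 0-based indices, world position of
voxel (i, j, k) = origin + (i+½, j+½, k+½)·spacing, all lengths in mm.

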