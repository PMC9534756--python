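# engulf3d

Volumetric quantification of glial engulfment of synaptic inputs in 3D
fluorescence microscopy.

Oligodendrocyte precursor cells (OPCs), microglia, and astrocytes remodel
neural circuits by engulfing presynaptic terminals. The standard way to
measure this is a volumetric engulfment assay: reconstruct a single glial
cell from its marker channel, mask a synaptic-marker channel with the cell
surface, segment the material retained inside, and report the **engulfment
index**

```
engulfment index = internalized target volume (µm³) / cell volume (µm³)
```

as a per-cell, dimensionless measure. `engulf3d` packages that assay — and
the companion analyses used alongside it — as deterministic, scriptable,
tested code for anyone quantifying glial–synapse interactions in confocal,
Airyscan, or two-photon z-stacks:

- **Cell reconstruction** (`engulf3d.reconstruct`) — threshold the marker
  channel, keep the 26-connected component traceable to the soma seed, and
  derive an anisotropic signed Euclidean distance field (negative inside,
  zero on boundary voxels, positive outside).
- **Engulfment assay** (`engulf3d.engulfment`) — internalized objects,
  engulfment index, and the spatial distribution of engulfment "loci"
  (single-linkage clusters within a 2 µm diameter: distance to soma,
  axis-aligned bounding box). The lysosome mask can stand in for the cell
  mask to quantify lysosome contents with the same code path.
- **Intact-synapse colocalization** (`engulf3d.colocalization`) — voxels
  where presynaptic and postsynaptic markers both exceed their channel
  means form synapse objects; a synapse counts as internalized when its
  centroid is more than 0.132 µm (one lateral pixel) inside the surface.
  Voxelwise Pearson correlation for reporter validation.
- **Digestion-reporter ratiometry** (`engulf3d.psyndig`) — a dual
  eGFP/mCherry presynaptic reporter whose green fluorophore quenches in
  acidic lysosomes: within- vs outside-lysosome green/red sum-intensity
  ratios (thresholds at 0.75 × channel mean) read out lysosomal
  processing.
- **Time-lapse input classification** (`engulf3d.timelapse`) — inputs are
  *noncontacting* (signed distance > 0), *contacting* (in [−270 nm, 0]),
  or *engulfed* (most-interior voxel < −270 nm); per-class mean volumes
  are normalized to the noncontacting baseline to cancel photobleaching.
- **FISH counting** (`engulf3d.fish`) — DAPI threshold → dilate →
  watershed ROIs, full-3D per-cell molecule counts, positivity at ≥ 5
  molecules.
- **ROUT outlier removal** (`engulf3d.robust`) — robust Lorentzian
  location fit, RSDR (68.27th percentile of |residuals|, small-sample
  corrected), and FDR-scheduled outermost-inward testing at Q = 1%;
  tidy per-cell tables ready for external ANOVA/t-tests.
- **Synthetic scenes** (`engulf3d.synthetic`) — a ground-truthed generator
  (ramified cell, class-placed puncta, lysosomes, quenched reporter,
  anisotropic voxels, PSF blur, Poisson + Gaussian noise, exponential
  bleaching, FISH fields) so every stage is testable without microscope
  data.

## Worked example

```python
from engulf3d import SceneSpec, generate_scene, reconstruct_cell, quantify_engulfment

spec = SceneSpec(rng_seed=42, puncta_counts={"inside": 5, "contacting": 4, "outside": 6})
channels, truth = generate_scene(spec)           # default SNR ≈ 10
roles = {c.channel_role: c for c in channels}

surface = reconstruct_cell(roles["cell"], soma_seed_um=truth.soma_center_um)
result = quantify_engulfment(surface, roles["presyn"])

print(f"cell volume        : {surface.volume_um3:8.1f} um^3")
print(f"internalized volume: {result.internalized_volume_um3:8.3f} um^3")
print(f"engulfment index   : {result.engulfment_index:.5f}")
print(f"objects / loci     : {result.n_objects} / {result.n_loci}")
print(f"locus bbox extent  : {tuple(round(e, 2) for e in result.loci_bbox_extent_um)} um")
```

prints

```
cell volume        :    194.3 um^3
internalized volume:    0.314 um^3
engulfment index   : 0.00161
objects / loci     : 9 / 7
locus bbox extent  : (3.05, 7.26, 9.26) um
```

The cell occupies 194 µm³ and contains 0.31 µm³ of presynaptic material —
an engulfment index of 0.0016, i.e. ~0.16% of the cell volume. Nine
objects are detected inside the mask: the five fully internal puncta plus
the interior portions of the four surface-contacting ones (the generator's
truth index for fully internal puncta alone is 0.00099). The objects group
into seven loci whose bounding box spans most of the arbor.

The same pipeline is available from the shell:

```bash
engulf3d simulate --spec spec.json --out scene/
engulf3d engulf --image scene/scene.ome.tif --cell-channel 0 --target-channel 1 --out results/
engulf3d classify --image scene/scene.ome.tif --cell-channel 0 --input-channel 1 --out classes/
engulf3d summarize --table per_cell.csv --rout-q 0.01 --out summary/
```

Every output directory contains `provenance.json` (parameters, thresholds,
version, seed); rerunning a seeded pipeline reproduces all artifacts
byte-for-byte.

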