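# somamorph

3D soma morphometry for invertebrate ganglia. Given an integer label
volume in which each voxel value identifies one neuronal cell body
(soma), `somamorph`:

1. **meshes** every soma (marching cubes, voxel-center convention) and
   measures its volume by the divergence theorem, cross-checked by exact
   voxel counts;
2. **derives the ganglionic surface** — the boundary a annotator would
   draw along the superficial cell bodies — as a smoothed (Taubin)
   mesh of the morphological closing of the cell-voxel union;
3. **classifies depth**: each soma's minimum distance *d* to that
   surface (nearest-neighbor search between meshes) splits the
   population at a threshold τ into *superficial* (*d* < τ) and
   *internalized* (*d* ≥ τ) neurons, with side (left/right of the
   midsagittal plane) and face (dorsal/ventral, from the local surface
   normal) attached;
4. **runs the nonparametric battery**: Mann–Whitney U (midranks, tie and
   continuity corrections, exact enumeration for small untied samples)
   and Spearman rank correlation, applied as left-vs-right,
   dorsal-vs-ventral, and superficial-vs-internalized volume
   comparisons plus the depth–volume correlation among internalized
   cells.

Because annotated ganglion volumes are large and rare, the package
includes a first-class **synthetic phantom generator**: a bilaterally
symmetric pair of ellipsoidal ganglia populated with non-overlapping
spherical somata whose statistics are planted — 542 + 557 cells, 526
internalized, lognormal volumes spanning >100-fold, a dorsal>ventral
volume effect, and a depth–volume Spearman correlation calibrated to
rs = −0.368. Every measurement can therefore be validated against known
ground truth.

Defaults mirror a segmented snail (*Lymnaea*) buccal ganglion pair:
τ = 8.125 µm, soma inclusion at equivalent diameter > 8 µm, neuritic
processes < ~2.5 µm stripped by morphological opening, voxel pitch
1.625 µm (2.5 µm on the fast "reduced" grid).

## Worked example

```python
from somamorph import RunConfig, SimConfig, run_pipeline

report = run_pipeline(RunConfig(sim=SimConfig.reduced(), seed=0))
for t in report.tests:
    print(t.label, round(t.statistic, 3), t.p_value)
```

prints (seed 0, coarse grid):

```
left_vs_right_volume 142487.5 0.1447...       # bilateral symmetry: no rejection
dorsal_vs_ventral_volume 17876.5 3.9e-06      # dorsal somata larger
superficial_vs_internalized_volume 78213.5 2.1e-42   # internal somata smaller
volume_vs_depth_internalized -0.392 2.3e-20   # smaller cells lie deeper
```

and `report.recovery` compares every measurement with the planted
truth: the 1,099 planted cells are recovered exactly, the measured
internalized fraction is 0.469 vs 0.479 planted, and the realized
depth–volume Spearman is −0.392 against −0.436 planted for that seed.

More narrative examples live in `examples/` (one script per
capability: phantom generation, surface + distances, the statistical
battery, mesh volumetry accuracy).

## Command line

A thin CLI wraps the same stages:

```bash
somamorph simulate --out vol.nrrd --seed 0 --reduced
somamorph surface vol.nrrd --out surface.ply
somamorph measure vol.nrrd surface.ply --out cells.csv
somamorph stats cells.csv --out report.json
somamorph run --outdir out/ --seed 0 --reduced   # all of the above
```

Volumes travel as NRRD (spacing in header) or multi-page TIFF with a
JSON spacing sidecar; meshes as PLY; tables as CSV; reports as JSON.

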