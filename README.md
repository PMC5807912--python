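# angioquant

Spatial quantification of angiogenesis from color-coded vessel annotations
of histologic cross sections.

## The problem

Implantation assays of angiogenesis (e.g. a biomaterial-filled silicone
tube sheathing a vascular pedicle) yield circular tissue cross sections
with a centric artery and vein. On high-resolution scans of such sections,
trained observers paint every vessel profile in a reserved color — central
artery **red**, central vein **blue**, every other vessel including de novo
capillaries **green**. `angioquant` turns these annotation rasters into a
quantitative, spatially resolved description of the vascular tree and
compares experimental groups statistically. It is aimed at labs running
implantation/ingrowth models who want more than a bare vessel count without
3-D imaging hardware.

## The method

For each sample, the tricolor raster is resampled to a 2,500 × 2,500 px
working grid (nearest-neighbor, so class colors are never blended), split
into per-class binary masks, and every 8-connected component becomes one
vessel mark with a moment-equivalent ellipse (centroid, area, major/minor
axis). Five read-out parameters follow:

1. **Total vessel count** `N` — capillary-class marks (central pair excluded);
2. **Total perfused area** `A = |⋃ᵢ (Mᵢ ⊕ B_r)|` — the single-counted union
   of all marks dilated by a disk of radius *r* = 150 µm, approximating the
   tissue volume reachable by oxygen diffusion (mm²);
3. **Perfused-area vessel density** `ρ = N / A` (vessels/mm²);
4. **Ingrowth distance** `dᵢ = ‖cᵢ − c_vein‖` — Euclidean distance of each
   mark's centroid to the central vein's centroid (µm), a proxy for
   penetration depth;
5. **Vessel diameter** — the minor axis of each mark's moment-equivalent
   ellipse (µm), wall included, robust to oblique sectioning.

Group comparison: per-group mean ± SEM, one-way ANOVA
(`F = MS_between/MS_within`, α = 0.05), and Duncan's multiple range post hoc
test with star-coded significance (`*`/`**`/`***` for p ≤ 0.05/0.01/0.001).
A synthetic-data module renders annotation images with exact ground truth
(configurable count, radial and diameter distributions), so every pipeline
stage is validated without real histology.

## Worked example

Generate a synthetic sample (120 capillaries around a centric vein/artery,
2,500 px at 2 µm/px) and analyze it:

```bash
cat > spec.yaml <<'EOF'
image_px: 2500
scale: 2.0
n_capillaries: 120
radial_distribution: [uniform, {low: 250.0, high: 2000.0}]
EOF
angioquant generate-synthetic --spec spec.yaml --n-samples 1 --seed 7 -o demo
angioquant analyze-sample demo/synthetic_000.png --scale 2.0 -o out
```

prints

```
sample           : synthetic_000
vessel count     : 120
perfused area    : 6.7897 mm^2
vessel density   : 17.67 vessels/mm^2
mean ingrowth    : 1228.3 um
mean diameter    : 15.5 um
```

All 120 painted capillaries were detected (the count never includes the
central artery/vein); their 150 µm dilation halos union to 6.79 mm² of
virtually perfused tissue, giving 17.7 vessels/mm²; the mean centroid
distance to the central vein is 1.23 mm and the median-15 µm log-normal
diameter distribution is recovered at 15.5 µm mean minor axis. Per-vessel
tables and per-sample metrics land in `out/` as CSV.

Multi-group studies run from a YAML config + manifest
(`angioquant analyze-study --config study.yaml`), emitting per-group
means ± SEM, ANOVA tables, Duncan stars, and normalized diameter/ingrowth
histograms (CSV + JSON). The same functionality is available as a library
(`angioquant.run_sample`, `angioquant.run_study`, …).

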