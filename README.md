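# biofilmdia

Quantification of cells and extracellular polymeric substances (EPS) in
drinking-water biofilms from confocal lambda-Z-stacks, together with the
microbial community-fingerprint statistics used alongside such imaging.

Biofilms on the inner walls of drinking-water pipes consist of microbial
cells embedded in an EPS matrix of carbohydrates and proteins. Triple
fluorophore staining with spectral (lambda-mode) confocal imaging records a
full binned emission spectrum at every pixel of every focal slice; linear
unmixing against per-fluorophore emission fingerprints then separates
cells, carbohydrates, proteins and surface autofluorescence in a single
sample. This package implements that analysis chain for people working on
biofilms in engineered water systems: microscopists quantifying stained
components in lambda-Z-stacks, and microbial ecologists analysing the
matching T-RFLP/ARISA community fingerprints.

## What it computes

**Imaging chain** (`quantify`): for each unmixed, median-filtered component
stack, coverage is computed for every detection threshold 1..4095 and a
threshold is chosen automatically on the plateau where a Kruskal–Wallis
test across thresholds (observations = replicate fields of view) finds no
difference. From the thresholded masks:

- *Volume* (µm³), relative to the detection threshold:
  `V = Δz · A · Σᵢ cᵢ`, where `Δz` is the depth step (default 2.35 µm, half
  the 4.7 µm optical section), `A` the field area (420 µm × 420 µm by
  default) and `cᵢ` the area-coverage fraction of slice *i*.
- *Spread* (µm), a thickness proxy independent of the coverage level and
  therefore robust to an uneven substratum:
  `S = V / (c_peak · A)`.
- *Peak location*: the slice of maximum coverage after aligning all
  components to the cell peak (cells = 0, negative toward the bulk water).
- Composition ratios (EPS:cells, carbohydrate:protein, ...) formed per
  field of view and summarised by median and range, plus rank-based group
  comparisons (Wilcoxon W) and VTK/PNG overlays for 3-D rendering.

**Fingerprint chain** (`fingerprint`): peak-height noise filter
(> 50 fluorescence units), fragment-size windows (50–500 nt T-RF,
94–827 nt ARISA), alignment into consensus bins at a 0.5 nt confidence
interval, relative abundance with a < 0.5 % exclusion rule, square-root
transform, Bray–Curtis similarities (%), richness / Shannon H′ / Pielou J′,
ANOSIM, SIMPER and SIMPROF-flagged group-average clustering, plus Local
Southern fragment sizing.

A seeded synthetic-data module generates 12-bit lambda stacks (10.7 nm
bins, 2.35 µm slice interval, uneven 20–80 µm substratum, EPS stratified
above the cells) and group-structured fingerprint datasets with exact voxel
and fragment truth, so the whole pipeline is testable without any imaging
data.

## Worked example

Simulate three fields of view and quantify them:

```sh
biofilmdia simulate stack --seed 7 --n-fov 3 --image-px 128 --out sim
biofilmdia quantify --stacks sim --fingerprints sim --out quant
```

which prints

```
quantified 3 stack(s); thresholds: {'carbohydrates': 1582, 'cells': 1597,
'proteins': 1617}; tables in quant
```

`quant/metrics.csv` then holds one row per field of view and component:

```
fov,component,threshold,volume_um3,spread_um,peak_location,area_coverage_peak
fov1,carbohydrates,1582,1552146.66,18.04,-1,0.4878
fov1,cells,1597,1033541.53,22.50,0,0.2604
fov1,proteins,1617,246360.84,14.45,-3,0.0966
...
```

The cell volume of 1.034 × 10⁶ µm³ is within 0.3 % of the generator's exact
voxel truth (1.036 × 10⁶ µm³, `sim/truth.csv`); the carbohydrate and
protein coverage peaks sit 1 and 3 slices above the cell peak — exactly the
stratification the scene was built with. `quant/ratio_summary.csv` reports
the per-FOV median composition ratios (here EPS:cells 1.74,
carbohydrate:protein 6.31).

For the fingerprint side:

```sh
biofilmdia simulate fingerprints --seed 7 --out fpsim
biofilmdia fingerprint --peaks fpsim/peaks.tsv --groups fpsim/groups.csv --out fpout
```

prints `ANOSIM: R = 1.000, p = 0.0002` for the two simulated communities,
and writes the community matrix, similarity matrix, diversity indices,
SIMPER table and a Newick dendrogram whose nodes carry
`[&simprof=significant|homogeneous]` flags.

`biofilmdia report --quantify-dir quant --out dist.png` renders the aligned
area-distribution plot (one panel per component, depth axis centred on the
cell peak).

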