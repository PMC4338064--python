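# Methods

This note records the models, conventions, parameter defaults and numerical
choices behind `biofilmdia`, and what the synthetic test bed does and does
not establish about real data.

## Lambda-Z-stacks and emission fingerprints

A lambda-Z-stack is a 4-D array `(z, λ, y, x)` of 12-bit intensities
(0–4095): at every pixel of every focal slice the emission spectrum is
recorded in equally wide wavelength bins. The geometry travels with the
data: slice interval (default 2.35 µm), optical section depth (4.7 µm;
the slice interval is half of it, so adjacent optical sections overlap at
Nyquist spacing), pixel pitch, field size (420 µm × 420 µm at 832 × 832 px
by default) and — declared, never inferred — which end of the z axis faces
the bulk water. Reading a TIFF without complete geometry raises; the CLI
can fall back on configured values, but logs that fall-back loudly.

An emission fingerprint is one endmember spectrum per stained component
(cells, carbohydrates, proteins) plus at most one autofluorescence spectrum
measured on unstained controls. Replicate fingerprints are condensed to a
single representative by the **medoid** after unit-sum normalisation: the
member spectrum minimising the summed Euclidean distance to all others,
ties broken by input order. A pointwise-median mode exists behind a flag,
but a pointwise median can produce a spectrum no replicate ever exhibited,
so the medoid is the default.

## Linear unmixing

Each voxel's spectrum is modelled as a non-negative combination of the
endmembers, solved by non-negative least squares; abundances are physical
stain concentrations, so the non-negativity constraint is the default and
an unconstrained mode exists only for comparison. The autofluorescence
coefficient is always estimated when a control spectrum is supplied but is
excluded from all biofilm metrics. The whole recorded spectral range is
used; no band selection.

The stack solver enumerates all candidate active sets (libraries have at
most a handful of endmembers), solves each restricted least-squares problem
vectorised over every voxel, and keeps the feasible solution with the
smallest residual. At the NNLS optimum the unconstrained solution on the
optimal support is feasible and attains the minimum, so this reproduces
`scipy.optimize.nnls` exactly (the test suite checks this voxel by voxel)
while remaining a few matrix products per support. A per-voxel RMS residual
map is returned as a fit diagnostic.

## Digital image analysis

*Median filter.* A 3 × 3 median is applied to every z-slice independently
(nearest-value edge replication) before any thresholding or quantification,
to suppress far-red shot noise while preserving edges.

*Quantisation.* Unmixed float abundances are rescaled to 0..4095 integers
so the canonical 1..4095 threshold domain applies verbatim. When several
fields of view are thresholded jointly, one shared scale per component
(4095 / ensemble maximum) is used and logged.

*Threshold selection.* Coverage (stain-positive pixels / total pixels) is
computed exactly for all 4095 thresholds from per-slice cumulative
histograms. Each FOV's total-coverage curve is normalised by its own
maximum; candidate thresholds are those with mean normalised coverage
strictly between 0 and 1. Within each contiguous candidate run (subsampled
every `step` = 10 thresholds) a two-pointer search finds the longest window
in which a Kruskal–Wallis test across thresholds (groups = thresholds,
observations = per-FOV normalised coverages) fails to reject at α = 0.05;
the median threshold of the longest plateau is returned. Degenerate
all-identical windows count as "no difference" by construction. If no
plateau spans at least `min_window` = 10 thresholds the selection refuses
and asks for manual review. All three knobs (α, window, step) are config
keys: the window construction is one defensible reading of a procedure that
is usually described only graphically.

*Volume.* `V = Δz · A · Σ cᵢ` with Δz the depth step and A the field area.
The default Δz is the 2.35 µm acquisition interval, not the 4.7 µm optical
section: with half-overlapping optical sections, using the full section
depth would double-count signal. Both Δz and A are explicit config keys, so
the literal optical-section reading is one setting away. Volumes are always
relative to the detection threshold. Per FOV, EPS = carbohydrates +
proteins and total = EPS + cells are summed **before** any averaging, and
composition ratios are formed per FOV and then summarised by median and
range — a median of ratios, never a ratio of medians.

*Alignment and peak location.* Stack limits are investigator-selected and
differ between FOVs, so profiles are aligned by labelling the slice of
maximum cell coverage as 0, negative indices toward the bulk water and
positive toward the substratum. Cells are the anchor because they produce
the EPS. Peak-location ties break toward the substratum (attached cells
seed growth at the wall). The depth axis of the area-distribution plots
uses 4.7 µm per slice by default (configurable), independent of the Δz used
for volume.

*Spread.* `S = V / (c_peak · A)` is the thickness proxy: for a uniform
k-slice profile it equals Δz · k at any coverage level, which is exactly
why it is insensitive to the low coverage fractions an uneven substratum
produces at the biofilm–plastic border. This invariance is enforced by a
property test under substratum randomisation.

*Group statistics.* Volume, spread and peak location are typically
non-normal, so comparisons are rank-based: a Shapiro–Wilk screen is
reported, then a two-sample Wilcoxon rank-sum test (W = Mann–Whitney U of
the first group, matching R's `wilcox.test`) or Kruskal–Wallis for more
than two groups, always alongside medians and ranges.

*Overlays.* Thresholded masks are exported as a legacy-ASCII VTK
structured-points volume (one scalar per component, co-localisation
preserved; colours documented at 50 % opacity in the header) plus optional
per-slice RGB PNGs.

## Community fingerprints

Peaks below or at 50 fluorescence units are noise-filtered (strictly
greater survives); size windows are 50–500 nt (T-RF) and 94–827 nt (ARISA),
inclusive. Alignment is a two-pass consensus binning at a 0.5 nt confidence
interval: peaks within a sample closer than 0.5 nt merge (areas summed),
then all peaks are processed in ascending size and join an existing bin iff
their size is within 0.5 nt of the bin's running-mean consensus. Processing
order is fixed to ascending size for determinism; the original web tool's
tie behaviour is unknowable. Relative abundance is peak-AREA based; heights
are carried but only used by the noise filter.

After conversion to within-sample relative abundance, entries contributing
strictly less than 0.5 % are zeroed and rows re-normalised ("exclude" is
read as exclusion-then-renormalisation; a flag skips the renormalisation).
Similarities are Bray–Curtis on square-root-transformed abundances,
expressed in percent. Diversity: richness S, Shannon H′ (natural log),
Pielou J′ = H′/ln S (flagged undefined at S = 1).

**ANOSIM** follows Clarke: R = (mean between-group dissimilarity rank −
mean within-group rank) / (n(n−1)/4), p by seeded label permutation
(default 9,999; the observed labelling counts as one permutation), with an
exhaustive mode for tiny designs. **SIMPER** averages each fragment bin's
term of the Bray–Curtis dissimilarity over all between-group pairs;
contributions sum to the average between-group dissimilarity by
construction, and within-group average similarity is reported per group.
**SIMPROF** tests a node's samples for multivariate structure: the π
statistic is the summed departure of the ordered similarity profile from
the mean profile of datasets obtained by permuting each bin independently
across samples; half the permutation budget (default 20,000) builds the
expected profile, half the null distribution. Clustering is group-average
(UPGMA, the PRIMER-E convention; the linkage is not usually named) on
Bray–Curtis dissimilarity, tested top-down from the root; subtrees whose
test fails to reject are flagged homogeneous in the exported Newick.

Calibration caveat: the SIMPROF permutation null assumes bins are
independently exchangeable across samples. On row-normalised
(relative-abundance) data that assumption is mildly violated even without
group structure, and the test becomes somewhat liberal (empirically ~0.11–
0.14 at nominal 0.05 on unstructured compositional data). The calibration
checks therefore generate exchangeable-bin null data, where the
implementation is exact (~0.045); on compositional data SIMPROF flags
should be read as a screening device, as they are in standard practice.

**Welch t-tests** (unequal variances, fractional Welch–Satterthwaite df)
compare diversity indices between groups. **Local Southern** sizing fits
the reciprocal mobility model `L = c/(m − m₀) + L₀` exactly through each of
the two overlapping flanking triplets of size standards (the three-point
fit reduces to a linear equation in m₀) and averages the two fitted sizes;
queries not bracketed by at least four standards raise.

## Synthetic data

The scene generator is the package's ground-truth test bed. Defaults are
the acquisition conditions the package targets: 420 µm square field at
832 × 832 px, 2.35/4.7 µm axial geometry, 20 spectral bins of 10.7 nm over
490.2–704.2 nm, 12-bit depth. Endmembers are synthetic Gaussians at the
fluorophores' emission maxima (cells 668 nm, carbohydrates 580 nm, proteins
520 nm, σ ≈ 20 nm) plus a broad autofluorescence (560 nm, σ 80 nm) at 15 %
of the component gain — self-contained and with controllable overlap,
rather than digitised instrument curves.

The substratum is band-limited Gaussian noise rescaled to an exact
peak-to-trough amplitude (default 40 µm within the supported 0–80 µm
range), with a configurable fraction (default 35 %) of the field at the
nominal plane — indentation-style roughness, which also keeps the coverage
argmax well defined for every component. Components occupy five-slice
bands above the local substratum with ±20 % lateral amplitude jitter:
cells four slices above the surface at 50 % lateral coverage, carbohydrates
one slice higher at 75 %, proteins three slices higher at 12 % — EPS
stratified above the cells, carbohydrate-dominant by volume
(carbohydrates > cells > proteins). Noise is Poisson shot noise on the
clean signal plus Gaussian read noise (σ = 8 counts). Truth (masks,
voxel-count volumes, peak offsets, substratum map) is recorded before
noise; every generator is a pure function of (params, seed).

What the scene does **not** emulate: continuous intensity gradients within
a component, scattering and depth-dependent attenuation, chromatic
aberration, stain cross-reactivity, or fluorophore bleed-through beyond
spectral overlap. Passing the recovery tests therefore shows the chain is
correct and self-consistent, not that any particular real biofilm will be
recovered within the same error.

The fingerprint generator produces two groups of nine samples (defaults),
~20 true fragments per group (five shared), lognormal abundances with
30 % replicate noise, 0.1 nt size jitter (warned about if it reaches half
the alignment tolerance) and sub-cutoff baseline peaks; real peaks are
always above the 50-unit cutoff, noise peaks always below, so expected
richness is exact.

The hydraulics helper computes the pipe Reynolds number Re = 4Q/(πDν);
with the facility defaults (0.4 l/s, 79.3 mm, ν = 1.11×10⁻⁶ m²/s at 16 °C
from standard water tables) it gives ≈ 5.79×10³. The facility's quoted wall
shear stress (0.30 N m⁻²) is about an order of magnitude above a
smooth-pipe Blasius estimate at these parameters and is deliberately not
used as an oracle; the closure behind that figure is not derivable from the
stated quantities.

## Problem sizes and numerics

Tests and `scripts/acceptance.py` run the scene generator at a reduced
field (96–208 px, 28 slices, 20 bins; substratum and lateral correlation
lengths scaled accordingly) — the package's chosen test-bed size; the
full-field defaults run identically but are unnecessary for verifying
correctness. Threshold search subsamples every 10th threshold. Permutation
counts are reduced in calibration loops (999–1,000) while production
defaults stay at 9,999 (ANOSIM) and 20,000 (SIMPROF). Quantisation rounds
half away from the midpoint via `np.rint`; NNLS feasibility uses a 1e-10
tolerance and support comparison a 1e-12 residual margin. Kruskal–Wallis on
fully degenerate windows is defined as "no difference" (p = 1) rather than
propagating scipy's 0/0 artefacts.

## Known limitations

- Volumes are relative to the detection threshold, not absolute biomass;
  comparisons are only meaningful at matched thresholds and stains.
- The threshold-plateau construction is one reading of a graphically
  described procedure; very steep coverage curves can legitimately fail to
  produce a plateau, which raises for manual review rather than guessing.
- SIMPROF on compositional data is mildly liberal (above).
- The exhaustive-support NNLS is exponential in the number of endmembers;
  it is intended for the 3–5 endmember libraries of triple-stain work.
- Fingerprint alignment assumes fragments are separated by more than the
  0.5 nt confidence interval; closer true fragments merge, as in the
  original tools.
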