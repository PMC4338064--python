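"""Seeded synthetic-data generators with exact ground truth.

The scene generator emulates the acquisition this package is built for:
12-bit lambda-Z-stacks (10.7 nm spectral bins, 4.7 um optical sections at
2.35 um intervals, 420 um square fields at 832 x 832 px) of a biofilm on an
uneven HDPE substratum (20-80 um relief), with cells, carbohydrates and
proteins stratified so the EPS components peak above the cells (carbohydrate
by 1 slice, protein by 3) and carbohydrate dominating the composition.
Endmember spectra are synthetic Gaussians at the fluorophores' emission
maxima (cells 668 nm, carbohydrates 580 nm, proteins 520 nm) plus a broad
autofluorescence; noise is Poisson shot noise plus Gaussian read noise.

Every generator is a pure function of (params, seed); truth volumes are
exact voxel counts times the voxel volume, recorded before noise.

A fingerprint-dataset generator and a facility-hydraulics helper (pipe
Reynolds number) complete the test bed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError
from .fingerprint import ALIGN_TOLERANCE_NT, FingerprintProfile, SIZE_WINDOWS
from .lambda_stack import (MAX_INTENSITY, LambdaZStack, StackGeometry,
                           lambda_bin_centres)


# ---------------------------------------------------------------------------
# substratum


def generate_substratum(shape, amplitude_um: float = 40.0,
                        correlation_length_px: float = 20.0,
                        seed: int | None = None) -> np.ndarray:
    """Smooth random surface height map (um) with an exact peak-to-trough
    amplitude.

    Band-limited noise (Gaussian-filtered white noise) rescaled so that
    max - min equals ``amplitude_um`` exactly; amplitude 0 gives a flat
    surface.  Deterministic for a given seed.
    """
    if not 0 <= amplitude_um <= 80:
        raise DataError("relief amplitude outside the supported 0-80 um range")
    ny, nx = shape
    if amplitude_um == 0:
        return np.zeros((ny, nx))
    rng = np.random.default_rng(seed)
    h = ndimage.gaussian_filter(rng.standard_normal((ny, nx)),
                                sigma=correlation_length_px, mode="wrap")
    h = h - h.min()
    return h * (amplitude_um / h.max())


# ---------------------------------------------------------------------------
# lambda-stack scene


@dataclass(frozen=True)
class ComponentSpec:
    """One component of the synthetic scene.

    ``peak_offset_slices`` is relative to the cell band centre; negative
    offsets lie toward the bulk water.  The component occupies a band of
    ``2 * band_halfwidth + 1`` slices above the local substratum wherever its
    lateral presence field is set.
    """

    coverage: float               # lateral fraction of the field occupied
    amplitude: float              # abundance level (arbitrary units)
    peak_offset_slices: int = 0
    band_halfwidth: int = 2
    emission_max_nm: float = 668.0
    emission_sd_nm: float = 20.0
    lateral_mode: str = "random"  # random | square (central block)


DEFAULT_COMPONENTS = {
    "cells": ComponentSpec(coverage=0.50, amplitude=1.0, peak_offset_slices=0,
                           emission_max_nm=668.0),
    "carbohydrates": ComponentSpec(coverage=0.75, amplitude=1.2,
                                   peak_offset_slices=-1, emission_max_nm=580.0),
    "proteins": ComponentSpec(coverage=0.12, amplitude=0.9,
                              peak_offset_slices=-3, emission_max_nm=520.0),
}


@dataclass(frozen=True)
class BiofilmSceneParams:
    """Scene parameters; the defaults are the acquisition conditions the
    package targets (420 um square field at 832 x 832 px, 2.35 um slice
    interval, 4.7 um optical sections, 10.7 nm bins over 490.2-704.2 nm)."""

    image_px: int = 832
    field_um: float = 420.0
    n_slices: int = 28
    slice_interval_um: float = 2.35
    optical_slice_um: float = 4.7
    lambda_lo_nm: float = 490.2
    lambda_hi_nm: float = 704.2
    n_bins: int = 20
    components: dict = field(default_factory=lambda: dict(DEFAULT_COMPONENTS))
    autofluorescence_level: float = 0.15
    autofluorescence_max_nm: float = 560.0
    autofluorescence_sd_nm: float = 80.0
    substratum_amplitude_um: float = 40.0
    substratum_correlation_px: float = 20.0
    substratum_flat_fraction: float = 0.35  # field fraction at the nominal plane
    lateral_correlation_px: float = 12.0    # patch size of component coverage
    cell_clearance_slices: int = 4     # cell band centre above the surface
    gain: float = 2400.0               # abundance unit -> detector counts
    noise: bool = True
    read_noise_sd: float = 8.0
    amplitude_jitter: float = 0.2      # lateral amplitude variation +-20%


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth of one generated field of view."""

    masks: dict                    # component -> bool (z, y, x), water side first
    volumes_um3: dict
    abundances: dict               # noiseless abundance fields
    peak_offsets: dict             # component -> slices relative to cells
    substratum_um: np.ndarray
    params: BiofilmSceneParams
    seed: int | None


def gaussian_spectrum(centres_nm, max_nm: float, sd_nm: float) -> np.ndarray:
    c = np.asarray(centres_nm, dtype=float)
    return np.exp(-0.5 * ((c - max_nm) / sd_nm) ** 2)


def _lateral_field(spec: ComponentSpec, shape, rng,
                   correlation_px: float = 12.0) -> np.ndarray:
    """Boolean lateral presence map at the requested coverage."""
    ny, nx = shape
    if spec.lateral_mode == "square":
        side_y = max(int(round(ny * math.sqrt(spec.coverage))), 1)
        side_x = max(int(round(nx * math.sqrt(spec.coverage))), 1)
        presence = np.zeros((ny, nx), dtype=bool)
        y0, x0 = (ny - side_y) // 2, (nx - side_x) // 2
        presence[y0:y0 + side_y, x0:x0 + side_x] = True
    elif spec.lateral_mode == "random":
        f = ndimage.gaussian_filter(rng.standard_normal((ny, nx)),
                                    sigma=correlation_px, mode="wrap")
        presence = f >= np.quantile(f, 1 - spec.coverage)
    else:
        raise DataError(f"unknown lateral_mode {spec.lateral_mode!r}")
    return presence


def generate_biofilm_stack(params: BiofilmSceneParams | None = None,
                           seed: int | None = None
                           ) -> tuple[LambdaZStack, SceneTruth]:
    """Assemble a 12-bit lambda stack from component abundance bands over a
    rough substratum, plus noise; the truth is recorded before noise.

    z index 0 is the bulk-water side.  Each component's true mask is the
    support of its noiseless abundance band; truth volumes are exact voxel
    counts times the voxel volume.
    """
    p = params or BiofilmSceneParams()
    rng = np.random.default_rng(seed)
    n = p.image_px
    nz = p.n_slices
    pixel_um = p.field_um / n
    centres, width = lambda_bin_centres(p.lambda_lo_nm, p.lambda_hi_nm, p.n_bins)

    substratum = generate_substratum((n, n), p.substratum_amplitude_um,
                                     p.substratum_correlation_px,
                                     seed=rng.integers(2**31))
    if p.substratum_flat_fraction > 0 and p.substratum_amplitude_um > 0:
        # HDPE-style relief: indentations below a nominal machined plane --
        # a fraction of the field sits at zero relief, the rest falls away
        # smoothly to the full amplitude
        u = substratum / p.substratum_amplitude_um
        q = np.quantile(u, p.substratum_flat_fraction)
        if q < 1.0:
            substratum = (p.substratum_amplitude_um
                          * np.maximum(0.0, (u - q) / (u.max() - q)))
    # surface slice index (water side first: higher relief -> smaller index)
    surf = (nz - 1 - np.rint(substratum / p.slice_interval_um)).astype(int)
    cell_centre = surf - p.cell_clearance_slices

    max_half = max(s.band_halfwidth for s in p.components.values())
    min_off = min((s.peak_offset_slices for s in p.components.values()), default=0)
    if (cell_centre.min() + min_off - max_half < 0
            or cell_centre.max() + max_half >= nz):
        raise DataError("infeasible geometry: component bands leave the stack; "
                        "increase n_slices or reduce relief/clearance")

    zidx = np.arange(nz)[:, None, None]
    abundances, masks, volumes = {}, {}, {}
    voxel_um3 = pixel_um * pixel_um * p.slice_interval_um
    for cid, spec in p.components.items():
        presence = _lateral_field(spec, (n, n), rng,
                                  correlation_px=p.lateral_correlation_px)
        centre = cell_centre + spec.peak_offset_slices
        band = np.abs(zidx - centre[None]) <= spec.band_halfwidth
        mask = band & presence[None]
        amp_map = spec.amplitude * (1.0 + p.amplitude_jitter
                                    * (2.0 * rng.random((n, n)) - 1.0))
        abundances[cid] = (mask * amp_map[None]).astype(np.float32)
        masks[cid] = mask
        volumes[cid] = float(np.count_nonzero(mask)) * voxel_um3

    spectra = {cid: gaussian_spectrum(centres, s.emission_max_nm, s.emission_sd_nm)
               for cid, s in p.components.items()}
    af_spec = gaussian_spectrum(centres, p.autofluorescence_max_nm,
                                p.autofluorescence_sd_nm)

    # assembled slice by slice to bound peak memory at full field size
    data = np.empty((nz, p.n_bins, n, n), dtype=np.uint16)
    af_slice = (p.autofluorescence_level * p.gain
                * af_spec)[:, None, None] * np.ones((1, n, n), dtype=np.float32)
    for iz in range(nz):
        clean = af_slice.copy()
        for cid, ab in abundances.items():
            clean += ab[iz][None] * (p.gain * spectra[cid]
                                     ).astype(np.float32)[:, None, None]
        if p.noise:
            noisy = rng.poisson(clean).astype(np.float32)
            noisy += rng.normal(0.0, p.read_noise_sd,
                                size=noisy.shape).astype(np.float32)
            data[iz] = np.clip(np.rint(noisy), 0, MAX_INTENSITY).astype(np.uint16)
        else:
            data[iz] = np.clip(np.rint(clean), 0, MAX_INTENSITY).astype(np.uint16)

    geom = StackGeometry(slice_interval_um=p.slice_interval_um,
                         optical_slice_um=p.optical_slice_um,
                         pixel_size_um=pixel_um,
                         field_width_um=p.field_um, field_height_um=p.field_um,
                         water_side="first")
    stack = LambdaZStack(intensities=data, geometry=geom,
                         lambda_bin_centres_nm=centres,
                         lambda_bin_width_nm=width)
    truth = SceneTruth(masks=masks, volumes_um3=volumes, abundances=abundances,
                       peak_offsets={cid: s.peak_offset_slices
                                     for cid, s in p.components.items()},
                       substratum_um=substratum, params=p, seed=seed)
    return stack, truth


def scene_spectra(params: BiofilmSceneParams | None = None) -> dict:
    """The generator's endmember spectra (including autofluorescence) on the
    scene's lambda bins, as plain arrays keyed by component id."""
    p = params or BiofilmSceneParams()
    centres, _ = lambda_bin_centres(p.lambda_lo_nm, p.lambda_hi_nm, p.n_bins)
    out = {cid: gaussian_spectrum(centres, s.emission_max_nm, s.emission_sd_nm)
           for cid, s in p.components.items()}
    out["autofluorescence"] = gaussian_spectrum(
        centres, p.autofluorescence_max_nm, p.autofluorescence_sd_nm)
    return out


def small_scene_params(image_px: int = 208, n_slices: int = 28,
                       **overrides) -> BiofilmSceneParams:
    """The default scene at a reduced field size (same physical pixel pitch
    scaled to the field): the problem size used by the test-bed."""
    return replace(BiofilmSceneParams(), image_px=image_px, n_slices=n_slices,
                   substratum_correlation_px=8.0, lateral_correlation_px=4.0,
                   **overrides)


# ---------------------------------------------------------------------------
# fingerprint dataset


@dataclass(frozen=True)
class FingerprintParams:
    """Group-structured fragment-profile generator settings.

    Defaults mirror a two-condition study with nine replicate samples per
    condition, ~20 true fragments per group of which a few are shared,
    lognormal abundances, < 0.25 nt size jitter, and sub-cutoff baseline
    noise peaks.
    """

    n_groups: int = 2
    samples_per_group: int = 9
    n_shared_fragments: int = 5
    n_unique_fragments: int = 15
    marker: str = "T-RF"
    abundance_sigma: float = 1.0    # lognormal sigma of true abundances
    replicate_sigma: float = 0.3    # per-sample multiplicative noise
    size_jitter_sd_nt: float = 0.1
    n_noise_peaks: int = 10         # baseline peaks below the height cutoff
    total_area: float = 1e5
    min_fragment_separation_nt: float = 2.0


def generate_fingerprint_dataset(params: FingerprintParams | None = None,
                                 seed: int | None = None) -> tuple[list, dict]:
    """Peak tables with known group structure.

    Returns (profiles, truth).  ``truth`` records the true fragment sizes per
    group and per sample, true abundances, and the generator parameters, so
    richness and group separation are known exactly.  Real peaks always have
    heights > 50 units; baseline noise peaks always <= 50 and are removed by
    the standard filter.
    """
    p = params or FingerprintParams()
    if p.size_jitter_sd_nt >= ALIGN_TOLERANCE_NT / 2:
        warnings.warn("size jitter sd >= half the alignment tolerance; "
                      "bins may merge")
    rng = np.random.default_rng(seed)
    lo, hi = SIZE_WINDOWS[p.marker]
    n_frag_total = p.n_shared_fragments + p.n_groups * p.n_unique_fragments
    grid = np.arange(lo + 1, hi - 1, p.min_fragment_separation_nt)
    if grid.size < n_frag_total:
        raise DataError("size window too small for the requested fragments")
    sizes = rng.choice(grid, size=n_frag_total, replace=False)
    shared = sizes[:p.n_shared_fragments]
    uniques = sizes[p.n_shared_fragments:].reshape(p.n_groups,
                                                   p.n_unique_fragments)

    profiles, truth_samples = [], {}
    group_sizes = {}
    for g in range(p.n_groups):
        gname = f"group{g + 1}"
        gsizes = np.sort(np.concatenate([shared, uniques[g]]))
        group_sizes[gname] = gsizes
        gabund = rng.lognormal(0.0, p.abundance_sigma, size=gsizes.size)
        gabund /= gabund.sum()
        for s in range(p.samples_per_group):
            sid = f"{gname}_s{s + 1}"
            areas = (p.total_area * gabund
                     * rng.lognormal(0.0, p.replicate_sigma, size=gsizes.size))
            jitter = rng.normal(0.0, p.size_jitter_sd_nt, size=gsizes.size) \
                if p.size_jitter_sd_nt > 0 else 0.0
            heights = 60.0 + 2000.0 * areas / areas.max()
            peaks = pd.DataFrame({"size_nt": gsizes + jitter,
                                  "height": heights, "area": areas})
            if p.n_noise_peaks:
                noise = pd.DataFrame({
                    "size_nt": rng.uniform(lo, hi, size=p.n_noise_peaks),
                    "height": rng.uniform(5.0, 49.0, size=p.n_noise_peaks),
                    "area": rng.uniform(1.0, 20.0, size=p.n_noise_peaks),
                })
                peaks = pd.concat([peaks, noise], ignore_index=True)
            profiles.append(FingerprintProfile(sample_id=sid, peaks=peaks,
                                               marker=p.marker))
            truth_samples[sid] = {"group": gname, "true_sizes": gsizes,
                                  "true_areas": areas}
    truth = {"group_sizes": group_sizes, "samples": truth_samples,
             "labels": [truth_samples[pr.sample_id]["group"] for pr in profiles],
             "params": p, "seed": seed}
    return profiles, truth


# ---------------------------------------------------------------------------
# facility hydraulics


@dataclass(frozen=True)
class FlowConfig:
    """Pipe-loop flow settings; defaults are the facility's steady state
    (0.4 l/s in a 79.3 mm HDPE pipe at 16 C; water kinematic viscosity
    1.11e-6 m^2/s from standard tables)."""

    flow_rate_l_s: float = 0.4
    internal_diameter_mm: float = 79.3
    temperature_c: float = 16.0
    kinematic_viscosity_m2_s: float = 1.11e-6

    def __post_init__(self):
        for name in ("flow_rate_l_s", "internal_diameter_mm",
                     "kinematic_viscosity_m2_s"):
            if getattr(self, name) <= 0:
                raise DataError(f"{name} must be strictly positive")


def reynolds_number(cfg: FlowConfig | None = None) -> float:
    """Pipe Reynolds number Re = 4 Q / (pi D nu), units handled internally."""
    c = cfg or FlowConfig()
    q = c.flow_rate_l_s / 1000.0          # m^3/s
    d = c.internal_diameter_mm / 1000.0   # m
    return 4.0 * q / (math.pi * d * c.kinematic_viscosity_m2_s)
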