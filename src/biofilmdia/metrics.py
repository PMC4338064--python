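"""Digital image analysis of unmixed biofilm component stacks.

Pipeline: 3x3 per-slice median filtering -> quantisation of float abundances
back onto the 12-bit threshold domain -> exhaustive coverage-vs-threshold
curves -> automated threshold selection on the Kruskal-Wallis-stable plateau
-> stain-positive masks -> per-slice area-coverage profiles aligned to the
cell peak -> volume, spread, peak location, composition ratios -> group
statistics and 3-D overlay export.

Conventions
-----------
* Profiles are stored water-side first: slice index 0 is the bulk-water end
  regardless of acquisition order (``StackGeometry.water_side``).
* Volume = depth_step_um x image_area_um2 x sum over slices of the area
  coverage fraction.  The default depth step is the 2.35 um acquisition
  interval (half the 4.7 um optical section, so overlapping sections are not
  double-counted) and the default area is the full field.  Volumes are
  relative to the detection threshold.
* Spread = volume / (peak coverage x image area): a thickness proxy that is
  exactly depth_step x k for any uniform k-slice profile, independent of the
  coverage level, hence robust to uneven substrata.
* Aligned slice indices: cell peak = 0, negative toward the bulk water,
  positive toward the substratum; peak-location ties break toward the
  substratum (attached cells seed growth at the wall).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .errors import DataError, PlateauNotFoundError
from .lambda_stack import MAX_INTENSITY, StackGeometry
from .unmixing import ComponentZStack

DEFAULT_DEPTH_STEP_UM = 2.35   # acquisition interval (optical slice / 2)
PLOT_DEPTH_STEP_UM = 4.7       # optical-slice step used for depth axes


# ---------------------------------------------------------------------------
# filtering, quantisation, coverage


def median_filter_stack(component: ComponentZStack) -> ComponentZStack:
    """3x3 median filter applied to each z slice independently; edges use
    nearest-value replication."""
    filtered = ndimage.median_filter(component.abundances, size=(1, 3, 3),
                                     mode="nearest")
    return replace(component, abundances=filtered)


@dataclass(frozen=True)
class QuantisedZStack:
    """Component abundances mapped onto the integer 0..4095 threshold domain.

    ``scale`` is the multiplicative factor applied before rounding; it is
    recorded so the mapping is reproducible and loggable.
    """

    component_id: str
    values: np.ndarray
    scale: float
    geometry: StackGeometry


def quantise_to_12bit(component: ComponentZStack,
                      scale: float | None = None) -> QuantisedZStack:
    """Rescale float abundances to 0..4095 integers so the 1..4095 threshold
    domain applies verbatim.

    If ``scale`` is not given it is ``4095 / max`` for this stack; pass a
    shared scale when thresholding an ensemble of FOVs jointly.
    """
    a = component.abundances
    if scale is None:
        amax = a.max()
        if amax <= 0:
            scale = 1.0
        else:
            scale = MAX_INTENSITY / amax
    vals = np.clip(np.rint(a * scale), 0, MAX_INTENSITY).astype(np.uint16)
    return QuantisedZStack(component_id=component.component_id, values=vals,
                           scale=float(scale), geometry=component.geometry)


@dataclass(frozen=True)
class BinaryZStack:
    """Stain-positive mask: voxels with quantised abundance >= threshold."""

    component_id: str
    mask: np.ndarray
    threshold_value: int
    geometry: StackGeometry


def area_coverage(mask_slice: np.ndarray) -> float:
    """Stain-positive pixels divided by total pixels of one slice."""
    m = np.asarray(mask_slice)
    return float(np.count_nonzero(m)) / m.size


def coverage_vs_threshold(quantised: QuantisedZStack) -> np.ndarray:
    """Exact per-slice coverage for every threshold 1..4095.

    Returns an array of shape (4095, n_slices): row t-1 holds the fraction
    of pixels with value >= t in each slice, computed from cumulative
    histograms rather than 4095 full passes.  Coverage is non-increasing in
    the threshold; threshold 1 labels every pixel >= 1 positive.
    """
    z = quantised.values.shape[0]
    npix = quantised.values.shape[1] * quantised.values.shape[2]
    out = np.empty((MAX_INTENSITY, z))
    for i in range(z):
        counts = np.bincount(quantised.values[i].ravel(),
                             minlength=MAX_INTENSITY + 1)
        n_ge = npix - np.cumsum(counts)        # n_ge[v] = # pixels > v
        out[:, i] = n_ge[:MAX_INTENSITY] / npix  # >= t  <=>  > t-1
    return out


def apply_threshold(quantised: QuantisedZStack, threshold: int) -> BinaryZStack:
    """Binary stain-positive mask at an integer threshold in 1..4095."""
    t = int(threshold)
    if not 1 <= t <= MAX_INTENSITY:
        raise DataError(f"threshold must lie in 1..{MAX_INTENSITY}")
    return BinaryZStack(component_id=quantised.component_id,
                        mask=quantised.values >= t, threshold_value=t,
                        geometry=quantised.geometry)


# ---------------------------------------------------------------------------
# automated threshold selection


def _kruskal_p(groups: np.ndarray) -> float:
    """Kruskal-Wallis p across threshold groups (rows); degenerate
    all-identical data fails to reject by construction."""
    groups = np.asarray(groups)
    if np.ptp(groups) == 0:  # scipy yields nan/0 division artefacts here
        return 1.0
    try:
        with np.errstate(divide="ignore", invalid="ignore"):
            p = float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all numbers identical
        return 1.0
    return 1.0 if np.isnan(p) else p


def select_threshold(tables, alpha: float = 0.05, min_window: int = 10,
                     step: int = 10) -> int:
    """Choose one threshold per fluorophore from replicate-FOV coverage data.

    For each FOV the total coverage-vs-threshold curve (summed over slices)
    is normalised by its own maximum.  Candidate thresholds are those whose
    mean normalised coverage lies strictly between 0 and 1; within each
    contiguous candidate run (subsampled every ``step`` thresholds) the
    longest window where a Kruskal-Wallis test across thresholds (groups =
    thresholds, observations = per-FOV normalised coverages) fails to reject
    at ``alpha`` is found.  The median threshold of the longest such plateau,
    rounded to an integer, is returned.

    Raises :class:`PlateauNotFoundError` when no plateau spans at least
    ``min_window`` thresholds, instructing manual review.
    """
    tables = list(tables)
    if not tables:
        raise DataError("need at least one coverage table")
    curves = []
    for tab in tables:
        tot = np.asarray(tab).sum(axis=1)
        m = tot.max()
        if m <= 0:
            raise DataError("constant-zero coverage curve; nothing to threshold")
        curves.append(tot / m)
    curves = np.stack(curves)                      # (n_fov, 4095)
    mean_curve = curves.mean(axis=0)
    candidate = (mean_curve > 0) & (mean_curve < 1)
    cand_idx = np.flatnonzero(candidate)           # 0-based; threshold = idx+1
    if cand_idx.size == 0:
        raise PlateauNotFoundError(
            "no thresholds with coverage strictly between 0 and maximum")

    # contiguous runs of candidate thresholds
    runs = np.split(cand_idx, np.flatnonzero(np.diff(cand_idx) > 1) + 1)
    best: np.ndarray | None = None
    for run in runs:
        sub = run[::step]
        if sub.size == 0:
            continue
        lo = 0
        hi = 0  # window is sub[lo:hi]
        while hi < sub.size:
            hi += 1
            while hi - lo >= 2 and _kruskal_p(curves[:, sub[lo:hi]].T) < alpha:
                lo += 1
            window = sub[lo:hi]
            span = window[-1] - window[0] + 1
            if best is None or span > (best[-1] - best[0] + 1):
                best = window.copy()
    if best is None or (best[-1] - best[0] + 1) < min_window:
        raise PlateauNotFoundError(
            f"no threshold-insensitive plateau of >= {min_window} thresholds "
            f"at alpha={alpha}; review the coverage curves manually")
    # median over the full plateau span, in threshold units (index + 1)
    return int(round((best[0] + best[-1]) / 2)) + 1


# ---------------------------------------------------------------------------
# area profiles, alignment, volume, spread


@dataclass(frozen=True)
class AreaProfile:
    """Per-slice area-coverage curve of one component.

    Stored water-side first.  ``aligned_indices`` is None before alignment;
    after :func:`align_to_cell_peak` the cell-peak slice has index 0,
    negative indices lie toward the bulk water and positive toward the
    substratum.  ``depth_step_um`` converts aligned indices to a normalised
    depth for plotting.
    """

    component_id: str
    fractions: np.ndarray
    depth_step_um: float = PLOT_DEPTH_STEP_UM
    aligned_indices: np.ndarray | None = None

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        if f.ndim != 1 or f.size == 0:
            raise DataError("profile must be a non-empty 1-D fraction array")
        if f.min() < 0 or f.max() > 1:
            raise DataError("coverage fractions must lie in [0, 1]")
        object.__setattr__(self, "fractions", f)
        if self.aligned_indices is not None:
            ai = np.asarray(self.aligned_indices, dtype=int)
            if ai.size != f.size or np.any(np.diff(ai) != 1):
                raise DataError("aligned indices must be consecutive and match")
            object.__setattr__(self, "aligned_indices", ai)

    @property
    def raw_indices(self) -> np.ndarray:
        return np.arange(self.fractions.size)

    @property
    def normalised_depth_um(self) -> np.ndarray:
        if self.aligned_indices is None:
            raise DataError("profile is not aligned")
        return self.aligned_indices * self.depth_step_um


def area_profile(binary: BinaryZStack,
                 depth_step_um: float = PLOT_DEPTH_STEP_UM) -> AreaProfile:
    """Per-slice coverage of a mask, reordered water-side first."""
    fr = np.array([area_coverage(sl) for sl in binary.mask])
    if binary.geometry.water_side == "last":
        fr = fr[::-1].copy()
    return AreaProfile(component_id=binary.component_id, fractions=fr,
                       depth_step_um=depth_step_um)


def _peak_index(fractions: np.ndarray) -> int:
    """Index of maximum coverage; ties break toward the substratum (larger
    index, since profiles run water -> substratum)."""
    f = np.asarray(fractions)
    return int(f.size - 1 - np.argmax(f[::-1]))


def align_to_cell_peak(profiles: dict, cells_id: str = "cells") -> dict:
    """Align every component's profile to the cell coverage peak.

    The slice of maximum cell coverage becomes aligned index 0; slices toward
    the bulk water are negative, toward the substratum positive.  Aligning an
    already-aligned set is a no-op (the alignment is re-derived from the same
    cell profile).
    """
    if cells_id not in profiles:
        raise DataError(f"no '{cells_id}' profile to align to")
    cells = profiles[cells_id]
    if not np.any(cells.fractions > 0):
        raise DataError("cell profile is all-zero; cannot align")
    peak = _peak_index(cells.fractions)
    out = {}
    for cid, prof in profiles.items():
        ai = prof.raw_indices - peak
        out[cid] = replace(prof, aligned_indices=ai)
    return out


def peak_location(profile: AreaProfile) -> int | None:
    """Aligned slice index of maximum coverage; ties break toward the
    substratum.  Returns None (flagged undefined) for an all-zero profile."""
    if profile.aligned_indices is None:
        raise DataError("profile must be aligned first")
    if not np.any(profile.fractions > 0):
        warnings.warn(f"{profile.component_id}: all-zero profile, "
                      "peak location undefined")
        return None
    return int(profile.aligned_indices[_peak_index(profile.fractions)])


def compute_volume(profile: AreaProfile,
                   depth_step_um: float = DEFAULT_DEPTH_STEP_UM,
                   image_area_um2: float | None = None,
                   geometry: StackGeometry | None = None) -> float:
    """Component volume (um^3), relative to the detection threshold:
    depth_step x image_area x sum of per-slice coverage fractions."""
    if image_area_um2 is None:
        if geometry is None:
            raise DataError("supply image_area_um2 or geometry")
        image_area_um2 = geometry.image_area_um2
    if depth_step_um <= 0 or image_area_um2 <= 0:
        raise DataError("geometry values must be positive")
    return float(depth_step_um * image_area_um2 * profile.fractions.sum())


def compute_spread(volume_um3: float, area_coverage_peak: float,
                   image_area_um2: float) -> float:
    """Spread (um) = volume / (peak coverage x image area), a thickness proxy
    independent of the coverage level for uniform profiles."""
    if area_coverage_peak <= 0:
        raise DataError("peak coverage must be positive to compute spread")
    return float(volume_um3 / (area_coverage_peak * image_area_um2))


@dataclass(frozen=True)
class StructureMetrics:
    """Volume, spread and peak location of one component in one FOV."""

    component_id: str
    volume_um3: float
    spread_um: float | None
    peak_location: int | None
    area_coverage_peak: float


def structure_metrics(profiles: dict, image_area_um2: float,
                      depth_step_um: float = DEFAULT_DEPTH_STEP_UM) -> dict:
    """Per-component metrics from aligned profiles of one FOV."""
    out = {}
    for cid, prof in profiles.items():
        vol = compute_volume(prof, depth_step_um=depth_step_um,
                             image_area_um2=image_area_um2)
        peak_cov = float(prof.fractions.max())
        spread = (compute_spread(vol, peak_cov, image_area_um2)
                  if peak_cov > 0 else None)
        out[cid] = StructureMetrics(component_id=cid, volume_um3=vol,
                                    spread_um=spread,
                                    peak_location=peak_location(prof)
                                    if np.any(prof.fractions > 0) else None,
                                    area_coverage_peak=peak_cov)
    return out


# ---------------------------------------------------------------------------
# composition ratios and group statistics

RATIO_DEFS = {
    "eps_to_cells": ("eps", "cells"),
    "carbohydrates_to_cells": ("carbohydrates", "cells"),
    "proteins_to_cells": ("proteins", "cells"),
    "carbohydrates_to_proteins": ("carbohydrates", "proteins"),
}


def composition_ratios(volumes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-FOV composition ratios and their non-parametric summaries.

    ``volumes``: one row per FOV with columns cells / carbohydrates /
    proteins (um^3).  EPS (= carbohydrates + proteins) and total biofilm are
    summed per FOV *before* averaging, and every ratio is formed per FOV and
    then summarised (median and min-max range) -- a median of ratios, never a
    ratio of medians.  Zero-denominator ratios are flagged NaN and excluded
    from the summaries, with the exclusion count reported.
    """
    df = volumes.copy()
    for col in ("cells", "carbohydrates", "proteins"):
        if col not in df:
            raise DataError(f"volumes table lacks a '{col}' column")
    df["eps"] = df["carbohydrates"] + df["proteins"]
    df["total_biofilm"] = df["eps"] + df["cells"]
    ratios = pd.DataFrame(index=df.index)
    for name, (num, den) in RATIO_DEFS.items():
        denom = df[den]
        ratios[name] = np.where(denom > 0, df[num] / denom.replace(0, np.nan),
                                np.nan)
    rows = []
    for name in ratios:
        r = ratios[name]
        rows.append({"ratio": name, "median": r.median(), "min": r.min(),
                     "max": r.max(), "n": int(r.notna().sum()),
                     "n_undefined": int(r.isna().sum())})
    return ratios, pd.DataFrame(rows).set_index("ratio")


def compare_groups(values, labels, alpha: float = 0.05) -> dict:
    """Distribution-free comparison of a per-FOV metric between groups.

    Runs a Shapiro-Wilk normality screen per group (reported, not acted on),
    then a two-sample Wilcoxon rank-sum test (statistic W = Mann-Whitney U of
    the first group, as R's ``wilcox.test`` reports) or a Kruskal-Wallis test
    for more than two groups.  Medians and ranges accompany the test.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = {}
    for g in pd.unique(labels):
        v = values[labels == g]
        if v.size < 2:
            raise DataError(f"group {g!r} has fewer than 2 observations")
        groups[g] = v
    report = {"groups": {}, "alpha": alpha}
    for g, v in groups.items():
        entry = {"n": int(v.size), "median": float(np.median(v)),
                 "min": float(v.min()), "max": float(v.max())}
        if v.size >= 3 and np.ptp(v) > 0:
            entry["shapiro_p"] = float(stats.shapiro(v).pvalue)
        report["groups"][g] = entry
    vals = list(groups.values())
    if len(vals) == 2:
        res = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        report.update(test="wilcoxon-rank-sum", W=float(res.statistic),
                      p=float(res.pvalue))
    else:
        res = stats.kruskal(*vals)
        report.update(test="kruskal-wallis", H=float(res.statistic),
                      p=float(res.pvalue))
    return report


# ---------------------------------------------------------------------------
# 3-D overlay export

OVERLAY_COLOURS = {  # RGB in [0,1]; rendered at 50% opacity
    "cells": (1.0, 0.0, 0.0),
    "carbohydrates": (0.0, 1.0, 0.0),
    "proteins": (0.0, 0.0, 1.0),
}


def export_overlay(masks: dict, path_prefix, opacity: float = 0.5,
                   write_pngs: bool = True) -> dict:
    """Write thresholded masks as a legacy-ASCII VTK structured-points volume
    (one scalar field per component, colour/opacity metadata in the header
    comment) plus per-slice RGB overlay PNGs.

    Overlapping components keep both scalars set, preserving co-localisation;
    the PNG overlay blends colours additively at ``opacity``.
    Returns {"vtk": path, "pngs": [paths]}.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.image as mpimg

    masks = dict(masks)
    shapes = {m.mask.shape for m in masks.values()}
    if len(shapes) != 1:
        raise DataError("masks must share a common shape")
    first = next(iter(masks.values()))
    for m in masks.values():
        if m.geometry != first.geometry:
            raise DataError("masks must share a common geometry")
    geom = first.geometry
    z, ny, nx = first.mask.shape

    vtk_path = f"{path_prefix}.vtk"
    colour_note = ", ".join(
        f"{cid}: rgb{OVERLAY_COLOURS.get(cid, (1, 1, 1))} at {opacity:.0%} opacity"
        for cid in masks)
    with open(vtk_path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"biofilm component overlay ({colour_note})\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {z}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {geom.pixel_size_um} {geom.pixel_size_um} "
                 f"{geom.slice_interval_um}\n")
        fh.write(f"POINT_DATA {nx * ny * z}\n")
        for cid, m in masks.items():
            fh.write(f"SCALARS {cid} unsigned_char 1\nLOOKUP_TABLE default\n")
            flat = m.mask.astype(np.uint8).ravel(order="C")
            for start in range(0, flat.size, 20):
                fh.write(" ".join(map(str, flat[start:start + 20])) + "\n")

    png_paths = []
    if write_pngs:
        for i in range(z):
            rgb = np.zeros((ny, nx, 3))
            for cid, m in masks.items():
                col = np.asarray(OVERLAY_COLOURS.get(cid, (1.0, 1.0, 1.0)))
                rgb += opacity * m.mask[i, :, :, None] * col
            p = f"{path_prefix}_slice{i:03d}.png"
            mpimg.imsave(p, np.clip(rgb, 0, 1))
            png_paths.append(p)
    return {"vtk": vtk_path, "pngs": png_paths}


def read_overlay_vtk(path) -> dict:
    """Reload a legacy-ASCII VTK overlay; returns {component_id: bool array
    (z, y, x)}.  Round-trip check for :func:`export_overlay`."""
    with open(path) as fh:
        lines = fh.read().split("\n")
    dims = None
    fields = {}
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("DIMENSIONS"):
            nx, ny, nz = map(int, line.split()[1:4])
            dims = (nz, ny, nx)
        elif line.startswith("SCALARS"):
            name = line.split()[1]
            i += 1  # skip LOOKUP_TABLE
            vals = []
            need = dims[0] * dims[1] * dims[2]
            while len(vals) < need:
                i += 1
                vals.extend(map(int, lines[i].split()))
            fields[name] = np.asarray(vals, dtype=bool).reshape(dims)
        i += 1
    return fields
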