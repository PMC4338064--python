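"""End-to-end pipelines tying the modules together.

``run_quantify``: read lambda stacks -> unmix -> median filter -> joint
threshold selection -> masks -> aligned area profiles -> volume / spread /
peak location -> composition ratios -> overlays, written as tidy tables.

``run_fingerprint``: peak tables -> noise filter -> fragment alignment ->
normalisation -> diversity indices -> Bray-Curtis -> ANOSIM / SIMPER /
SIMPROF clustering, written as tables, a Newick dendrogram and a JSON
test report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import fingerprint as fp
from . import metrics as mx
from .config import resolve_config
from .errors import ConfigurationError, GeometryError
from .lambda_stack import FingerprintLibrary, read_lambda_stack, read_spectrum
from .unmixing import unmix_stack

log = logging.getLogger("biofilmdia")


def _geometry_overrides(cfg: dict) -> dict:
    g = cfg["geometry"]
    out = {}
    for key in ("slice_interval_um", "optical_slice_um", "water_side",
                "field_width_um", "field_height_um", "pixel_size_um"):
        if g.get(key) is not None:
            out[key] = g[key]
    return out


def load_fingerprint_library(paths) -> FingerprintLibrary:
    """Build a library from 2-column fingerprint files (one per component)."""
    spectra = []
    for path in paths:
        spec, _ = read_spectrum(path)
        spectra.append(spec)
    if not spectra:
        raise ConfigurationError("no fingerprint files supplied")
    return FingerprintLibrary(spectra=tuple(spectra))


def run_quantify(stack_paths, library: FingerprintLibrary, config: dict | None,
                 out_dir, write_overlays: bool = True) -> dict:
    """Quantify every stack (FOV) and write the report bundle.

    Thresholds are selected per component across the FOV ensemble on a
    shared quantisation scale; geometry overrides in the config fill any
    fields absent from the stack metadata (each resolved value is logged).
    """
    stack_paths = [Path(p) for p in stack_paths]
    if not stack_paths:
        raise ConfigurationError("no input stacks")
    cfg, cfg_log = resolve_config(config)
    for line in cfg_log:
        log.info("config: %s", line)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    overrides = _geometry_overrides(cfg)
    stained = library.stained_ids

    filtered = {}  # fov -> {component: ComponentZStack}
    geoms = {}
    for path in stack_paths:
        try:
            stack = read_lambda_stack(path)
        except GeometryError:
            # metadata incomplete: fall back on configured geometry, loudly
            log.warning("geometry missing in %s; applying configured values %s",
                        path, overrides)
            stack = read_lambda_stack(path, geometry=overrides)
        comps, _resid = unmix_stack(stack, library,
                                    nonnegative=cfg["unmixing"]["nonnegative"])
        filtered[path.stem] = {cid: mx.median_filter_stack(comps[cid])
                               for cid in stained}
        geoms[path.stem] = stack.geometry

    # shared 12-bit scale per component across the FOV ensemble
    scales = {cid: max(filtered[f][cid].abundances.max() for f in filtered)
              for cid in stained}
    quantised = {}
    for fov, comps in filtered.items():
        quantised[fov] = {}
        for cid in stained:
            s = 4095.0 / scales[cid] if scales[cid] > 0 else 1.0
            quantised[fov][cid] = mx.quantise_to_12bit(comps[cid], scale=s)
            log.info("quantisation: %s/%s scale=%.6g", fov, cid, s)

    thresholds = {}
    for cid in stained:
        tables = [mx.coverage_vs_threshold(quantised[f][cid]) for f in quantised]
        thresholds[cid] = mx.select_threshold(
            tables, alpha=cfg["threshold"]["alpha"],
            min_window=cfg["threshold"]["min_window"],
            step=cfg["threshold"]["step"])
        log.info("threshold: %s -> %d", cid, thresholds[cid])

    g = cfg["geometry"]
    rows, profile_rows = [], []
    volumes_by_fov = {}
    for fov in quantised:
        geom = geoms[fov]
        area = g["image_area_um2"] or geom.image_area_um2
        masks = {cid: mx.apply_threshold(quantised[fov][cid], thresholds[cid])
                 for cid in stained}
        profiles = {cid: mx.area_profile(masks[cid],
                                         depth_step_um=g["plot_depth_step_um"])
                    for cid in stained}
        profiles = mx.align_to_cell_peak(profiles)
        sm = mx.structure_metrics(profiles, image_area_um2=area,
                                  depth_step_um=g["depth_step_um"])
        volumes_by_fov[fov] = {cid: sm[cid].volume_um3 for cid in stained}
        for cid, m in sm.items():
            rows.append({"fov": fov, "component": cid,
                         "threshold": thresholds[cid],
                         "volume_um3": m.volume_um3, "spread_um": m.spread_um,
                         "peak_location": m.peak_location,
                         "area_coverage_peak": m.area_coverage_peak})
        for cid, prof in profiles.items():
            for ai, d, f in zip(prof.aligned_indices,
                                prof.normalised_depth_um, prof.fractions):
                profile_rows.append({"fov": fov, "component": cid,
                                     "aligned_slice": int(ai),
                                     "depth_um": float(d),
                                     "area_coverage_fraction": float(f)})
        if write_overlays:
            mx.export_overlay(masks, out_dir / f"overlay_{fov}",
                              write_pngs=False)

    metrics_df = pd.DataFrame(rows)
    profiles_df = pd.DataFrame(profile_rows)
    vol_tab = pd.DataFrame(volumes_by_fov).T
    ratios, ratio_summary = mx.composition_ratios(vol_tab)

    metrics_df.to_csv(out_dir / "metrics.csv", index=False)
    profiles_df.to_csv(out_dir / "area_profiles.csv", index=False)
    ratios.to_csv(out_dir / "ratios_per_fov.csv")
    ratio_summary.to_csv(out_dir / "ratio_summary.csv")
    (out_dir / "run_log.txt").write_text("\n".join(cfg_log) + "\n")
    return {"metrics": metrics_df, "profiles": profiles_df,
            "ratios": ratios, "ratio_summary": ratio_summary,
            "thresholds": thresholds, "out_dir": out_dir}


def run_fingerprint(profiles, labels=None, config: dict | None = None,
                    out_dir=None) -> dict:
    """Fingerprint analysis chain over per-sample peak profiles.

    ``labels`` (group per profile, aligned with ``profiles``) enables
    ANOSIM / SIMPER and the index t-tests; without it only indices,
    similarities and SIMPROF clustering are produced.  With a single sample
    the similarity stages are skipped with a notice.
    """
    cfg, cfg_log = resolve_config(config)
    fcfg = cfg["fingerprint"]
    profiles = [fp.filter_peaks(p, height_cutoff=fcfg["height_cutoff"])
                for p in profiles]
    results: dict = {"notices": []}

    if len(profiles) < 2:
        matrix = fp.align_fragments(profiles, tolerance=fcfg["align_tolerance_nt"]) \
            if profiles else None
        results["notices"].append(
            "single sample: similarity stage skipped; indices only")
        if matrix is not None:
            norm = fp.normalise(matrix, min_fraction=fcfg["abundance_cutoff"],
                                renormalise=fcfg["renormalise"])
            results["community_matrix"] = norm
            results["indices"] = fp.diversity(norm)
        _write_fp(results, cfg_log, out_dir)
        return results

    matrix = fp.align_fragments(profiles, tolerance=fcfg["align_tolerance_nt"])
    norm = fp.normalise(matrix, min_fraction=fcfg["abundance_cutoff"],
                        renormalise=fcfg["renormalise"])
    sim = fp.bray_curtis(norm)
    results.update(community_matrix=norm, similarity=sim,
                   indices=fp.diversity(norm))

    if len(profiles) >= 3:
        clustering = fp.simprof_cluster(norm,
                                        n_perm=fcfg["simprof_permutations"],
                                        alpha=fcfg["alpha"], seed=fcfg["seed"])
        results["simprof"] = clustering

    if labels is not None:
        labels = np.asarray(labels)
        uniq, counts = np.unique(labels, return_counts=True)
        if uniq.size >= 2 and counts.min() >= 2:
            results["anosim"] = fp.anosim(sim, labels,
                                          permutations=fcfg["anosim_permutations"],
                                          seed=fcfg["seed"])
            if uniq.size == 2:
                results["simper"] = fp.simper(norm, labels)
                results["index_tests"] = fp.compare_indices(
                    results["indices"], labels)
        else:
            results["notices"].append("groups too small for ANOSIM; skipped")
    _write_fp(results, cfg_log, out_dir)
    return results


def _write_fp(results: dict, cfg_log, out_dir) -> None:
    if out_dir is None:
        return
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if "community_matrix" in results:
        results["community_matrix"].to_csv(out_dir / "community_matrix.csv")
    if "similarity" in results:
        results["similarity"].to_csv(out_dir / "similarity.csv")
    if "indices" in results:
        results["indices"].to_csv(out_dir / "indices.csv")
    if "index_tests" in results:
        results["index_tests"].to_csv(out_dir / "index_ttests.csv")
    if "simper" in results:
        results["simper"]["contributions"].to_csv(out_dir / "simper.csv")
    if "simprof" in results:
        (out_dir / "dendrogram.nwk").write_text(results["simprof"].newick + "\n")
    report = {"notices": results["notices"]}
    if "anosim" in results:
        report["anosim"] = results["anosim"]
    if "simper" in results:
        report["simper_average_dissimilarity"] = \
            results["simper"]["average_dissimilarity"]
        report["simper_within_group_similarity"] = \
            {str(k): v for k, v in
             results["simper"]["within_group_similarity"].items()}
    (out_dir / "report.json").write_text(json.dumps(report, indent=2))
    (out_dir / "run_log.txt").write_text("\n".join(cfg_log) + "\n")


def plot_area_distributions(profiles_df: pd.DataFrame, path) -> None:
    """Area-distribution figure: one panel per component, per-FOV curves,
    depth axis aligned to the cell peak (substratum downward)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comps = list(pd.unique(profiles_df["component"]))
    fig, axes = plt.subplots(1, len(comps), figsize=(4 * len(comps), 5),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, cid in zip(axes, comps):
        sub = profiles_df[profiles_df["component"] == cid]
        for fov, g in sub.groupby("fov"):
            ax.plot(g["area_coverage_fraction"], g["depth_um"], lw=0.8)
        ax.axhline(0.0, color="tab:blue", ls="--", lw=0.8)
        ax.set_title(cid)
        ax.set_xlabel("area coverage fraction")
    axes[0].set_ylabel("normalised depth (um)\n(negative = bulk water)")
    axes[0].invert_yaxis()  # bulk water (negative) at the top
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
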