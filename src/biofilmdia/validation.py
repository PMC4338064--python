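"""Self-validation experiments on synthetic data with known truth.

Each function runs one documented check of the analysis chain -- volume and
spread against voxel-count oracles, unmixing recovery, threshold-plateau
containment, end-to-end parameter recovery, and the calibration of the
permutation statistics -- and returns plain numbers.  They are used by the
test suite and by ``scripts/acceptance.py``; all randomness is seeded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import fingerprint as fp
from . import metrics as mx
from .lambda_stack import (EmissionSpectrum, FingerprintLibrary, LambdaZStack,
                           StackGeometry, lambda_bin_centres)
from .synthetic import (BiofilmSceneParams, generate_biofilm_stack,
                        scene_spectra, small_scene_params)
from .unmixing import unmix_stack

STAINED = ("cells", "carbohydrates", "proteins")


def scene_library(params: BiofilmSceneParams | None = None) -> FingerprintLibrary:
    spectra = scene_spectra(params)
    return FingerprintLibrary(tuple(EmissionSpectrum(cid, vals)
                                    for cid, vals in spectra.items()))


def volume_spread_oracle_suite(n_stacks: int = 50, seed: int = 0) -> dict:
    """Random small binary stacks: the volume formula must equal the
    voxel-count oracle, and the spread of uniform k-slice profiles must be
    depth_step x k exactly.  Returns worst-case relative errors."""
    rng = np.random.default_rng(seed)
    worst_vol = 0.0
    worst_spread = 0.0
    for _ in range(n_stacks):
        nz = int(rng.integers(2, 12))
        n = int(rng.integers(4, 16))
        step = float(rng.uniform(0.5, 5.0))
        pix = float(rng.uniform(0.2, 2.0))
        geom = StackGeometry(slice_interval_um=step, optical_slice_um=2 * step,
                             pixel_size_um=pix, field_width_um=pix * n,
                             field_height_um=pix * n)
        mask = rng.random((nz, n, n)) < rng.uniform(0.1, 0.9)
        binary = mx.BinaryZStack(component_id="c", mask=mask,
                                 threshold_value=1, geometry=geom)
        prof = mx.area_profile(binary)
        vol = mx.compute_volume(prof, depth_step_um=step, geometry=geom)
        oracle = mask.sum() * pix * pix * step
        if oracle > 0:
            worst_vol = max(worst_vol, abs(vol - oracle) / oracle)
        k = int(rng.integers(1, 20))
        f = float(rng.uniform(0.01, 1.0))
        area = float(rng.uniform(10.0, 1e6))
        uprof = mx.AreaProfile(component_id="u", fractions=np.full(k, f))
        spread = mx.compute_spread(mx.compute_volume(uprof, step, area), f, area)
        worst_spread = max(worst_spread, abs(spread - step * k) / (step * k))
    return {"max_rel_err_volume": worst_vol,
            "max_rel_err_spread": worst_spread, "n": n_stacks}


def unmixing_noiseless_error(seed: int = 0) -> dict:
    """Integer-valued noiseless mixtures: maximum absolute abundance error."""
    rng = np.random.default_rng(seed)
    amat = np.array([[4.0, 0.0, 0.0, 1.0],
                     [1.0, 3.0, 0.0, 1.0],
                     [0.0, 1.0, 3.0, 2.0],
                     [0.0, 0.0, 1.0, 1.0],
                     [0.0, 0.0, 0.0, 1.0]])
    ids = ["cells", "carbohydrates", "proteins", "autofluorescence"]
    lib = FingerprintLibrary(tuple(EmissionSpectrum(cid, amat[:, i])
                                   for i, cid in enumerate(ids)))
    coeffs = rng.integers(0, 150, size=(4, 3, 8, 8)).astype(float)
    clean = np.einsum("bc,czyx->zbyx", amat, coeffs)
    centres, width = lambda_bin_centres(650.7, 704.2, 5)
    geom = StackGeometry(slice_interval_um=2.35, optical_slice_um=4.7,
                         pixel_size_um=1.0, field_width_um=8.0,
                         field_height_um=8.0)
    stack = LambdaZStack(intensities=clean.astype(np.uint16), geometry=geom,
                         lambda_bin_centres_nm=centres,
                         lambda_bin_width_nm=width)
    comps, resid = unmix_stack(stack, lib)
    err = max(np.abs(comps[cid].abundances - coeffs[i]).max()
              for i, cid in enumerate(ids))
    return {"max_abs_err": float(err),
            "max_residual": float(resid.values.max()),
            "n": int(clean.size)}


def unmixing_noisy_correlation(seed: int = 0, image_px: int = 96) -> dict:
    """Voxelwise correlation between unmixed abundances and generator truth
    on the Poisson-noise synthetic scene."""
    params = small_scene_params(image_px=image_px)
    stack, truth = generate_biofilm_stack(params, seed=seed)
    comps, _ = unmix_stack(stack, scene_library(params))
    est = np.concatenate([comps[c].abundances.ravel() for c in STAINED])
    tru = np.concatenate([truth.abundances[c].ravel() for c in STAINED])
    return {"correlation": float(np.corrcoef(est, tru)[0, 1]),
            "n": int(est.size)}


def threshold_plateau_check(seed: int = 0, n_fov: int = 5) -> dict:
    """Two-level ensemble (background 100, signal 3000): the selected
    threshold must land inside the analytically known plateau 101..3000."""
    rng = np.random.default_rng(seed)
    tables = []
    n = 32
    for _ in range(n_fov):
        frac = rng.uniform(0.4, 0.6)
        npix = n * n
        sl = np.full(npix, 100, dtype=np.uint16)
        sl[:int(round(frac * npix))] = 3000
        geom = StackGeometry(slice_interval_um=2.35, optical_slice_um=4.7,
                             pixel_size_um=1.0, field_width_um=float(n),
                             field_height_um=float(n))
        q = mx.QuantisedZStack(component_id="c",
                               values=np.stack([sl.reshape(n, n)] * 3),
                               scale=1.0, geometry=geom)
        tables.append(mx.coverage_vs_threshold(q))
    t = mx.select_threshold(tables)
    return {"threshold": int(t), "in_plateau": bool(101 <= t <= 3000),
            "plateau": (101, 3000), "n": n_fov}


def end_to_end_recovery(seed: int = 0, image_px: int = 160,
                        n_fov: int = 3) -> dict:
    """Full chain on the synthetic scene: generate -> unmix -> filter ->
    joint threshold -> mask -> align -> metrics, compared against exact
    voxel truth.  Returns the worst volume error (%) and the recovered
    EPS peak offsets."""
    params = small_scene_params(image_px=image_px)
    lib = scene_library(params)
    filtered, truths = {}, {}
    for i in range(n_fov):
        stack, truth = generate_biofilm_stack(params, seed=seed + i)
        comps, _ = unmix_stack(stack, lib)
        filtered[i] = {c: mx.median_filter_stack(comps[c]) for c in STAINED}
        truths[i] = truth
        geom = stack.geometry
    scales = {c: max(filtered[i][c].abundances.max() for i in filtered)
              for c in STAINED}
    quant = {i: {c: mx.quantise_to_12bit(filtered[i][c],
                                         scale=4095.0 / scales[c])
                 for c in STAINED} for i in filtered}
    thresholds = {c: mx.select_threshold(
        [mx.coverage_vs_threshold(quant[i][c]) for i in quant])
        for c in STAINED}
    worst = {c: 0.0 for c in STAINED}
    offsets = {c: set() for c in STAINED}
    for i in quant:
        masks = {c: mx.apply_threshold(quant[i][c], thresholds[c])
                 for c in STAINED}
        profiles = mx.align_to_cell_peak(
            {c: mx.area_profile(masks[c]) for c in STAINED})
        sm = mx.structure_metrics(profiles,
                                  image_area_um2=geom.image_area_um2,
                                  depth_step_um=geom.slice_interval_um)
        for c in STAINED:
            tv = truths[i].volumes_um3[c]
            worst[c] = max(worst[c], 100.0 * abs(sm[c].volume_um3 - tv) / tv)
            offsets[c].add(sm[c].peak_location)
    return {"max_volume_error_pct": worst,
            "peak_offsets": {c: sorted(offsets[c]) for c in STAINED},
            "true_offsets": {c: truths[0].peak_offsets[c] for c in STAINED},
            "thresholds": thresholds,
            "n": n_fov * image_px * image_px * params.n_slices}


def anosim_type1(seed: int = 0, n_sims: int = 200, n_perm: int = 999,
                 n_samples: int = 10, n_bins: int = 15) -> dict:
    """Type-I error and p-value uniformity of ANOSIM under the null
    (random labels on exchangeable samples)."""
    from scipy.stats import kstest

    rng = np.random.default_rng(seed)
    labels = np.array(["a"] * (n_samples // 2) + ["b"] * (n_samples // 2))
    pvals = []
    for _ in range(n_sims):
        x = rng.lognormal(0.0, 1.0, size=(n_samples, n_bins))
        m = pd.DataFrame(x / x.sum(axis=1, keepdims=True),
                         index=[f"s{j}" for j in range(n_samples)])
        res = fp.anosim(fp.bray_curtis(m), labels, permutations=n_perm,
                        seed=int(rng.integers(2**31)))
        pvals.append(res["p"])
    pvals = np.asarray(pvals)
    return {"type1_rate": float(np.mean(pvals <= 0.05)),
            "ks_uniform_p": float(kstest(pvals, "uniform").pvalue),
            "n": n_sims}


def simprof_type1(seed: int = 0, n_sims: int = 200, n_perm: int = 1000,
                  n_samples: int = 10, n_bins: int = 15) -> dict:
    """Type-I error of the SIMPROF test under its null: fragment bins
    independently exchangeable across samples."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_sims):
        m = pd.DataFrame(rng.lognormal(0.0, 1.0, size=(n_samples, n_bins)),
                         index=[f"s{j}" for j in range(n_samples)])
        res = fp.simprof_test(m, n_perm=n_perm,
                              seed=int(rng.integers(2**31)))
        rejections += res["p"] <= 0.05
    return {"type1_rate": rejections / n_sims, "n": n_sims}


def simper_consistency(seed: int = 0) -> dict:
    """SIMPER contributions must sum to the average between-group
    Bray-Curtis dissimilarity (absolute closure error)."""
    rng = np.random.default_rng(seed)
    x = rng.random((10, 12))
    m = pd.DataFrame(x / x.sum(axis=1, keepdims=True),
                     index=[f"s{j}" for j in range(10)])
    labels = np.array(["g1"] * 5 + ["g2"] * 5)
    res = fp.simper(m, labels)
    sim = fp.bray_curtis(m)
    between = [100.0 - sim.iloc[i, j] for i in range(5) for j in range(5, 10)]
    err = abs(res["contributions"]["contribution_pct"].sum()
              - float(np.mean(between)))
    return {"closure_error": float(err), "n": int(m.size)}


def bray_curtis_hand_example() -> float:
    """x=(0.5,0.5,0) vs y=(0.5,0,0.5) after sqrt transform -> 50.0 %."""
    m = pd.DataFrame([[0.5, 0.5, 0.0], [0.5, 0.0, 0.5]], index=["x", "y"])
    return float(fp.bray_curtis(m).loc["x", "y"])
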