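import numpy as np
import pytest

import biofilmdia as b


@pytest.fixture(scope="session")
def scene_library():
    """Fingerprint library matching the synthetic scene's endmembers."""
    params = b.small_scene_params()
    spectra = b.scene_spectra(params)
    return b.FingerprintLibrary(
        tuple(b.EmissionSpectrum(cid, vals) for cid, vals in spectra.items()))


@pytest.fixture(scope="session")
def tiny_scene():
    """One small noisy field of view with ground truth (seeded)."""
    params = b.small_scene_params(image_px=96)
    stack, truth = b.generate_biofilm_stack(params, seed=11)
    return params, stack, truth


def make_stack(intensities, bin_lo=650.7, bin_hi=704.2, pixel_um=1.0,
               water_side="first"):
    """LambdaZStack around an integer (z, lam, y, x) array with simple
    geometry; spectral axis spans the given detection range."""
    intensities = np.asarray(intensities)
    z, lam, ny, nx = intensities.shape
    centres, width = b.lambda_bin_centres(bin_lo, bin_hi, lam)
    geom = b.StackGeometry(slice_interval_um=2.35, optical_slice_um=4.7,
                           pixel_size_um=pixel_um,
                           field_width_um=pixel_um * nx,
                           field_height_um=pixel_um * ny,
                           water_side=water_side)
    return b.LambdaZStack(intensities=intensities, geometry=geom,
                          lambda_bin_centres_nm=centres,
                          lambda_bin_width_nm=width)
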