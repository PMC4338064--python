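"""Per-pixel linear spectral unmixing against a fingerprint library.

Each voxel's observed spectrum is decomposed as a non-negative linear
combination of endmember spectra (stained components plus autofluorescence).
Abundances are physical stain concentrations, so the default solver is
non-negative least squares; an unconstrained mode is available for
comparison.  The autofluorescence coefficient is estimated like any other
endmember but is reported separately and excluded from biofilm metrics.

The stack solver is exact NNLS, vectorised over all voxels by enumerating
candidate active sets (libraries have <= a handful of endmembers): for the
optimal NNLS support, the unconstrained least-squares solution restricted to
that support is feasible and attains the minimum, so scanning all supports
and keeping the feasible solution with the smallest residual reproduces
scipy.optimize.nnls exactly.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import tifffile
from scipy.optimize import nnls

from .errors import DataError
from .lambda_stack import FingerprintLibrary, LambdaZStack, StackGeometry


@dataclass(frozen=True)
class ComponentZStack:
    """Non-negative abundance field (z, y, x) for one unmixed component."""

    component_id: str
    abundances: np.ndarray
    geometry: StackGeometry
    provenance: dict = None

    def __post_init__(self):
        a = np.asarray(self.abundances, dtype=float)
        if a.ndim != 3:
            raise DataError("abundances must be 3-D (z, y, x)")
        if a.size and a.min() < -1e-9:
            raise DataError("abundances must be non-negative")
        object.__setattr__(self, "abundances", np.maximum(a, 0.0))
        object.__setattr__(self, "provenance", dict(self.provenance or {}))

    @property
    def spatial_shape(self):
        return self.abundances.shape


@dataclass(frozen=True)
class ResidualMap:
    """Per-voxel RMS residual of the spectral fit (fit-quality diagnostic)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise DataError("residuals must be non-negative")
        object.__setattr__(self, "values", v)


def _check_library(observed_len: int, library: FingerprintLibrary) -> np.ndarray:
    if library.n_bins != observed_len:
        raise DataError(
            f"observed spectrum has {observed_len} bins, library has {library.n_bins}")
    a = library.matrix.astype(float)
    if np.linalg.matrix_rank(a) < a.shape[1]:
        raise DataError("fingerprint library is singular/collinear")
    return a


def unmix_pixel(observed, library: FingerprintLibrary,
                nonnegative: bool = True) -> dict:
    """Least-squares abundances for one observed spectrum.

    Returns {component_id: abundance}; the autofluorescence coefficient is
    included under its own id (callers exclude it from biofilm signal).
    """
    y = np.asarray(observed, dtype=float)
    if y.ndim != 1:
        raise DataError("observed spectrum must be 1-D")
    a = _check_library(y.size, library)
    if nonnegative:
        coeffs, _ = nnls(a, y)
    else:
        coeffs = np.linalg.lstsq(a, y, rcond=None)[0]
    return dict(zip(library.component_ids, coeffs))


def _nnls_batch(a: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Exact batched NNLS: argmin_{c>=0} ||a c - x|| for every column of x.

    a: (bins, k) full-rank endmember matrix; x: (bins, N).
    Returns coefficients (k, N).
    """
    k = a.shape[1]
    n = x.shape[1]
    best_rss = np.einsum("ij,ij->j", x, x)  # all-zero solution
    best = np.zeros((k, n))
    for size in range(1, k + 1):
        for support in combinations(range(k), size):
            idx = list(support)
            a_s = a[:, idx]
            sol = np.linalg.pinv(a_s) @ x
            feasible = (sol >= -1e-10).all(axis=0)
            if not feasible.any():
                continue
            resid = x - a_s @ sol
            rss = np.einsum("ij,ij->j", resid, resid)
            take = feasible & (rss < best_rss - 1e-12)
            if take.any():
                best_rss[take] = rss[take]
                best[:, take] = 0.0
                best[np.ix_(idx, np.flatnonzero(take))] = np.maximum(sol[:, take], 0.0)
    return best


def unmix_stack(stack: LambdaZStack, library: FingerprintLibrary,
                nonnegative: bool = True) -> tuple[dict, ResidualMap]:
    """Voxelwise unmixing of a lambda stack.

    Returns ({component_id: ComponentZStack}, ResidualMap).  Deterministic.
    """
    a = _check_library(stack.n_bins, library)
    z, lam, ny, nx = stack.shape
    x = stack.intensities.transpose(1, 0, 2, 3).reshape(lam, -1).astype(float)
    if nonnegative:
        coeffs = _nnls_batch(a, x)
    else:
        coeffs = np.linalg.lstsq(a, x, rcond=None)[0]
    resid = x - a @ coeffs
    rms = np.sqrt(np.einsum("ij,ij->j", resid, resid) / lam).reshape(z, ny, nx)
    prov = {
        "library_sha1": hashlib.sha1(
            np.ascontiguousarray(a).tobytes()).hexdigest(),
        "nonnegative": bool(nonnegative),
    }
    out = {}
    for i, cid in enumerate(library.component_ids):
        ab = coeffs[i].reshape(z, ny, nx)
        if not nonnegative:
            ab = np.maximum(ab, 0.0)  # clip for the physical container
        out[cid] = ComponentZStack(component_id=cid, abundances=ab,
                                   geometry=stack.geometry, provenance=prov)
    return out, ResidualMap(values=rms)


def reconstruct(components: dict, library: FingerprintLibrary) -> np.ndarray:
    """Re-mix component stacks through the library (diagnostic)."""
    a = library.matrix.astype(float)
    first = next(iter(components.values()))
    z, ny, nx = first.spatial_shape
    coeffs = np.stack([components[c].abundances.reshape(-1)
                       for c in library.component_ids])
    return (a @ coeffs).reshape(library.n_bins, z, ny, nx).transpose(1, 0, 2, 3)


def write_component_tiff(component: ComponentZStack, path) -> None:
    """Write an unmixed component as single-channel 32-bit float TIFF."""
    tifffile.imwrite(path, component.abundances.astype(np.float32))
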