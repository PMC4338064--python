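"""Data model and I/O for confocal lambda-Z-stacks and emission fingerprints.

A lambda-Z-stack records a full (binned) emission spectrum at every pixel of
every focal slice: a 4-D array indexed (z, lambda bin, y, x) of 12-bit
intensities.  Emission fingerprints are the per-fluorophore (or
autofluorescence) reference spectra used as endmembers in linear unmixing.

TIFF page ordering for plain multi-page TIFF is z-major, lambda-minor; the
geometry travels in a JSON ImageDescription and can be overridden on read.
Missing geometry raises rather than defaulting silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

from .errors import DataError, GeometryError

MAX_INTENSITY = 4095  # 12-bit detector scale; thresholds live in 1..4095

_GEOMETRY_FIELDS = (
    "slice_interval_um",
    "optical_slice_um",
    "pixel_size_um",
    "field_width_um",
    "field_height_um",
    "water_side",
)


def nyquist_interval_um(optical_slice_um: float) -> float:
    """Acquisition step between adjacent slices for half-overlapping optical
    sections: half the optical slice depth (e.g. 4.7 um -> 2.35 um)."""
    if optical_slice_um <= 0:
        raise ValueError("optical slice depth must be positive")
    return optical_slice_um / 2.0


def lambda_bin_centres(lo_edge_nm: float, hi_edge_nm: float, n_bins: int):
    """Bin centres and common width for a detection range split into equal
    spectral bins (e.g. 650.7-704.2 nm in 5 bins -> width 10.7 nm).

    Returns (centres, width).
    """
    if n_bins < 1:
        raise ValueError("need at least one bin")
    if hi_edge_nm <= lo_edge_nm:
        raise ValueError("detection range is empty")
    width = (hi_edge_nm - lo_edge_nm) / n_bins
    centres = lo_edge_nm + width * (np.arange(n_bins) + 0.5)
    return centres, width


@dataclass(frozen=True)
class StackGeometry:
    """Physical geometry of an acquisition.

    ``water_side`` states which end of the z axis faces the bulk water:
    ``"first"`` means z index 0 is the bulk-water side, ``"last"`` the
    substratum side is first.  It must be declared, never inferred.
    """

    slice_interval_um: float
    optical_slice_um: float
    pixel_size_um: float
    field_width_um: float
    field_height_um: float
    water_side: str = "first"

    def __post_init__(self):
        for name in ("slice_interval_um", "optical_slice_um", "pixel_size_um",
                     "field_width_um", "field_height_um"):
            if getattr(self, name) <= 0:
                raise GeometryError(f"{name} must be positive")
        if self.water_side not in ("first", "last"):
            raise GeometryError("water_side must be 'first' or 'last'")

    @property
    def image_area_um2(self) -> float:
        return self.field_width_um * self.field_height_um

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in _GEOMETRY_FIELDS}


@dataclass(frozen=True)
class LambdaZStack:
    """4-D intensity array (z, lambda, y, x) with voxel and spectral geometry."""

    intensities: np.ndarray
    geometry: StackGeometry
    lambda_bin_centres_nm: np.ndarray
    lambda_bin_width_nm: float

    def __post_init__(self):
        a = np.asarray(self.intensities)
        if a.ndim != 4:
            raise DataError("intensities must be 4-D (z, lambda, y, x)")
        if a.shape[0] < 1:
            raise DataError("need at least one z slice")
        if a.min() < 0 or a.max() > MAX_INTENSITY:
            raise DataError(f"intensities must lie in 0..{MAX_INTENSITY}")
        centres = np.asarray(self.lambda_bin_centres_nm, dtype=float)
        if centres.ndim != 1 or centres.size != a.shape[1]:
            raise DataError("lambda bin centres must match the lambda axis")
        if centres.size > 1:
            spacing = np.diff(centres)
            if np.any(spacing <= 0):
                raise DataError("lambda bin centres must be strictly ascending")
            if np.max(np.abs(spacing - self.lambda_bin_width_nm)) > 1e-6:
                raise DataError("lambda bin spacing must equal the bin width")
        ncols = a.shape[3]
        nrows = a.shape[2]
        if abs(self.geometry.field_width_um - self.geometry.pixel_size_um * ncols) > 1e-6:
            raise GeometryError("field_width_um != pixel_size_um * n_cols")
        if abs(self.geometry.field_height_um - self.geometry.pixel_size_um * nrows) > 1e-6:
            raise GeometryError("field_height_um != pixel_size_um * n_rows")
        object.__setattr__(self, "intensities", a)
        object.__setattr__(self, "lambda_bin_centres_nm", centres)

    @property
    def n_slices(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_bins(self) -> int:
        return self.intensities.shape[1]

    @property
    def shape(self):
        return self.intensities.shape

    @property
    def spatial_shape(self):
        z, _, y, x = self.intensities.shape
        return (z, y, x)


@dataclass(frozen=True)
class EmissionSpectrum:
    """A component's fluorescence fingerprint over the lambda bins."""

    component_id: str
    intensities: np.ndarray
    excitation_nm: float | None = None
    normalisation: str = "raw"  # raw | unit-sum | unit-max

    def __post_init__(self):
        v = np.asarray(self.intensities, dtype=float)
        if v.ndim != 1:
            raise DataError("spectrum must be 1-D")
        if np.any(v < 0):
            raise DataError("spectrum intensities must be non-negative")
        if not np.any(v > 0):
            raise DataError("spectrum must have at least one positive value")
        if self.normalisation not in ("raw", "unit-sum", "unit-max"):
            raise DataError("unknown normalisation tag")
        object.__setattr__(self, "intensities", v)

    def __len__(self) -> int:
        return self.intensities.size

    def normalised(self, mode: str = "unit-sum") -> "EmissionSpectrum":
        v = self.intensities
        if mode == "unit-sum":
            v = v / v.sum()
        elif mode == "unit-max":
            v = v / v.max()
        else:
            raise ValueError("mode must be 'unit-sum' or 'unit-max'")
        return replace(self, intensities=v, normalisation=mode)


AUTOFLUORESCENCE_ID = "autofluorescence"


@dataclass(frozen=True)
class FingerprintLibrary:
    """Ordered endmember spectra: the stained components plus (at most) one
    autofluorescence spectrum identified by ``autofluorescence_id``."""

    spectra: tuple
    autofluorescence_id: str = AUTOFLUORESCENCE_ID

    def __post_init__(self):
        spectra = tuple(self.spectra)
        if not spectra:
            raise DataError("library must contain at least one spectrum")
        ids = [s.component_id for s in spectra]
        if len(set(ids)) != len(ids):
            raise DataError("component_ids must be unique")
        n = len(spectra[0])
        if any(len(s) != n for s in spectra):
            raise DataError("all spectra must have the same length")
        if ids.count(self.autofluorescence_id) > 1:
            raise DataError("at most one autofluorescence spectrum")
        m = self.__class__._matrix_of(spectra)
        norms = np.linalg.norm(m, axis=0)
        gram = (m / norms).T @ (m / norms)
        iu = np.triu_indices(len(spectra), k=1)
        if iu[0].size and np.any(gram[iu] >= 1 - 1e-9):
            raise DataError("spectra are mutually (near-)identical; unmixing is singular")
        object.__setattr__(self, "spectra", spectra)

    @staticmethod
    def _matrix_of(spectra) -> np.ndarray:
        return np.stack([s.intensities for s in spectra], axis=1)

    @property
    def component_ids(self):
        return [s.component_id for s in self.spectra]

    @property
    def n_bins(self) -> int:
        return len(self.spectra[0])

    @property
    def matrix(self) -> np.ndarray:
        """Endmember matrix, one column per component (bins x components)."""
        return self._matrix_of(self.spectra)

    @property
    def autofluorescence(self) -> EmissionSpectrum | None:
        for s in self.spectra:
            if s.component_id == self.autofluorescence_id:
                return s
        return None

    @property
    def stained_ids(self):
        return [i for i in self.component_ids if i != self.autofluorescence_id]


# ---------------------------------------------------------------------------
# stack I/O


def write_lambda_stack(stack: LambdaZStack, path) -> None:
    """Write as multi-page TIFF, z-major lambda-minor, geometry in the
    ImageDescription as JSON.  Round-trips bit-exactly."""
    z, lam, y, x = stack.shape
    meta = {
        "biofilmdia": {
            "n_slices": z,
            "n_bins": lam,
            "lambda_bin_centres_nm": list(map(float, stack.lambda_bin_centres_nm)),
            "lambda_bin_width_nm": float(stack.lambda_bin_width_nm),
            **stack.geometry.to_dict(),
        }
    }
    pages = stack.intensities.reshape(z * lam, y, x).astype(np.uint16)
    tifffile.imwrite(path, pages, description=json.dumps(meta))


def read_lambda_stack(path, geometry: dict | None = None) -> LambdaZStack:
    """Read a TIFF/OME-TIFF lambda-Z-stack.

    ``geometry`` overrides/supplies metadata fields: any of the
    :class:`StackGeometry` fields plus ``n_slices``, ``n_bins``,
    ``lambda_bin_centres_nm``, ``lambda_bin_width_nm``.  Every required field
    must come from the file or the overrides; nothing is defaulted here.
    """
    overrides = dict(geometry or {})
    try:
        with tifffile.TiffFile(path) as tf:
            pages = tf.asarray()
            desc = tf.pages[0].description
    except (OSError, ValueError, tifffile.TiffFileError) as exc:
        raise DataError(f"unreadable TIFF file {path!r}: {exc}") from exc
    meta = {}
    if desc:
        try:
            meta = json.loads(desc).get("biofilmdia", {})
        except (json.JSONDecodeError, AttributeError):
            meta = {}
    meta.update(overrides)

    missing = [k for k in ("n_slices", "n_bins", "lambda_bin_centres_nm",
                           "lambda_bin_width_nm", *_GEOMETRY_FIELDS)
               if k not in meta]
    if missing:
        raise GeometryError(
            f"geometry fields missing from metadata and overrides: {missing}")

    pages = np.asarray(pages)
    if pages.ndim == 2:
        pages = pages[None]
    z, lam = int(meta["n_slices"]), int(meta["n_bins"])
    if pages.ndim == 4:
        if pages.shape[:2] != (z, lam):
            raise DataError(
                f"file shape {pages.shape[:2]} inconsistent with declared (z={z}, lambda={lam})")
        arr = pages
    else:
        if pages.shape[0] != z * lam:
            raise DataError(
                f"{pages.shape[0]} pages inconsistent with declared (z={z}, lambda={lam})")
        arr = pages.reshape(z, lam, *pages.shape[1:])
    geom = StackGeometry(**{k: meta[k] for k in _GEOMETRY_FIELDS})
    return LambdaZStack(
        intensities=arr,
        geometry=geom,
        lambda_bin_centres_nm=np.asarray(meta["lambda_bin_centres_nm"], dtype=float),
        lambda_bin_width_nm=float(meta["lambda_bin_width_nm"]),
    )


# ---------------------------------------------------------------------------
# fingerprint extraction and selection


def extract_spectrum(stack: LambdaZStack, region, component_id: str = "region",
                     excitation_nm: float | None = None) -> EmissionSpectrum:
    """Mean spectrum over a voxel region.

    ``region`` is a sequence of (z, y, x) voxel indices; the result is the
    per-bin mean intensity over those voxels, tagged ``raw``.
    """
    region = np.atleast_2d(np.asarray(region, dtype=np.intp))
    if region.size == 0:
        raise DataError("region is empty")
    if region.shape[1] != 3:
        raise DataError("region must be (z, y, x) triples")
    z, _, y, x = stack.shape
    if (np.any(region < 0) or np.any(region[:, 0] >= z)
            or np.any(region[:, 1] >= y) or np.any(region[:, 2] >= x)):
        raise DataError("region exceeds stack bounds")
    vals = stack.intensities[region[:, 0], :, region[:, 1], region[:, 2]]
    return EmissionSpectrum(component_id=component_id,
                            intensities=vals.mean(axis=0, dtype=float),
                            excitation_nm=excitation_nm)


def medoid_spectrum(spectra, mode: str = "medoid") -> EmissionSpectrum:
    """Select the representative 'median spectrum' of replicate fingerprints.

    ``medoid`` (default): spectra are unit-sum normalised and the member
    minimising the summed Euclidean distance to all others is returned
    (un-normalised, as supplied); ties break by input order.  ``pointwise``:
    per-bin median, which may produce a spectrum no replicate exhibited.
    """
    spectra = list(spectra)
    if not spectra:
        raise DataError("need at least one spectrum")
    n = len(spectra[0])
    if any(len(s) != n for s in spectra):
        raise DataError("mixed spectrum lengths")
    mat = np.stack([s.normalised("unit-sum").intensities for s in spectra])
    if mode == "pointwise":
        med = np.median(np.stack([s.intensities for s in spectra]), axis=0)
        return EmissionSpectrum(component_id=spectra[0].component_id,
                                intensities=med,
                                excitation_nm=spectra[0].excitation_nm)
    if mode != "medoid":
        raise ValueError("mode must be 'medoid' or 'pointwise'")
    d = np.linalg.norm(mat[:, None, :] - mat[None, :, :], axis=2)
    return spectra[int(np.argmin(d.sum(axis=1)))]


# ---------------------------------------------------------------------------
# fingerprint text I/O (2-column: wavelength nm, intensity)


def write_spectrum(spectrum: EmissionSpectrum, wavelengths_nm, path) -> None:
    wavelengths_nm = np.asarray(wavelengths_nm, dtype=float)
    if wavelengths_nm.size != len(spectrum):
        raise DataError("wavelength axis must match spectrum length")
    with open(path, "w") as fh:
        fh.write(f"# component: {spectrum.component_id}\n")
        if spectrum.excitation_nm is not None:
            fh.write(f"# excitation_nm: {spectrum.excitation_nm}\n")
        fh.write("wavelength_nm\tintensity\n")
        for w, v in zip(wavelengths_nm, spectrum.intensities):
            fh.write(f"{w:.6g}\t{v:.10g}\n")


def read_spectrum(path) -> tuple[EmissionSpectrum, np.ndarray]:
    """Read a 2-column fingerprint file; returns (spectrum, wavelengths)."""
    component, excitation = None, None
    wl, vals = [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line.lstrip("# ").partition(":")
                if key.strip() == "component":
                    component = val.strip()
                elif key.strip() == "excitation_nm":
                    excitation = float(val)
                continue
            parts = line.replace(",", "\t").split()
            if parts[0].lower().startswith("wavelength"):
                continue
            wl.append(float(parts[0]))
            vals.append(float(parts[1]))
    if component is None:
        raise DataError(f"{path}: header must name the component ('# component: ...')")
    return (EmissionSpectrum(component_id=component, intensities=np.asarray(vals),
                             excitation_nm=excitation),
            np.asarray(wl))
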