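"""Run configuration: defaults, file loading, resolution and provenance.

Every setting has exactly one source per run -- CLI override, config file,
or documented default -- and the resolved value is logged with that source
so a run is fully reconstructable from its log.  Config files may be TOML
or YAML (by extension).
"""

from __future__ import annotations

import copy
from pathlib import Path

from .errors import ConfigurationError

DEFAULTS: dict = {
    "geometry": {
        "slice_interval_um": 2.35,
        "optical_slice_um": 4.7,
        "depth_step_um": 2.35,       # Eq-1 depth step (acquisition interval)
        "plot_depth_step_um": 4.7,   # depth axis of area-distribution plots
        "image_area_um2": None,      # None -> from stack geometry
        "water_side": None,          # None -> must come from stack metadata
        "field_width_um": 420.0,
        "field_height_um": 420.0,
        "pixel_size_um": None,       # None -> field width / pixel count
    },
    "threshold": {
        "alpha": 0.05,
        "min_window": 10,
        "step": 10,
    },
    "unmixing": {
        "nonnegative": True,
    },
    "fingerprint": {
        "height_cutoff": 50.0,
        "marker": "T-RF",
        "abundance_cutoff": 0.005,
        "align_tolerance_nt": 0.5,
        "anosim_permutations": 9999,
        "simprof_permutations": 20000,
        "alpha": 0.05,
        "renormalise": True,
        "seed": 0,
    },
}

#: provenance notes echoed in the run log for every constant that came from
#: the imaging / fingerprinting protocol this package implements
PROVENANCE = {
    ("geometry", "slice_interval_um"): "acquisition interval between slices",
    ("geometry", "optical_slice_um"): "confocal optical section depth dZ",
    ("geometry", "depth_step_um"): "volume depth step (dZ/2, Nyquist spacing)",
    ("geometry", "plot_depth_step_um"): "depth-axis step of distribution plots",
    ("geometry", "field_width_um"): "field of view width",
    ("geometry", "field_height_um"): "field of view height",
    ("threshold", "alpha"): "Kruskal-Wallis plateau significance level",
    ("threshold", "min_window"): "minimum plateau length in thresholds",
    ("fingerprint", "height_cutoff"): "peak-height noise cutoff (fluorescence units)",
    ("fingerprint", "abundance_cutoff"): "exclude fragments <0.5% of profile",
    ("fingerprint", "align_tolerance_nt"): "fragment alignment confidence interval",
    ("fingerprint", "simprof_permutations"): "SIMPROF permutation count",
}


def load_config_file(path) -> dict:
    """Read a TOML or YAML config file into a nested dict."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    text = path.read_text()
    if path.suffix.lower() == ".toml":
        import tomllib
        try:
            return tomllib.loads(text)
        except tomllib.TOMLDecodeError as exc:
            raise ConfigurationError(f"invalid TOML in {path}: {exc}") from exc
    import yaml
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"invalid YAML in {path}: {exc}") from exc
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return data


def resolve_config(file_cfg: dict | None = None,
                   cli_overrides: dict | None = None) -> tuple[dict, list]:
    """Merge defaults < config file < CLI overrides.

    Returns (resolved nested dict, log lines).  Unknown keys raise.
    """
    resolved = copy.deepcopy(DEFAULTS)
    sources = {(b, k): "default" for b in DEFAULTS for k in DEFAULTS[b]}
    for layer, name in ((file_cfg or {}, "config-file"),
                        (cli_overrides or {}, "cli")):
        for block, entries in layer.items():
            if block not in resolved:
                raise ConfigurationError(f"unknown config block {block!r}")
            if not isinstance(entries, dict):
                raise ConfigurationError(f"config block {block!r} must be a mapping")
            for key, val in entries.items():
                if key not in resolved[block]:
                    raise ConfigurationError(f"unknown config key {block}.{key}")
                resolved[block][key] = val
                sources[(block, key)] = name
    log = []
    for block in resolved:
        for key, val in resolved[block].items():
            note = PROVENANCE.get((block, key))
            suffix = f"  [{note}]" if note else ""
            log.append(f"{block}.{key} = {val!r} ({sources[(block, key)]}){suffix}")
    return resolved, log
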