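"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration errors -> 2,
data errors -> 3, anything else (internal) -> 4.
"""


class BiofilmDIAError(Exception):
    """Base class for package errors."""


class ConfigurationError(BiofilmDIAError):
    """Invalid or incomplete run configuration."""


class DataError(BiofilmDIAError):
    """Input data violates a documented contract."""


class GeometryError(DataError):
    """Missing or inconsistent stack geometry."""


class PlateauNotFoundError(DataError):
    """No threshold-insensitive plateau of the required length exists;
    the coverage curves need manual review."""
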