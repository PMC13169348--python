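"""Exception hierarchy."""


class EnrefError(Exception):
    """Base class for all errors raised by this package."""


class XYZParseError(EnrefError):
    """A frame of a multi-structure XYZ file could not be parsed."""


class StructureError(EnrefError):
    """Inconsistent atom counts/symbols across frames, or a degenerate geometry."""


class DataError(EnrefError):
    """A conformer is missing data (energy, B norm, ...) required by an operation."""


class ConfigError(EnrefError):
    """Invalid protocol, thresholds, or calculator configuration."""


class SpectrumError(EnrefError):
    """Invalid spectral parameters, windows, or non-overlapping grids."""
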