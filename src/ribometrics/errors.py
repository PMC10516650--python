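"""Exception hierarchy shared across the package."""


class RibometricsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(RibometricsError):
    """A coordinate file could not be parsed."""


class MapFormatError(RibometricsError):
    """A density-map file is not a supported MRC/CCP4 variant."""


class DegenerateInputError(RibometricsError):
    """An input is formally valid but makes the requested quantity undefined
    (empty correlation mask, zero variance, collinear point set, ...)."""


class InsufficientPairsError(RibometricsError):
    """Fewer paired atoms than a superposition requires."""


class ConfigurationError(RibometricsError):
    """A parameter table is missing a required entry (e.g. a vdW radius)."""
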