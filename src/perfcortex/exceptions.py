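"""Exception hierarchy for the perfcortex pipeline."""


class PerfcortexError(Exception):
    """Base class for all pipeline errors."""


class VolumeParseError(PerfcortexError):
    """A file could not be read as a NIfTI volume."""


class ShapeError(PerfcortexError, ValueError):
    """Arrays do not share the expected grid shape or dimensionality."""


class SchemaError(PerfcortexError, ValueError):
    """A tabular input is missing mandatory columns or is otherwise malformed."""


class ConfigurationError(PerfcortexError, ValueError):
    """A configuration value is outside its admissible range."""


class DomainError(PerfcortexError, ValueError):
    """A numeric argument is outside the physical domain of the model."""


class DegenerateInputError(PerfcortexError, ValueError):
    """A statistical routine received an input on which it is undefined."""


class CollinearityError(DegenerateInputError):
    """Regression design matrix is numerically rank deficient."""
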