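"""Exception hierarchy shared across the package."""


class HyperbinError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HyperbinError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateInputError(HyperbinError, ValueError):
    """An input is structurally valid but carries no usable signal
    (e.g. a k-mer profile with zero total counts)."""


class InconsistencyError(HyperbinError, ValueError):
    """Two inputs that must agree do not (e.g. a profile whose counts are
    not contained in the corpus statistics it is weighted against)."""


class ConfigurationError(HyperbinError, ValueError):
    """A configuration combination is incomplete or contradictory."""


class FastaParseError(HyperbinError, ValueError):
    """A FASTA file could not be parsed; carries the offending line number."""


class LineageValidationError(HyperbinError, ValueError):
    """A lineage table row violates the ranked no-gap rule."""


class ModelFormatError(HyperbinError, ValueError):
    """A serialized model file is missing, truncated, or of a wrong version."""
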