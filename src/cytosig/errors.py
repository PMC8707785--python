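"""Exception hierarchy."""


class CytosigError(Exception):
    """Base class for all package errors."""


class FormatError(CytosigError):
    """A file does not have the expected structure (e.g. missing column)."""


class ValidationError(CytosigError):
    """Structurally valid input that violates a study invariant."""


class ConfigurationError(CytosigError):
    """Invalid configuration (generator, limits, pipeline)."""


class QcFailure(CytosigError):
    """Raised under strict QC when a control check fails."""


class NoCoverError(CytosigError):
    """A stimulus with no induced cytokine makes a covering panel impossible."""
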