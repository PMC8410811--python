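"""Exception hierarchy shared across the analysis modules."""


class AmdtoxError(Exception):
    """Base class for all package errors."""


class ReferenceDataError(AmdtoxError):
    """A background concentration, toxic-response factor or PNEC is missing
    or non-positive for an analyte that needs it."""


class ConfigurationError(AmdtoxError):
    """An analysis was configured inconsistently (e.g. an enrichment-factor
    reference element with no measured concentration)."""


class SchemeCoverageError(AmdtoxError):
    """A classification scheme does not assign exactly one label to a value."""


class TableFormatError(AmdtoxError):
    """A TSV input does not match its declared dialect."""


class EmptySampleError(AmdtoxError):
    """A community sample contains no reads."""
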