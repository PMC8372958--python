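"""Exception hierarchy for the cytogate pipeline."""


class CytogateError(Exception):
    """Base class for all cytogate errors."""


class UnsupportedFormatError(CytogateError):
    """FCS file declares a version or data layout this reader does not handle."""


class IntegrityError(CytogateError):
    """File contents contradict the file's own declared structure."""


class FCSParseError(CytogateError):
    """TEXT segment unparseable or a mandatory keyword is missing."""


class InvalidInputError(CytogateError, ValueError):
    """Caller-supplied values violate an operation's preconditions."""


class ConfigurationError(CytogateError):
    """Batch directory or configuration does not satisfy the pipeline's conventions."""


class SchemaError(CytogateError):
    """An event table lacks a channel an operation requires."""


class DataError(CytogateError):
    """Data present but unusable (too few events, empty pool, ...)."""


class FitFailureError(CytogateError):
    """Every EM initialization diverged or collapsed."""


class CalibrationError(CytogateError):
    """Bead calibration could not produce a valid monotone linear map."""
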