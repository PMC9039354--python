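"""Exception hierarchy shared across the pipeline."""


class LiverAuditError(Exception):
    """Base class for all package errors."""


class ParseError(LiverAuditError):
    """A file could not be parsed (malformed row, wrong arity, empty file)."""


class ValidationError(LiverAuditError):
    """A value violated a domain constraint (unknown sex token, bad label)."""


class StateError(LiverAuditError):
    """An operation was applied to a cohort in the wrong preprocessing state."""


class ImputationError(LiverAuditError):
    """No imputation statistic could be computed (column entirely missing)."""


class ParameterError(LiverAuditError):
    """A resampling parameter is inconsistent with the data it is applied to."""


class SplitError(LiverAuditError):
    """A train/test split could not satisfy its representation constraints."""


class FitError(LiverAuditError):
    """A learner could not be fitted (e.g. single-class training fold)."""


class ConfigurationError(LiverAuditError):
    """An experiment or feature-selection configuration is invalid."""


class DegenerateRunsError(LiverAuditError):
    """Too many repeated runs were flagged degenerate; the audit aborted."""
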