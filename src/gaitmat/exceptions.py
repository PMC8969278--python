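"""Exception hierarchy for gaitmat."""


class GaitmatError(Exception):
    """Base class for all gaitmat errors."""


class FormatError(GaitmatError):
    """A raw export file cannot be mapped onto the expected columns."""


class RowParseError(GaitmatError):
    """A single row of a raw export could not be parsed.

    Carries the 1-based file line number in ``line``.
    """

    def __init__(self, message, line=None):
        super().__init__(message)
        self.line = line


class LinkageError(GaitmatError):
    """A sensor point references a pass that is absent from the metadata."""


class GenerationError(GaitmatError):
    """The synthetic generator was asked to produce infeasible geometry."""


class ProfileValidationError(GaitmatError):
    """A gait profile violates its own feasibility constraints."""


class DegenerateFootprintError(GaitmatError):
    """A footprint has too few / collinear points to support geometry."""


class ParameterError(GaitmatError):
    """An operation was called with parameters outside its contract."""


class CurveError(GaitmatError):
    """ROC/PR curves are undefined (e.g. a single class present)."""
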