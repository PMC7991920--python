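"""Exception hierarchy for the perimetry engine."""


class PerimetryError(Exception):
    """Base class for all engine errors."""


class DomainError(PerimetryError, ValueError):
    """An argument is outside its documented domain."""


class CalibrationIntegrityError(PerimetryError):
    """Measured luminance decreases with gray level."""


class IncompleteCurveError(PerimetryError):
    """Calibration table lacks the gray 0 or gray 255 endpoint."""


class DuplicateKnotError(PerimetryError):
    """Calibration table repeats a gray level."""


class OutOfGamutError(PerimetryError):
    """Requested luminance exceeds the display maximum."""


class UnsupportedPatternError(PerimetryError):
    """Unknown test-pattern name."""


class UnsupportedStimulusError(PerimetryError):
    """Unknown Goldmann stimulus size label."""


class MembershipError(PerimetryError):
    """Location is not part of the pattern."""


class ExhaustedStaircaseError(PerimetryError):
    """A finished staircase was asked for another presentation."""


class IncompleteStaircaseError(PerimetryError):
    """Threshold estimate requested before the staircase finished."""


class IneligibleLocationError(PerimetryError):
    """False-negative probe requested at a location never seen."""


class RunawaySessionError(PerimetryError):
    """Session exceeded the safety cap on presentations."""


class LogIntegrityError(PerimetryError):
    """Event log is malformed (sequence gaps, inconsistent levels, ...)."""


class PatternMismatchError(PerimetryError):
    """Normative model and result cover different patterns/locations."""


class DegenerateCohortError(PerimetryError):
    """Normative cohort has zero variance at some location."""


class IncompleteResultError(PerimetryError):
    """A report statistic was requested from an incomplete threshold map."""


class ReportSchemaError(PerimetryError):
    """Report document violates the published schema."""
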