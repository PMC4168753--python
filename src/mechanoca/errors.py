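"""Exception hierarchy for the mechanoca pipeline.

Every error raised by the package derives from :class:`MechanoCaError`.
The CLI maps :class:`SchemaError` (and subclasses) to exit code 2 and all
other package errors to exit code 3.
"""


class MechanoCaError(Exception):
    """Base class for all package errors."""


class InvalidMetadataError(MechanoCaError):
    """Probe metadata violates an invariant (e.g. non-positive spring constant)."""


class MalformedCurveError(MechanoCaError):
    """A force curve violates a structural invariant (non-monotone time,
    degenerate segments, mismatched lengths)."""


class PreconditionError(MechanoCaError):
    """An operation was called before its prerequisite stage ran."""


class GeometryError(MechanoCaError):
    """An ROI or window lies (partly) outside the data it indexes."""


class DegenerateTraceError(MechanoCaError):
    """A trace cannot be normalized (non-positive baseline)."""


class CorrectionFailedError(MechanoCaError):
    """An artifact-correction fit failed; carries the uncorrected trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


class CoverageError(MechanoCaError):
    """The deflection record does not span the fluorescence trace."""


class AlignmentUndefinedError(MechanoCaError):
    """Timebase alignment is undefined (flat input or lag outside window)."""


class NoiseUndefinedError(MechanoCaError):
    """No linear portion of the required length exists for noise estimation."""


class ScheduleError(MechanoCaError):
    """A stimulation schedule is inconsistent with the recording span."""


class ConfigError(MechanoCaError):
    """A generator or pipeline configuration violates an invariant."""


class InsufficientDataError(MechanoCaError):
    """Too few observations for the requested statistic."""


class FitFailedError(MechanoCaError):
    """A nonlinear fit failed to converge or is unidentifiable."""


class InvalidTableError(MechanoCaError):
    """A contingency table contains negative or non-integer counts."""


class SchemaError(MechanoCaError):
    """An input file does not match the documented schema."""


class UnsupportedFormatError(SchemaError):
    """An input file is in a format the reader does not accept (e.g. RGB TIFF)."""


class PipelineError(MechanoCaError):
    """The manifest-driven pipeline produced no usable cells."""
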