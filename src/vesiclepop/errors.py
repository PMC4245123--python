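"""Exception hierarchy for the vesiclepop pipeline."""


class VesiclepopError(Exception):
    """Base class for all package errors."""


class ParameterError(VesiclepopError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class DataError(VesiclepopError, ValueError):
    """Input data violates a precondition (e.g. non-positive diameters)."""


class InputError(VesiclepopError, OSError):
    """A required input file or directory is missing or unreadable."""


class AggregationError(VesiclepopError, ValueError):
    """Too few samples to aggregate (population statistics need >= 2 chambers)."""


class CorrectionError(VesiclepopError, ValueError):
    """A correction edit references a label that does not exist."""


class MeasurementError(VesiclepopError, ValueError):
    """An object could not be measured (degenerate contour)."""


class PipelineError(VesiclepopError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""
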