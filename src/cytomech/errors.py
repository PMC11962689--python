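"""Exception hierarchy for cytomech.

Every failure mode raised by the library derives from :class:`CytomechError`
so callers can catch the package's errors with a single except clause.
"""


class CytomechError(Exception):
    """Base class for all cytomech errors."""


class SchemaError(CytomechError):
    """A container file is missing a required field or attribute."""


class CorruptRecordError(CytomechError):
    """A container record violates a structural invariant (e.g. length mismatch)."""


class UnsupportedFormatError(CytomechError):
    """An input file is in a format the reader does not handle."""


class GenerationError(CytomechError):
    """A synthetic-data spec cannot be realised (e.g. setpoint unreachable)."""


class PlacementError(GenerationError):
    """Requested particles cannot be placed without overlap."""


class NoContactError(CytomechError):
    """No tip-sample contact crossing was found in an approach curve."""


class DegenerateCurveError(NoContactError):
    """A curve carries no usable signal (e.g. identically zero deflection)."""


class InsufficientIndentationError(CytomechError):
    """Fewer than the minimum number of valid post-contact points."""


class TopographyQualityError(CytomechError):
    """Too many pixels failed contact detection to build a height map."""


class InvalidRadiusError(CytomechError):
    """The effective tip radius model evaluates to R <= 0 somewhere."""


class CollinearityError(CytomechError):
    """The two force-law basis functions are numerically collinear."""


class InitializationError(CytomechError):
    """The Monte-Carlo tip search was started from inadmissible coefficients."""


class SearchFailureError(CytomechError):
    """The Monte-Carlo tip search could not find any admissible proposal."""


class InsufficientDataError(CytomechError):
    """Too few values survive filtering to compute a summary."""


class AmbiguousMaskError(CytomechError):
    """A shape measurement was requested on a multi-component mask."""


class ZeroEnergyError(CytomechError):
    """An orientation histogram was requested on a constant image region."""


class UndefinedStatisticError(CytomechError):
    """A test statistic is undefined for the given samples."""


class PipelineStageError(CytomechError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
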