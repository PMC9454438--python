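"""Exception hierarchy shared across the package."""


class HipCongruencyError(Exception):
    """Base class for all package errors."""


class ParameterError(HipCongruencyError, ValueError):
    """A scalar parameter violates its contract (e.g. negative radius)."""


class InvalidPolygonError(HipCongruencyError, ValueError):
    """A polygon fails validation: too few vertices, non-finite or duplicate
    consecutive coordinates, or self-intersection."""


class DegenerateAnnotationError(HipCongruencyError, ValueError):
    """An annotation cannot be measured (e.g. zero-area acetabulum)."""


class DegenerateLandmarkError(HipCongruencyError, ValueError):
    """Coincident landmark points make an angle undefined."""


class InvalidAnnotationError(HipCongruencyError, ValueError):
    """An annotation file violates the schema (bad shape, bad label use)."""


class IncompleteSideError(InvalidAnnotationError):
    """A side present in an annotation file is missing its acetabulum or
    femoral head polygon."""


class SampleSizeError(HipCongruencyError, ValueError):
    """Too few observations or groups for the requested statistic."""


class IncompleteDataError(HipCongruencyError, ValueError):
    """A ratings matrix contains missing cells."""


class DegenerateVarianceError(HipCongruencyError, ValueError):
    """A group has zero variance where a variance-based test requires it."""


class GenerationError(HipCongruencyError, RuntimeError):
    """Synthetic generation failed (e.g. jitter could not produce a simple
    polygon within the retry budget)."""
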