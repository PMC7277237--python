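"""Exception hierarchy for molaraxis.

All library errors derive from :class:`MolarAxisError` so callers can catch
one base class; subclasses mirror the failure modes of the pipeline stages
(annotation parsing, geometry, landmark seeding, iterative refinement,
statistics).
"""


class MolarAxisError(Exception):
    """Base class for all molaraxis errors."""


class AnnotationError(MolarAxisError):
    """Malformed or unsupported annotation input (label map, LabelMe JSON)."""


class UnknownLabelError(AnnotationError):
    """Label-map index or shape label not covered by the label table."""


class GeometryError(MolarAxisError):
    """Invalid polygon geometry (self-intersecting, degenerate)."""


class EmptyMaskError(MolarAxisError):
    """Operation requires a non-empty binary mask."""


class DegenerateMaskError(MolarAxisError):
    """Mask too thin for landmark estimation (< 3 occupied rows)."""


class UndefinedAxisError(MolarAxisError):
    """Landmark pair is coincident; no axis direction defined."""


class ParameterError(MolarAxisError):
    """Invalid phantom shape or noise parameters."""


class CanvasError(MolarAxisError):
    """Phantom does not fit the requested canvas."""


class PlacementError(MolarAxisError):
    """Scene placement failed after retries (overlapping instances)."""


class CensorError(MolarAxisError):
    """Censoring band retains too few contour rows."""


class SplitError(MolarAxisError):
    """Side splitting needs at least two occupied contour rows."""


class FitError(MolarAxisError):
    """Side-line regression needs >= 2 points with distinct y."""


class RefinementError(MolarAxisError):
    """Iterative orientation refinement failed; carries the iteration index."""

    def __init__(self, message: str, iteration: int | None = None):
        super().__init__(message)
        self.iteration = iteration


class ShapeMismatchError(MolarAxisError):
    """Mask pair dimensions differ."""


class SampleSizeError(MolarAxisError):
    """Too few paired observations for the requested statistic."""


class MissingDataError(MolarAxisError):
    """Incomplete ratings table for ICC."""


class StageError(MolarAxisError):
    """Demirjian stage letter outside A-H."""


class AngleDomainError(MolarAxisError):
    """Angle magnitude outside [0, 90] degrees."""
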