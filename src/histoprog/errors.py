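"""Exception hierarchy for the histoprog pipeline.

Every stage raises a subclass of :class:`HistoprogError` so callers can catch
pipeline failures without masking programming errors.
"""


class HistoprogError(Exception):
    """Base class for all histoprog errors."""


class ImageLoadError(HistoprogError):
    """An image file could not be read or decoded."""


class ParameterError(HistoprogError, ValueError):
    """An operation received an out-of-range or inconsistent parameter."""


class StainEstimationError(HistoprogError):
    """Base class for stain-matrix estimation failures."""


class InsufficientTissueError(StainEstimationError):
    """Too few tissue (high optical density) pixels to estimate stains."""


class DegenerateStainError(StainEstimationError):
    """The optical-density cloud is effectively one-dimensional (one stain)."""


class CropSizeError(HistoprogError):
    """Requested crop does not fit inside the source image."""


class LabelError(HistoprogError):
    """Class labels unusable for the requested analysis (e.g. single class)."""


class NoEventsError(HistoprogError):
    """Survival data contain no (or too few) observed events."""


class UndefinedConcordanceError(HistoprogError):
    """No comparable pairs; the concordance index is undefined."""


class DegenerateFeatureError(HistoprogError):
    """A feature is (near-)constant and cannot enter a regression."""


class DegenerateClusteringError(HistoprogError):
    """All points identical; clustering metrics are undefined."""


class AlignmentError(HistoprogError):
    """Two sample-indexed tables share too few sample ids."""


class IPLParseError(HistoprogError):
    """A pathway-entity identifier does not follow '<index>_<concept>'."""


class GroupSizeError(HistoprogError):
    """A group has too few samples for the requested test."""


class SimulationSpecError(HistoprogError, ValueError):
    """A synthetic-data specification is internally inconsistent."""


class ConfigError(HistoprogError, ValueError):
    """Pipeline configuration failed validation."""
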