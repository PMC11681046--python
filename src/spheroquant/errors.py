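"""Exception types raised across the pipeline.

All inherit from :class:`SpheroquantError` so batch drivers can isolate
per-spheroid failures without swallowing programming errors.
"""


class SpheroquantError(Exception):
    """Base class for all pipeline errors."""


class ImageFormatError(SpheroquantError):
    """Input image has an unsupported layout (e.g. multi-channel without a selector)."""


class DimensionError(SpheroquantError):
    """Arrays that must share a shape do not."""


class EmptyMaskError(SpheroquantError):
    """An operation requiring foreground pixels received an empty mask."""


class DegenerateSpheroidError(SpheroquantError):
    """The largest connected component is too small to be a spheroid."""


class UndefinedAngleError(SpheroquantError):
    """Angle requested for a point coincident with the centroid."""


class InsufficientDataError(SpheroquantError):
    """Too few points for the requested statistic (e.g. PCA on <2 pixels)."""
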