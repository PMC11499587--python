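"""Exception hierarchy shared across the toolkit."""


class PlotPhenoError(Exception):
    """Base class for all toolkit errors."""


class RasterSizeError(PlotPhenoError):
    """Requested raster exceeds the configured pixel budget."""


class OrientationUndeterminedError(PlotPhenoError):
    """Too few vegetated components to estimate the grid angle."""


class FrameError(PlotPhenoError):
    """Detections from incompatible coordinate frames were mixed."""


class FormatError(PlotPhenoError):
    """Unsupported or malformed input format."""


class ParseError(FormatError):
    """Malformed annotation file; message names the offending record."""


class InsufficientGridError(PlotPhenoError):
    """Fewer centers than needed to recover a plot grid."""


class GridUndeterminedError(PlotPhenoError):
    """Fitted lines yield no usable intersections."""


class BoundsError(PlotPhenoError):
    """Requested region lies outside the raster."""


class IncompleteHeadingError(PlotPhenoError):
    """Heading-ratio series never brackets the requested crossing."""


class UndefinedMetricError(PlotPhenoError):
    """Metric undefined for the given inputs (e.g. AP without ground truth)."""


class PipelineStageError(PlotPhenoError):
    """Wraps a failure inside segment_plots, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
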