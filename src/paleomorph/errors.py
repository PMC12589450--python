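"""Exception hierarchy shared across the package."""


class PaleomorphError(Exception):
    """Base class for all package-specific errors."""


class TPSParseError(PaleomorphError, ValueError):
    """A TPS record is malformed (bad LM=/POINTS= counts, stray tokens...)."""


class StructureError(PaleomorphError, ValueError):
    """Configurations in one dataset disagree in landmark/curve structure."""


class DegenerateShapeError(PaleomorphError, ValueError):
    """All landmarks coincide; centroid size is zero."""


class DegenerateCurveError(PaleomorphError, ValueError):
    """A digitized curve has zero arc length and cannot be resampled."""


class DegenerateDataError(PaleomorphError, ValueError):
    """Too few observations for the requested statistic."""


class PipelineStageError(PaleomorphError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
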