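"""Exception types shared across the package."""


class NetprofilerError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(NetprofilerError, ValueError):
    """A parameter value violates its contract (non-positive bandwidth, k >= n, ...)."""


class DegenerateInputError(NetprofilerError, ValueError):
    """Input is structurally valid but degenerate (constant modulator, zero-variance gene, ...)."""


class DegenerateWeightsError(NetprofilerError, ValueError):
    """Kernel weights are unusable for fitting (all zero, or fewer than two positive)."""


class DegenerateLabelingError(NetprofilerError, ValueError):
    """Percentile labeling produced fewer than two samples in a class."""


class AlignmentError(NetprofilerError, ValueError):
    """Sample or gene identifiers of two inputs do not align."""


class PipelineStageError(NetprofilerError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {message}")
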