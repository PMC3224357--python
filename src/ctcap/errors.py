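"""Exception hierarchy for the ctcap package."""


class CtcapError(Exception):
    """Base class for all package errors."""


class InvalidMeasurementError(CtcapError, ValueError):
    """A physical measurement (height, weight, dose, CTDI) is non-positive,
    non-finite, or otherwise unusable."""


class ConfigurationError(CtcapError, ValueError):
    """A configuration (population ranges, protocol, geometry) is inconsistent."""


class InvalidPitchError(CtcapError, ValueError):
    """Helical pitch must be strictly positive."""


class SpectrumInfeasibleError(CtcapError, ValueError):
    """The requested beam quality cannot be reached at the given tube potential."""


class BatchingError(CtcapError, ValueError):
    """Photon count incompatible with the requested batch statistics."""


class IncompleteTableError(CtcapError, KeyError):
    """An organ-dose table is missing an organ required by the weighting scheme."""

    def __init__(self, organ: str):
        super().__init__(organ)
        self.organ = organ

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"organ dose table is missing required organ: {self.organ!r}"


class UndefinedComparisonError(CtcapError, ValueError):
    """Percent difference is undefined when the mean of the operands is <= 0."""


class SingularDesignError(CtcapError, ValueError):
    """Regression design matrix is rank deficient."""


class InsufficientDataError(CtcapError, ValueError):
    """Not enough paired observations for the requested statistic."""


class GenerationError(CtcapError, RuntimeError):
    """Synthetic-data generation could not satisfy its constraints."""


class PipelineStageError(CtcapError, RuntimeError):
    """A pipeline stage failed; carries the stage name and the original error."""

    def __init__(self, stage: str, original: BaseException):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage
        self.original = original
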