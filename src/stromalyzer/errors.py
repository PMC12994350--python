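"""Exception hierarchy.

Every failure mode named in a module contract gets its own type so callers
(and the CLI exit-code mapping) can distinguish validation problems from
stage failures.
"""


class StromalyzerError(Exception):
    """Base class for all package errors."""


class ParameterError(StromalyzerError, ValueError):
    """An argument violates a precondition (bad threshold, size, spacing...)."""


class InvalidClassError(ParameterError):
    """A class code outside the known tissue legend."""


class SizeError(ParameterError):
    """A raster or patch dimension is too small."""


class InfeasibleSceneError(StromalyzerError):
    """A hot-spot scene request leaves no tumor+stroma pixels to place."""


class DegenerateReferenceError(StromalyzerError):
    """Stain-normalization reference contains no tissue (all near-white)."""


class MissingClassError(StromalyzerError):
    """Training data lacks one or more required tissue classes."""


class EmptyEvaluationError(StromalyzerError):
    """Evaluation region mask selects no pixels."""


class FoldError(StromalyzerError):
    """Cross-validation fold construction impossible (fewer slides than folds)."""


class OutOfBoundsError(StromalyzerError):
    """Requested hot-spot circle lies entirely outside the raster."""


class UndefinedTSRError(StromalyzerError):
    """No tumor or stroma pixels inside the circle: TSR has no denominator."""


class DegenerateKappaError(StromalyzerError):
    """Chance agreement equals 1; Cohen's kappa is undefined."""


class DegenerateICCError(StromalyzerError):
    """Zero total variance; the intraclass correlation is undefined."""


class StageFailure(StromalyzerError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
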