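"""Exception hierarchy shared across the pipeline.

``InvalidArgumentError`` subclasses ``ValueError`` so that generic argument
validation can be caught uniformly; the remaining classes mark conditions
that a caller may want to handle specifically (e.g. retry with a longer
baseline, or report a degenerate fit instead of aborting).
"""


class InvalidArgumentError(ValueError):
    """An argument violates a documented precondition."""


class InsufficientBaselineError(InvalidArgumentError):
    """Too few volume triggers in the pre-stimulus baseline to build a template."""


class OutOfRangeError(InvalidArgumentError):
    """A requested window extends beyond the recording bounds."""

    def __init__(self, message, offending_onsets=None):
        super().__init__(message)
        self.offending_onsets = list(offending_onsets) if offending_onsets else []


class DegenerateFitError(ArithmeticError):
    """The fit target carries no usable signal (e.g. all-zero fMRI epoch)."""


class DegenerateStandardizationError(ArithmeticError):
    """Zero variance within an experiment makes z-scoring undefined."""


class CharacterizationError(ArithmeticError):
    """The function handed to the kernel characterizer is not a single positive pulse."""
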