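"""Exception hierarchy shared across the package."""


class EdahabError(Exception):
    """Base class for package errors."""


class ParameterError(EdahabError, ValueError):
    """An argument violates a precondition (ranges, lengths, signs)."""


class ConfigurationError(EdahabError, ValueError):
    """Inputs are individually valid but jointly inconsistent
    (e.g. stimulus onsets so close their response windows overlap)."""


class DegenerateInputError(EdahabError, ValueError):
    """The computation is undefined on this input (zero variance,
    every point an outlier, ...)."""


class StaircaseConvergenceError(EdahabError, RuntimeError):
    """Repeat-until-agreement staircase failed to produce two consecutive
    equal pass thresholds within the allowed number of passes.

    Carries the completed passes in ``.passes`` for inspection.
    """

    def __init__(self, message, passes):
        super().__init__(message)
        self.passes = passes
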