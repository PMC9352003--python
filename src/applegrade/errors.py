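"""Exception hierarchy shared across the vision, chemometrics and grading layers."""


class AppleGradeError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(AppleGradeError, ValueError):
    """A parameter is outside its documented domain (e.g. gamma <= 0)."""


class EmptyMaskError(AppleGradeError, ValueError):
    """An operation requiring foreground pixels received an empty mask."""


class DegenerateInputError(AppleGradeError, ValueError):
    """Input is structurally valid but numerically degenerate
    (constant spectrum, zero-variance response, singular calibration...)."""


class RenderError(AppleGradeError, ValueError):
    """A synthetic fixture cannot be drawn (fruit larger than the frame)."""


class PairingError(AppleGradeError, ValueError):
    """Image and spectrum records could not be matched by sample id."""
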