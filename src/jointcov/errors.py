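"""Exception hierarchy.

Validation-type errors (bad inputs, malformed files) exit the CLI with
status 1; everything else raises as a runtime error (status 2).
"""


class JointcovError(Exception):
    """Base class for all package errors."""


class ValidationError(JointcovError):
    """Inputs violate a documented precondition."""


class FormatError(ValidationError):
    """A file does not follow the expected tabular dialect."""


class AlignmentError(ValidationError):
    """Tumor/normal/label inputs do not cover the same identifiers."""


class ImputationError(JointcovError):
    """A probe row cannot be imputed (e.g. entirely missing in one tissue)."""


class FitError(JointcovError):
    """A discriminant fit is impossible (group too small, non-finite data)."""


class SplitError(JointcovError):
    """Cross-validation splits cannot be formed or mostly degenerate."""


class ScreenError(JointcovError):
    """A screening operation received an unusable record set."""
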