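"""Exception hierarchy for panel validation and degenerate statistics."""


class CSSPanelError(Exception):
    """Base class for all csspanel errors."""


class FormatError(CSSPanelError):
    """A file is structurally malformed (e.g. a required column is missing)."""


class ValidationError(CSSPanelError):
    """Input data violates a panel invariant (unknown strain, duplicates...)."""


class ParameterError(CSSPanelError):
    """An argument is outside its admissible range."""


class PreconditionError(CSSPanelError):
    """A statistical operation was called on inputs it cannot handle
    (n < 2, undefined SD)."""


class DegenerateInputError(CSSPanelError):
    """Both groups have zero variance but different means: the t statistic
    is infinite and no finite p-value exists."""


class UndefinedNormalizerError(CSSPanelError):
    """The normalizing denominator (host-donor difference or panel range)
    is zero, so the effect size is undefined."""
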