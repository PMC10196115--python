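"""Exception hierarchy for painlfp.

All package errors derive from :class:`PainLFPError` so callers (and the
CLI) can distinguish user/input problems from genuine bugs.
"""


class PainLFPError(Exception):
    """Base class for all painlfp errors."""


class InvalidArgumentError(PainLFPError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(PainLFPError, ValueError):
    """Input is formally valid but statistically degenerate (e.g. zero variance)."""


class InsufficientDataError(PainLFPError, ValueError):
    """Not enough samples/trials for the requested computation."""


class TemplateInfeasibleError(PainLFPError, ValueError):
    """An evoked-potential template spec cannot realize its stated extrema."""


class UnusableHemisphereError(PainLFPError, ValueError):
    """A hemisphere has no retained channels."""


class SchemaError(PainLFPError, ValueError):
    """An on-disk container violates the package schema."""
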