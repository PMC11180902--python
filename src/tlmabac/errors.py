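"""Exception hierarchy.

Every error raised by the library derives from :class:`TlmabacError` and
carries a short machine-readable ``code`` used by the CLI for exit status
and structured error output.
"""


class TlmabacError(Exception):
    """Base class for all library errors."""

    code = "error"


class DomainError(TlmabacError):
    """An input value lies outside its mathematical domain."""

    code = "domain"


class ConstraintError(TlmabacError):
    """A fuzzy-number invariant or the rung-q constraint is violated."""

    code = "constraint"


class IncompatibleScaleError(TlmabacError):
    """Two operands live on different linguistic term scales."""

    code = "incompatible-scale"


class WeightPolicyError(TlmabacError):
    """A weight vector violates the configured weight policy."""

    code = "weight-policy"


class DimensionError(TlmabacError):
    """Array shapes / lengths do not agree."""

    code = "dimension"


class FormatError(TlmabacError):
    """A serialized cube, config or report cannot be parsed."""

    code = "format"


class InfeasibleSpecError(TlmabacError):
    """A generator spec admits no valid sample within the rejection budget."""

    code = "infeasible-spec"
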