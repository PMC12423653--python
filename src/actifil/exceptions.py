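"""Exception hierarchy for actifil."""


class ActifilError(Exception):
    """Base class for all actifil-specific errors."""


class InvalidParameterError(ActifilError, ValueError):
    """A parameter is outside its documented domain."""


class ConditioningError(ActifilError, ArithmeticError):
    """A linear system required by the solver is too ill-conditioned to trust."""


class RootNotFoundError(ActifilError, RuntimeError):
    """A bracketed root-find failed to locate a sign change."""


class ConstraintInfeasibleError(ActifilError, ValueError):
    """An optimization constraint set admits no feasible configuration."""
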