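"""Exception hierarchy shared across the package."""


class AmbigemError(Exception):
    """Base class for all package errors."""


class ValidationError(AmbigemError):
    """Input violates a documented invariant (bad model, bad table, bad config)."""


class FormatError(AmbigemError):
    """A file could not be parsed as the declared format."""


class MappingError(ValidationError):
    """Expression data cannot be mapped onto the model (e.g. no gene overlap)."""


class InfeasibleError(AmbigemError):
    """An optimization problem that should be feasible is not."""


class SolverError(AmbigemError):
    """The numerical backend failed or returned an unusable status."""
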