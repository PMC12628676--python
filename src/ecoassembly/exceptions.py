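"""Package exception hierarchy."""


class EcoAssemblyError(Exception):
    """Base class for all package errors."""


class ParameterError(EcoAssemblyError, ValueError):
    """A function argument is outside its documented range."""


class DataValidationError(EcoAssemblyError, ValueError):
    """An input table, tree or metadata frame violates an invariant."""


class CrossReferenceError(DataValidationError):
    """Identifiers fail to match across table, tree and metadata."""


class SignalGateError(EcoAssemblyError, RuntimeError):
    """The phylogenetic-signal prerequisite failed and --force was not given."""
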