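"""Exception taxonomy shared across the package."""


class NumericalError(RuntimeError):
    """A solver failed to converge; the message carries residual diagnostics."""


class ConfigError(ValueError):
    """A configuration file violated the schema."""


class UndefinedResultError(ValueError):
    """A quantity is mathematically undefined for the given input
    (e.g. a correlation of a zero-variance vector, an empty reference tumor)."""
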