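"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A model configuration file is missing a section or malformed."""


class ModelValidationError(ValueError):
    """A probability table violates stochasticity or shape constraints."""


class DecompositionError(ValueError):
    """The replication-rate table cannot be decomposed as requested."""


class EnumerationLimitError(RuntimeError):
    """An exhaustive history enumeration would exceed the size guard."""


class UnsupportedModelError(ValueError):
    """The operation requires model structure (e.g. memoryless sensing) absent here."""
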