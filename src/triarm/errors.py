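"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """An invalid generator/analysis configuration value."""


class DomainError(ValueError):
    """An input outside the clinical formula's domain (e.g. negative insulin)."""


class ParseError(ValueError):
    """A trial CSV that violates the schema (unknown arm, non-numeric cell)."""


class UnimputableError(ValueError):
    """A variable with no observed values cannot be imputed."""
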