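"""Exception types shared across the pipeline."""


class DomainError(ValueError):
    """Input outside the mathematical domain of an operation."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete configuration."""


class EmptyPlotError(ValueError):
    """A plot retained no usable pixels/points after masking."""


class SchemaError(ValueError):
    """Feature names, shapes or lengths do not line up."""
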