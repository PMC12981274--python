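"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input object violates its structural invariants."""


class ConfigurationError(ValueError):
    """A configuration value is inconsistent with the data or other settings."""


class NumericError(RuntimeError):
    """A numerical procedure (bisection, GLM fit) failed to converge."""


class ResourceError(RuntimeError):
    """A sampling or memory budget was exhausted."""
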