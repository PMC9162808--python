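"""Exception types shared across the package."""


class DomainError(ValueError):
    """An argument lies outside its physically meaningful domain."""


class ConfigurationError(ValueError):
    """A parameter combination is internally inconsistent (e.g. Nyquist
    violation, inadmissible transition-width ratio)."""


class DegenerateSignalError(ValueError):
    """The input signal carries no usable information (zero power,
    constant samples, empty frames)."""


class InsufficientCyclesError(ValueError):
    """Fewer complete cardiac cycles were found than the minimum required
    for index computation."""
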