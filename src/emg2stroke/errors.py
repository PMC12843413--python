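"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A parameter value violates a stage's preconditions (e.g. a filter
    frequency at or above Nyquist, a non-positive duration)."""


class DegenerateSignalError(ValueError):
    """The input signal is degenerate for the requested operation
    (e.g. constant signal passed to min-max normalization)."""


class ValidationError(ValueError):
    """A dataset- or cohort-level consistency check failed."""
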