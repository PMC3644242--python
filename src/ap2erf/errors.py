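"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A cohort or run configuration is internally inconsistent."""


class InputError(ValueError):
    """An input record is malformed (bad alphabet, ragged alignment, ...)."""
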