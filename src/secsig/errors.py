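"""Exception types shared across the pipeline stages."""


class ConfigurationError(ValueError):
    """An input configuration violates a stated invariant."""


class AnalysisError(RuntimeError):
    """A stage received data it cannot analyse (e.g. an all-zero sample)."""
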