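"""Exception types shared across the pipeline."""


class InputError(ValueError):
    """Invalid user-supplied data or configuration."""


class ComputationError(RuntimeError):
    """A numerical guard fired during analysis (degenerate model, zero denominator)."""
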