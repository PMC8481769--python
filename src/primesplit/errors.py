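"""Exception types shared across the pipeline."""


class ValidationError(ValueError):
    """An input table or record violates the documented schema or invariants."""


class DegenerateMixingError(ValueError):
    """The two isotopic end-members coincide; the mixing model cannot partition."""
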