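"""Exception types shared across the package."""


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


class DegenerateInputError(ValueError):
    """Raised when an input is formally valid but makes a statistic undefined
    (e.g. zero variance of the differential values, or all pairs tied)."""
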