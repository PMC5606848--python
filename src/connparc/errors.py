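"""Exception types shared across the package."""


class DegenerateInputError(ValueError):
    """Raised when an input is structurally valid but analytically degenerate.

    Examples: an all-zero affinity matrix fed to spectral clustering, or an
    empty union of binarized tract maps when building a maximum probability
    map. Subclasses :class:`ValueError` so callers that only distinguish
    "bad input" from "internal bug" need a single except clause.
    """
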