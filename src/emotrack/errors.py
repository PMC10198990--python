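"""Exception hierarchy for the emotrack pipeline."""


class EmotrackError(Exception):
    """Base class for all emotrack errors."""


class ValidationError(EmotrackError, ValueError):
    """Malformed input data or configuration."""


class StructuralError(ValidationError):
    """A rating table violates the structural contract (missing samples,
    mismatched time bases, too few raters)."""


class DegenerateInputError(EmotrackError, ValueError):
    """Input is structurally valid but statistically degenerate
    (e.g. all-constant rating matrix)."""


class UndefinedCorrelationError(DegenerateInputError):
    """A correlation is requested for a zero-variance series.  Callers in
    the pipeline record the cell as missing rather than inventing r = 0."""
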