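"""Exception types shared across the pipeline."""


class CarpetError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(CarpetError, ValueError):
    """Arguments violate a documented precondition."""


class DegenerateInputError(InvalidInputError):
    """Input is syntactically valid but statistically degenerate (e.g. zero variance)."""


class FormatError(CarpetError, ValueError):
    """A file does not conform to its declared dialect."""


class UndefinedMeanError(CarpetError):
    """An aggregate was requested over zero qualifying observations."""


class PlacementImpossibleError(CarpetError):
    """No valid genomic placement exists under the given constraints."""
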