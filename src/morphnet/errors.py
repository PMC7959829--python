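"""Exception hierarchy shared across the pipeline stages."""


class MorphnetError(Exception):
    """Base class for all morphnet errors."""


class FormatError(MorphnetError):
    """The input file does not conform to the expected tabular layout."""


class ValidationError(MorphnetError):
    """The input parses but violates a domain invariant."""


class EmptyInputError(ValidationError):
    """A table with no data rows was supplied."""


class DegenerateRangeError(MorphnetError):
    """Pooled value range has zero width; a histogram cannot be formed."""


class DisconnectedGraphError(MorphnetError):
    """No spanning tree exists on the positive-weight edges."""


class ModelSpecificationError(MorphnetError):
    """The regression design matrix is unusable (rank deficient or constant)."""
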