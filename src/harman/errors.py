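"""Exception hierarchy for the harman package."""


class HarmanError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(HarmanError):
    """A delimited input file contains a cell that cannot be interpreted."""


class ValidationError(HarmanError):
    """An input object violates a structural invariant (duplicates, empty batches...)."""


class MismatchError(ValidationError):
    """Matrix and design refer to different sample sets."""


class DegenerateInputError(HarmanError):
    """Input carries no usable variance (constant matrix, zero-spread scores)."""
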