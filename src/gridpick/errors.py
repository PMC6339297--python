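"""Exception hierarchy shared across the toolkit."""


class GridpickError(Exception):
    """Base class for all toolkit errors."""


class FormatError(GridpickError, ValueError):
    """A file does not parse under the declared dialect/container rules."""


class ValidationError(GridpickError, ValueError):
    """An in-memory object violates its invariants (non-finite values, out-of-range probabilities, ...)."""


class ShapeError(GridpickError, ValueError):
    """Array shapes are incompatible with the requested operation."""


class CapacityError(GridpickError, RuntimeError):
    """A randomized placement could not be satisfied within the attempt budget."""


class DomainError(GridpickError, ValueError):
    """The requested quantity is undefined for this input (e.g. SNR of a zero-signal image)."""
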