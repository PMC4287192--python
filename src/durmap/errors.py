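"""Package exception hierarchy.

All validation failures raised by durmap derive from :class:`DurmapError`,
so callers (and the CLI) can distinguish bad inputs from genuine bugs.
"""


class DurmapError(Exception):
    """Base class for all durmap errors."""


class ValidationError(DurmapError, ValueError):
    """An input violates a documented precondition."""


class EmptyResultError(DurmapError):
    """A stage produced nothing to work with (e.g. all markers filtered out)."""


class UndefinedEstimateError(DurmapError):
    """An estimate is undefined for the given data (e.g. zero informative meioses)."""
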