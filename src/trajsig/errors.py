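"""Exception hierarchy shared across the package."""


class TrajsigError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(TrajsigError, ValueError):
    """A caller supplied data that cannot be processed (non-finite, empty, ...)."""


class ContractError(TrajsigError, ValueError):
    """An internal interface contract was violated (mismatched shapes, names, ...)."""


class FormatError(TrajsigError, ValueError):
    """An input table does not have the expected layout."""
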