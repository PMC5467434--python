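"""Exception hierarchy shared across the package."""


class FlagtopoError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(FlagtopoError):
    """Input data violates a domain invariant (self-loop, duplicate edge, ...)."""


class ContractError(FlagtopoError):
    """An operation was called on an object that cannot support it
    (e.g. maximality on a dimension-truncated simplex table)."""


class ResourceBudgetError(FlagtopoError):
    """A computation would exceed its configured memory/size budget."""
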