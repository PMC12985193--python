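"""Exception hierarchy.

All anticipated failures raise a subclass of :class:`DistUQError` so callers
(and the CLI) can distinguish validated input problems from genuine bugs.
"""


class DistUQError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(DistUQError):
    """A table or config does not match the declared schema."""


class ValidationError(DistUQError):
    """Input data violates an invariant (duplicate ids, NaN features, ...)."""


class ContractError(DistUQError):
    """An operation was called outside its precondition."""
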