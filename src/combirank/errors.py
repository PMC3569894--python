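"""Exception hierarchy for combirank.

All pipeline-raised errors derive from :class:`CombirankError` so callers
(and the CLI) can distinguish domain failures from programming errors.
"""


class CombirankError(Exception):
    """Base class for all combirank errors."""


class SchemaError(CombirankError):
    """An input table is missing a mandatory column or is malformed."""


class ValidationError(CombirankError):
    """A record violates a domain invariant (duplicate id, bad Ki, ...)."""


class ConfigurationError(CombirankError):
    """A configuration object is inconsistent or incomplete."""


class UndefinedSimilarityError(CombirankError):
    """Functional-group similarity is undefined (an empty group set)."""


class UnsupportedArityError(CombirankError):
    """A candidate has more constituents than the method supports (max 3)."""
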