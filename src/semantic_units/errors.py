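"""Exception hierarchy. Every error raised by the package derives from
SemanticUnitsError so callers (and the CLI) can catch one base class."""


class SemanticUnitsError(Exception):
    pass


class NotFoundError(SemanticUnitsError, KeyError):
    """Unit, triple, or layer lookup failed."""


class SchemaError(SemanticUnitsError, ValueError):
    """Schema file or schema object violates the dialect invariants."""


class FormatError(SemanticUnitsError, ValueError):
    """Serialized input (Turtle/TriG/JSON) cannot be parsed or is malformed."""


class StateError(SemanticUnitsError, RuntimeError):
    """Operation requires a store state not yet established (e.g. partition)."""


class CycleError(SemanticUnitsError, ValueError):
    """Cyclic compound-unit membership."""


class UnresolvedMemberError(SemanticUnitsError, KeyError):
    """Compound unit references a UPRI not registered in the store."""


class UniquenessViolation(SemanticUnitsError, ValueError):
    """Set-list unit received a duplicate member."""


class CardinalityViolation(SemanticUnitsError, ValueError):
    """List-unit member count outside the declared cardinality bracket."""


class UnsupportedOperation(SemanticUnitsError, RuntimeError):
    """Operation not applicable to this unit (e.g. no display template)."""
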