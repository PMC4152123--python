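"""Exception hierarchy shared by all spnlab modules."""


class SpnLabError(Exception):
    """Base class for all spnlab errors."""


class IdentityCollisionError(SpnLabError):
    """An element id is already taken within its container."""


class DanglingEdgeError(SpnLabError):
    """An edge or arc references an endpoint that does not exist."""


class ValidationError(SpnLabError):
    """A model object violates its structural invariants."""


class MustFlattenError(SpnLabError):
    """An operation requiring a flat net was given a hierarchical one."""


class EmptyCoarsePlaceError(SpnLabError):
    """A coarse place expands to zero leaf places."""


class DisabledFireError(SpnLabError):
    """Attempt to fire a transition that is not enabled."""


class SchemaError(SpnLabError):
    """A document does not match the expected schema.

    ``path`` is a JSON-pointer-like location of the offending element.
    """

    def __init__(self, message: str, path: str = ""):
        super().__init__(f"{message} (at {path!r})" if path else message)
        self.path = path


class ParseError(SpnLabError):
    """A document could not be parsed at all."""


class EmptyInputError(ParseError):
    """The input document is empty."""


class UnsupportedVersionError(SchemaError):
    """The document declares a format version newer than this library supports."""


class BindingError(SpnLabError):
    """A template instantiation is missing a required binding site."""

    def __init__(self, site: str):
        super().__init__(f"missing required binding for site {site!r}")
        self.site = site


class CompositionError(SpnLabError):
    """Two nets cannot be composed (e.g. shared id with mismatched roles)."""


class DomainError(SpnLabError):
    """A numeric argument is outside its valid domain."""
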