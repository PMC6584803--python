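"""Exception hierarchy."""


class HexitopeError(Exception):
    """Base class for package errors."""


class StructureParseError(HexitopeError):
    """A coordinate file could not be parsed."""


class StructureError(HexitopeError):
    """Structure/trajectory contents violate an invariant (atom counts, keys)."""


class ConfigurationError(HexitopeError):
    """Entity/region/run configuration is incomplete or inconsistent."""


class LookupFailure(HexitopeError):
    """A residue, entity or region referenced by name does not exist."""
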