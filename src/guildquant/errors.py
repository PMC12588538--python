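"""Exception hierarchy shared across the package."""


class GuildQuantError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GuildQuantError):
    """A file does not conform to the expected table/tree/placement format."""


class ValidationError(GuildQuantError):
    """Parsed content violates a domain invariant (e.g. negative count)."""


class RangeError(GuildQuantError):
    """A scalar input falls outside its documented domain."""


class ReferenceLookupError(GuildQuantError):
    """A cross-reference (sample id, gene, tree edge) does not resolve."""


class InsufficientDataError(GuildQuantError):
    """Too few observations to perform the requested estimate."""


class DegenerateInputError(GuildQuantError):
    """Input is structurally valid but degenerate (all-zero, zero variance)."""


class ConfigError(GuildQuantError):
    """A simulation or analysis configuration violates its invariants."""


class AlignmentError(GuildQuantError):
    """Two objects that must share a grid/axis do not."""
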