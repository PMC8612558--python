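"""Exception hierarchy for the Area-of-Habitat pipeline."""


class AOHError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(AOHError, ValueError):
    """An argument violates a documented precondition."""


class FormatError(AOHError, ValueError):
    """An input file does not match the expected dialect."""


class ValidationError(AOHError, ValueError):
    """A record fails row-level validation (e.g. latitude out of range)."""


class SpeciesNotFoundError(AOHError, KeyError):
    """The requested species is absent from an input file."""


class DegenerateInputError(AOHError, ValueError):
    """Too few / too degenerate points for a geometric construction."""


class DegenerateSpeciesError(AOHError, ValueError):
    """A virtual species has no suitable habitat in its landscape."""


class EmptyPartitionError(AOHError, ValueError):
    """Neither presences nor absences exist: occupancy cannot be assigned."""
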