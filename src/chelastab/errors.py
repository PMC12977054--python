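"""Exception hierarchy.

Every failure mode promised by the public API raises a subclass of
:class:`ChelastabError`, so callers can catch the package's errors without
netting :class:`ValueError` raised by numpy et al.
"""


class ChelastabError(Exception):
    """Base class for all chelastab errors."""


class XYZFormatError(ChelastabError):
    """Malformed XYZ file: bad count line, wrong atom count, non-numeric field."""


class NoMetalAtomError(ChelastabError):
    """No atom from the configured metal set was found in the structure."""


class MultipleMetalAtomsError(ChelastabError):
    """More than one atom from the configured metal set was found."""


class UnknownElementError(ChelastabError):
    """Element symbol missing from the frozen atomic-data tables."""

    def __init__(self, symbol: str, table: str = "covalent radii"):
        self.symbol = symbol
        super().__init__(f"element {symbol!r} not present in the {table} table")


class StructureMismatchError(ChelastabError):
    """Two structures expected to be atom-by-atom equivalent are not."""


class EmptySelectionError(ChelastabError):
    """A filter or join produced no records."""


class ConvergenceError(ChelastabError):
    """Iterative procedure failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        self.last_iterate = last_iterate
        super().__init__(message)


class SingularComponentError(ChelastabError):
    """A mixture component collapsed (width below floor or coincident centers)."""


class NoInteriorMinimumError(ChelastabError):
    """Density profile has its minimum at an endpoint: no interior critical point."""


class FixtureIntegrityError(ChelastabError):
    """Packaged data file failed its checksum."""


class GenerationError(ChelastabError):
    """Synthetic generator could not place atoms without steric overlap."""
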