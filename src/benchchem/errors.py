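"""Exception hierarchy.

Every domain failure raises a subclass of :class:`BenchchemError` carrying a
short machine-greppable ``code``; the CLI prints ``code: message`` and exits 1.
"""


class BenchchemError(Exception):
    """Base class for all domain errors."""

    code = "ERR"

    def __str__(self) -> str:  # noqa: D105
        return super().__str__() or self.code


# -- chemgraph ---------------------------------------------------------------

class ElementError(BenchchemError):
    """Unknown chemical element symbol."""

    code = "ERR_ELEMENT"


class PseudoAtomError(BenchchemError):
    """A pseudo atom (Pol/Sur) appeared where a real element is required."""

    code = "ERR_PSEUDO_ATOM"


class EmptyFormulaError(BenchchemError):
    """Operation undefined for an empty formula."""

    code = "ERR_EMPTY_FORMULA"


class AromaticBondError(BenchchemError):
    """Aromatic bond orders must be kekulized before formula computation."""

    code = "ERR_AROMATIC_BOND"


class MoleculeError(BenchchemError):
    """Structural invariant of a molecule violated."""

    code = "ERR_MOLECULE"


# -- molfile_io --------------------------------------------------------------

class ParseError(BenchchemError):
    """Malformed molfile/SDF input; carries a line or record position."""

    code = "ERR_PARSE"

    def __init__(self, message: str, line: int | None = None,
                 record_index: int | None = None):
        super().__init__(message)
        self.line = line
        self.record_index = record_index

    def __str__(self) -> str:
        loc = ""
        if self.line is not None:
            loc = f" (line {self.line})"
        elif self.record_index is not None:
            loc = f" (record {self.record_index})"
        return f"{super().__str__()}{loc}"


class CapacityError(BenchchemError):
    """Molecule exceeds V2000 fixed-width capacity (999 atoms/bonds)."""

    code = "ERR_CAPACITY"


class DialectError(BenchchemError):
    """Feature not allowed by the selected molfile dialect."""

    code = "ERR_DIALECT"


# -- polymer_calc ------------------------------------------------------------

class SupportModelError(BenchchemError):
    """Supported molecule must contain exactly one singly-bonded pseudo atom."""

    code = "ERR_SUPPORT_MODEL"


class LoadingError(BenchchemError):
    """Loading/fragment combination is physically impossible."""

    code = "ERR_LOADING"


class DegenerateMassError(BenchchemError):
    """Yield unobservable: product and start fragments have equal mass."""

    code = "ERR_DEGENERATE_MASS"


class DegenerateMarkerError(BenchchemError):
    """Yield unobservable: marker percent insensitive to conversion."""

    code = "ERR_DEGENERATE_MARKER"


# -- oligomer ----------------------------------------------------------------

class SequenceSyntaxError(BenchchemError):
    """Malformed monomer sequence string; carries token position."""

    code = "ERR_SEQUENCE"

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class UnknownMonomerError(BenchchemError):
    """Sequence token not present in the monomer library."""

    code = "ERR_UNKNOWN_MONOMER"

    def __init__(self, token: str, position: int):
        super().__init__(f"unknown monomer {token!r} at position {position}")
        self.token = token
        self.position = position


class ValenceError(BenchchemError):
    """Attachment atom has no open valence for a new bond."""

    code = "ERR_VALENCE"


# -- template_store ----------------------------------------------------------

class StorePermissionError(BenchchemError):
    """Actor lacks the moderator role required for this operation."""

    code = "ERR_PERMISSION"


class DuplicateError(BenchchemError):
    """Unique-name constraint violated."""

    code = "ERR_DUPLICATE"


class NotFoundError(BenchchemError):
    """Referenced record does not exist (or is not visible to the actor)."""

    code = "ERR_NOT_FOUND"


class EmptyStructureError(BenchchemError):
    """A template requires at least one atom."""

    code = "ERR_EMPTY_STRUCTURE"


class StateError(BenchchemError):
    """Operation requires a different store state (e.g. an empty store)."""

    code = "ERR_STATE"


# -- cli ---------------------------------------------------------------------

class ConfigError(BenchchemError):
    """Malformed configuration file."""

    code = "ERR_CONFIG"
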