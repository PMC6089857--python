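"""Oligomer assembly from monomer templates.

A monomer template is a molecular fragment with two marked attachment
atoms — primary (chain entry, e.g. the backbone amide N of a peptoid
residue) and secondary (chain exit, the carbonyl C). A hyphen-separated
sequence string such as ``N2Ph-N1cPr-N2iPr`` is tokenized, each token looked
up in a :class:`MonomerLibrary`, and the fragments joined by single bonds
from each monomer's secondary atom to the next monomer's primary atom. No
atoms are removed: the templates are stored with the attachment valences
open, so bond formation simply consumes one implicit hydrogen at each joined
atom (no condensation chemistry is modelled).

``reversed`` order reverses the monomer list before assembly, flipping the
sequence between N→C and C→N readings.

The bundled :func:`peptoid_library` provides seven N-substituted glycine
monomers under their conventional side-chain abbreviations. The side-chain
structures are the package's own drawings (fixtures), chosen as plausible
readings of the abbreviations.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .chemgraph import (
    Atom,
    Bond,
    BondOrder,
    Molecule,
    implicit_hydrogens,
)
from .errors import (
    MoleculeError,
    SequenceSyntaxError,
    UnknownMonomerError,
    ValenceError,
)
from .molfile_io import read_sdf

SEPARATOR = "-"


class SequenceOrder(Enum):
    NORMAL = "normal"
    REVERSED = "reversed"


@dataclass(frozen=True)
class MonomerTemplate:
    """A fragment plus its two attachment atom indices (0-based)."""

    abbreviation: str
    fragment: Molecule
    primary_atom: int
    secondary_atom: int

    def __post_init__(self) -> None:
        n = len(self.fragment.atoms)
        if not (0 <= self.primary_atom < n and 0 <= self.secondary_atom < n):
            raise MoleculeError("attachment atom index out of range")
        if self.primary_atom == self.secondary_atom:
            raise MoleculeError("primary and secondary attachment atoms must differ")
        h = implicit_hydrogens(self.fragment)
        for which, idx in (("primary", self.primary_atom),
                           ("secondary", self.secondary_atom)):
            if h[idx] < 1:
                raise ValenceError(
                    f"{which} attachment atom {idx} of {self.abbreviation!r} "
                    "has no open valence")


class MonomerLibrary:
    """Abbreviation → template map; abbreviations are case-sensitive and must
    not contain the sequence separator."""

    def __init__(self, templates: list[MonomerTemplate] = ()):  # type: ignore[assignment]
        self.entries: dict[str, MonomerTemplate] = {}
        for t in templates:
            self.add(t)

    def add(self, template: MonomerTemplate) -> None:
        abbr = template.abbreviation
        if not abbr or SEPARATOR in abbr:
            raise MoleculeError(
                f"invalid abbreviation {abbr!r}: must be non-empty and free of "
                f"{SEPARATOR!r}")
        if abbr in self.entries:
            raise MoleculeError(f"duplicate abbreviation {abbr!r}")
        self.entries[abbr] = template

    def __contains__(self, abbr: str) -> bool:
        return abbr in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_sdf(cls, text: str) -> "MonomerLibrary":
        """Load a library from an SDF whose records carry ``abbreviation``,
        ``primary_atom`` and ``secondary_atom`` properties (atom numbers
        1-based, matching molfile convention)."""
        lib = cls()
        for rec in read_sdf(text):
            lib.add(MonomerTemplate(
                abbreviation=rec.properties["abbreviation"],
                fragment=rec.molecule,
                primary_atom=int(rec.properties["primary_atom"]) - 1,
                secondary_atom=int(rec.properties["secondary_atom"]) - 1,
            ))
        return lib


def parse_sequence(text: str) -> list[str]:
    """Split a hyphen-separated sequence into tokens; empty tokens are errors."""
    if not text or not text.strip():
        raise SequenceSyntaxError("empty sequence", position=0)
    tokens = [t.strip() for t in text.split(SEPARATOR)]
    for pos, tok in enumerate(tokens):
        if not tok:
            raise SequenceSyntaxError(f"empty token at position {pos}", position=pos)
    return tokens


def resolve(tokens: list[str], library: MonomerLibrary) -> list[MonomerTemplate]:
    """Look up each token (case-sensitive) in the library, preserving order."""
    out = []
    for pos, tok in enumerate(tokens):
        if tok not in library:
            raise UnknownMonomerError(tok, pos)
        out.append(library.entries[tok])
    return out


@dataclass(frozen=True)
class MonomerSpan:
    """Placement of one monomer inside an assembled oligomer: its atom range
    and the absolute indices of its attachment atoms."""

    start: int
    length: int
    primary: int
    secondary: int


def assemble_with_spans(
    monomers: list[MonomerTemplate],
    order: SequenceOrder = SequenceOrder.NORMAL,
) -> tuple[Molecule, list[MonomerSpan]]:
    """Join monomers into a chain; also return per-monomer atom spans.

    Fragments are deep-copied (library templates are never mutated). For
    each consecutive pair a SINGLE bond runs from the secondary atom of
    monomer i to the primary atom of monomer i+1. Joined attachment atoms
    must have an open valence; terminal ones keep theirs filled with
    implicit H.
    """
    if not monomers:
        raise SequenceSyntaxError("cannot assemble an empty monomer list")
    seq = list(monomers)
    if order is SequenceOrder.REVERSED:
        seq.reverse()

    atoms: list[Atom] = []
    bonds: list[Bond] = []
    spans: list[MonomerSpan] = []
    for t in seq:
        frag = t.fragment.copy()
        offset = len(atoms)
        atoms.extend(frag.atoms)
        bonds.extend(Bond(a=b.a + offset, b=b.b + offset, order=b.order,
                          display=b.display) for b in frag.bonds)
        spans.append(MonomerSpan(
            start=offset, length=len(frag.atoms),
            primary=offset + t.primary_atom,
            secondary=offset + t.secondary_atom,
        ))

    joined = Molecule(atoms=atoms, bonds=bonds,
                      name=SEPARATOR.join(t.abbreviation for t in seq))
    h_before = implicit_hydrogens(joined)
    for i in range(len(spans) - 1):
        sec, prim = spans[i].secondary, spans[i + 1].primary
        if h_before[sec] < 1:
            raise ValenceError(
                f"secondary attachment atom of monomer {i} has no open valence")
        if h_before[prim] < 1:
            raise ValenceError(
                f"primary attachment atom of monomer {i + 1} has no open valence")
        joined.bonds.append(Bond(a=sec, b=prim, order=BondOrder.SINGLE))
        h_before[sec] -= 1
        h_before[prim] -= 1
    joined.validate()
    return joined, spans


def assemble(
    monomers: list[MonomerTemplate],
    order: SequenceOrder = SequenceOrder.NORMAL,
) -> Molecule:
    """Join monomers into a chain molecule (see :func:`assemble_with_spans`)."""
    molecule, _ = assemble_with_spans(monomers, order)
    return molecule


def layout_chain(m: Molecule, monomer_boundaries: list[MonomerSpan]) -> Molecule:
    """Deterministic left-to-right placement of an assembled chain.

    Each monomer keeps its template geometry and is rigidly translated so
    that its primary atom sits one bond length (1.0 molfile unit) along +x
    from the previous monomer's secondary atom.
    """
    out = m.copy()
    for i in range(1, len(monomer_boundaries)):
        prev = monomer_boundaries[i - 1]
        span = monomer_boundaries[i]
        anchor = out.atoms[prev.secondary]
        prim = out.atoms[span.primary]
        dx = anchor.x + 1.0 - prim.x
        dy = anchor.y - prim.y
        for j in range(span.start, span.start + span.length):
            out.atoms[j].x += dx
            out.atoms[j].y += dy
    return out


def build_oligomer(
    sequence: str,
    library: MonomerLibrary,
    order: SequenceOrder = SequenceOrder.NORMAL,
) -> Molecule:
    """Sequence string → laid-out chain molecule (parse, resolve, assemble,
    layout in one call)."""
    monomers = resolve(parse_sequence(sequence), library)
    molecule, spans = assemble_with_spans(monomers, order)
    return layout_chain(molecule, spans)


# -- bundled peptoid monomer fixtures ---------------------------------------

def _ring6(cx: float, cy: float) -> list[tuple[float, float]]:
    # kekulized benzene hexagon, radius 1.0
    return [(cx, cy - 1.0), (cx + 0.87, cy - 0.5), (cx + 0.87, cy + 0.5),
            (cx, cy + 1.0), (cx - 0.87, cy + 0.5), (cx - 0.87, cy - 0.5)]


def _peptoid(abbreviation: str, side_atoms: list[Atom],
             side_bonds: list[tuple[int, int, BondOrder]]) -> MonomerTemplate:
    """N-substituted glycine backbone N(0)-CA(1)-C(2)=O(3); side chain atoms
    appended after the backbone, attached to N. Side bond indices are local
    to ``side_atoms``; (-1, j) attaches side atom j to the backbone N."""
    atoms = [
        Atom("N", x=0.0, y=0.0),
        Atom("C", x=0.87, y=0.5),
        Atom("C", x=1.73, y=0.0),
        Atom("O", x=1.73, y=-1.0),
    ] + side_atoms
    bonds = [
        Bond(0, 1, BondOrder.SINGLE),
        Bond(1, 2, BondOrder.SINGLE),
        Bond(2, 3, BondOrder.DOUBLE),
    ]
    for a, b, order in side_bonds:
        bonds.append(Bond(a + 4 if a >= 0 else 0, b + 4, order))
    frag = Molecule(atoms=atoms, bonds=bonds, name=abbreviation)
    return MonomerTemplate(abbreviation=abbreviation, fragment=frag,
                           primary_atom=0, secondary_atom=2)


def _phenyl(cy: float) -> tuple[list[Atom], list[tuple[int, int, BondOrder]]]:
    ring = [Atom("C", x=px, y=py) for px, py in _ring6(0.0, cy)]
    S, D = BondOrder.SINGLE, BondOrder.DOUBLE
    bonds = [(0, 1, D), (1, 2, S), (2, 3, D), (3, 4, S), (4, 5, D), (5, 0, S)]
    return ring, bonds


def peptoid_library() -> MonomerLibrary:
    """The seven bundled peptoid monomers (fixture structures).

    Abbreviations follow the usual peptoid side-chain shorthand: ``N<n>``
    counts methylenes between the backbone N and the terminal group —
    phenethyl (N2Ph), cyclopropylmethyl (N1cPr), isopentyl (N2iPr), propyl
    (N2Me), methoxypropyl (N3m), benzyl (N1ph) and propargyl (N1ppg).
    """
    S, D, T = BondOrder.SINGLE, BondOrder.DOUBLE, BondOrder.TRIPLE
    lib = MonomerLibrary()

    # N2Ph: -CH2CH2-C6H5
    ring, ring_bonds = _phenyl(4.0)
    side = [Atom("C", x=0.0, y=1.0), Atom("C", x=0.0, y=2.0)] + ring
    bonds = [(-1, 0, S), (0, 1, S), (1, 2, S)]
    bonds += [(a + 2, b + 2, o) for a, b, o in ring_bonds]
    lib.add(_peptoid("N2Ph", side, bonds))

    # N1cPr: -CH2-cyclopropyl
    side = [Atom("C", x=0.0, y=1.0), Atom("C", x=0.0, y=2.0),
            Atom("C", x=-0.5, y=2.87), Atom("C", x=0.5, y=2.87)]
    lib.add(_peptoid("N1cPr", side,
                     [(-1, 0, S), (0, 1, S), (1, 2, S), (2, 3, S), (3, 1, S)]))

    # N2iPr: -CH2CH2-CH(CH3)2
    side = [Atom("C", x=0.0, y=1.0), Atom("C", x=0.0, y=2.0),
            Atom("C", x=0.0, y=3.0), Atom("C", x=-0.7, y=3.6),
            Atom("C", x=0.7, y=3.6)]
    lib.add(_peptoid("N2iPr", side,
                     [(-1, 0, S), (0, 1, S), (1, 2, S), (2, 3, S), (2, 4, S)]))

    # N2Me: -CH2CH2-CH3
    side = [Atom("C", x=0.0, y=1.0), Atom("C", x=0.0, y=2.0),
            Atom("C", x=0.0, y=3.0)]
    lib.add(_peptoid("N2Me", side, [(-1, 0, S), (0, 1, S), (1, 2, S)]))

    # N3m: -(CH2)3-O-CH3
    side = [Atom("C", x=0.0, y=1.0), Atom("C", x=0.0, y=2.0),
            Atom("C", x=0.0, y=3.0), Atom("O", x=0.0, y=4.0),
            Atom("C", x=0.0, y=5.0)]
    lib.add(_peptoid("N3m", side,
                     [(-1, 0, S), (0, 1, S), (1, 2, S), (2, 3, S), (3, 4, S)]))

    # N1ph: -CH2-C6H5
    ring, ring_bonds = _phenyl(3.0)
    side = [Atom("C", x=0.0, y=1.0)] + ring
    bonds = [(-1, 0, S), (0, 1, S)]
    bonds += [(a + 1, b + 1, o) for a, b, o in ring_bonds]
    lib.add(_peptoid("N1ph", side, bonds))

    # N1ppg: -CH2-C#CH
    side = [Atom("C", x=0.0, y=1.0), Atom("C", x=0.0, y=2.0),
            Atom("C", x=0.0, y=3.0)]
    lib.add(_peptoid("N1ppg", side, [(-1, 0, S), (0, 1, S), (1, 2, T)]))

    return lib
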