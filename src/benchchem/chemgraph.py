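"""Molecular graph model and formula/mass arithmetic.

A :class:`Molecule` is an ordered list of :class:`Atom` plus a list of
:class:`Bond`. Two pseudo element labels are allowed — ``Pol`` for a polymer
bead and ``Sur`` for a surface — so that solid-supported structures can be
drawn with the undefined support collapsed into a single symbol. All mass
arithmetic lives on :class:`Formula`, an element→count multiset.

Implicit hydrogens follow the common V2000 convention: a bundled valence
table for the organic subset (all other elements get no implicit H), with a
charge correction of ``+charge`` for the nitrogen family and ``−|charge|``
for the oxygen family. A dative (coordinative) bond consumes one valence
unit at the donor and none at the acceptor, which is what makes drawn
organometallic complexes (e.g. amine→metal) come out with sensible H counts.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Iterator, Mapping

from .errors import (
    AromaticBondError,
    ElementError,
    EmptyFormulaError,
    MoleculeError,
    PseudoAtomError,
)
from .masses import ATOMIC_WEIGHTS, KNOWN_ELEMENTS, MONOISOTOPIC_MASSES

PSEUDO_LABELS = frozenset({"Pol", "Sur"})

#: Implicit-H valences for the organic subset; everything else gets 0.
DEFAULT_VALENCES: dict[str, int] = {
    "H": 1, "B": 3, "C": 4, "N": 3, "O": 2, "F": 1,
    "Si": 4, "P": 3, "S": 2, "Cl": 1, "Br": 1, "I": 1,
}

_N_FAMILY = frozenset({"N", "P", "As", "Sb", "Bi"})
_O_FAMILY = frozenset({"O", "S", "Se", "Te"})


class BondOrder(Enum):
    SINGLE = 1
    DOUBLE = 2
    TRIPLE = 3
    AROMATIC = 4
    DATIVE = 9


class BondDisplay(Enum):
    PLAIN = "plain"
    DASHED = "dashed"
    ARROW = "arrow"


class AttachmentRole(Enum):
    NONE = "none"
    PRIMARY = "primary"
    SECONDARY = "secondary"


@dataclass
class Atom:
    """One node of the molecular graph.

    ``element`` is a periodic-table symbol or one of the pseudo labels
    ``Pol``/``Sur``; ``isotope`` is a mass number or ``None``; coordinates
    are in molfile length units.
    """

    element: str
    charge: int = 0
    isotope: int | None = None
    x: float = 0.0
    y: float = 0.0
    z: float = 0.0
    attachment_role: AttachmentRole = AttachmentRole.NONE

    def __post_init__(self) -> None:
        if self.element not in KNOWN_ELEMENTS and self.element not in PSEUDO_LABELS:
            raise ElementError(f"unknown element symbol {self.element!r}")
        if self.isotope is not None and self.isotope <= 0:
            raise MoleculeError(f"isotope mass number must be positive, got {self.isotope}")

    @property
    def is_pseudo(self) -> bool:
        return self.element in PSEUDO_LABELS


@dataclass
class Bond:
    """Edge between atoms ``a`` and ``b`` (0-based indices into the atom list).

    For DATIVE bonds atom ``a`` is the donor by convention; ``display`` is a
    rendering hint (dashed vs arrow) valid only for DATIVE bonds.
    """

    a: int
    b: int
    order: BondOrder = BondOrder.SINGLE
    display: BondDisplay = BondDisplay.PLAIN

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise MoleculeError("bond endpoints must differ")
        if self.display is not BondDisplay.PLAIN and self.order is not BondOrder.DATIVE:
            raise MoleculeError("dashed/arrow display is reserved for dative bonds")

    @property
    def pair(self) -> frozenset[int]:
        return frozenset((self.a, self.b))


@dataclass
class Molecule:
    """Atoms plus bonds plus a free-text name."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[Bond] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        n = len(self.atoms)
        seen: set[frozenset[int]] = set()
        for b in self.bonds:
            if not (0 <= b.a < n and 0 <= b.b < n):
                raise MoleculeError(f"bond ({b.a},{b.b}) references a missing atom")
            if b.pair in seen:
                raise MoleculeError(f"duplicate bond between atoms {b.a} and {b.b}")
            seen.add(b.pair)

    def copy(self) -> "Molecule":
        return Molecule(
            atoms=[replace(a) for a in self.atoms],
            bonds=[replace(b) for b in self.bonds],
            name=self.name,
        )

    def has_pseudo_atoms(self) -> bool:
        return any(a.is_pseudo for a in self.atoms)

    def equivalent(self, other: "Molecule", coord_decimals: int = 4) -> bool:
        """Structural equality with coordinates compared to a fixed precision."""
        if len(self.atoms) != len(other.atoms) or len(self.bonds) != len(other.bonds):
            return False
        for p, q in zip(self.atoms, other.atoms):
            if (p.element, p.charge, p.isotope) != (q.element, q.charge, q.isotope):
                return False
            for u, v in ((p.x, q.x), (p.y, q.y), (p.z, q.z)):
                if round(u, coord_decimals) != round(v, coord_decimals):
                    return False
        for s, t in zip(self.bonds, other.bonds):
            if (s.a, s.b, s.order) != (t.a, t.b, t.order):
                return False
        return True


_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class Formula(Mapping[str, int]):
    """Immutable element→count multiset with mass arithmetic.

    Counts are strictly positive and pseudo labels are rejected. Supports
    ``+`` (multiset union) and ``*`` (integer scaling).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]] = ()):
        items = dict(counts)
        for el, n in items.items():
            if el in PSEUDO_LABELS:
                raise PseudoAtomError(f"pseudo label {el!r} cannot appear in a formula")
            if el not in KNOWN_ELEMENTS:
                raise ElementError(f"unknown element symbol {el!r}")
            if not isinstance(n, int) or n < 1:
                raise ValueError(f"count for {el} must be a positive integer, got {n!r}")
        self._counts: dict[str, int] = items

    @classmethod
    def from_string(cls, text: str) -> "Formula":
        """Parse a plain formula string such as ``C8H8`` or ``CH2Cl``."""
        text = text.strip()
        counts: dict[str, int] = {}
        pos = 0
        while pos < len(text):
            m = _FORMULA_TOKEN.match(text, pos)
            if not m or not m.group(1):
                raise ElementError(f"cannot parse formula {text!r} at position {pos}")
            el, digits = m.group(1), m.group(2)
            if el not in KNOWN_ELEMENTS:
                raise ElementError(f"unknown element symbol {el!r} in {text!r}")
            counts[el] = counts.get(el, 0) + (int(digits) if digits else 1)
            pos = m.end()
        return cls(counts)

    # Mapping protocol
    def __getitem__(self, el: str) -> int:
        return self._counts[el]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self._counts)
        for el, n in other.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged)

    def __mul__(self, k: int) -> "Formula":
        if not isinstance(k, int) or k < 1:
            raise ValueError("formula can only be scaled by a positive integer")
        return Formula({el: n * k for el, n in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        return NotImplemented

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __repr__(self) -> str:
        return f"Formula({formula_to_hill_string(self)!r})"


def effective_valence(atom: Atom) -> int:
    """Target valence of an atom after the molfile charge correction."""
    base = DEFAULT_VALENCES.get(atom.element, 0)
    if base == 0:
        return 0
    if atom.element in _N_FAMILY:
        base += atom.charge
    elif atom.element in _O_FAMILY:
        base -= abs(atom.charge)
    return max(base, 0)


def implicit_hydrogens(m: Molecule) -> list[int]:
    """Implicit H count per atom under the bundled valence model.

    Bond orders add to an atom's used valence (single 1, double 2, triple 3);
    a dative bond adds 1 at the donor (``bond.a``) and 0 at the acceptor.
    Aromatic orders are rejected: kekulize first.
    """
    used = [0] * len(m.atoms)
    for b in m.bonds:
        if b.order is BondOrder.AROMATIC:
            raise AromaticBondError(
                "aromatic bond orders carry no H-count information; kekulize first")
        if b.order is BondOrder.DATIVE:
            used[b.a] += 1
        else:
            used[b.a] += b.order.value
            used[b.b] += b.order.value
    return [max(effective_valence(a) - u, 0) for a, u in zip(m.atoms, used)]


def molecular_formula(m: Molecule) -> Formula:
    """Formula of a molecule with implicit hydrogens filled in.

    Pseudo atoms must be substituted first (see
    :func:`benchchem.polymer_calc.export_defined_part`).
    """
    for i, a in enumerate(m.atoms):
        if a.is_pseudo:
            raise PseudoAtomError(
                f"atom {i} is a pseudo atom ({a.element}); substitute the support first")
    counts: dict[str, int] = {}
    for a in m.atoms:
        counts[a.element] = counts.get(a.element, 0) + 1
    for h in implicit_hydrogens(m):
        if h:
            counts["H"] = counts.get("H", 0) + h
    return Formula(counts)


def formula_to_hill_string(f: Formula) -> str:
    """Hill order: C first, then H, then the rest alphabetically; count 1 omitted.

    Without carbon, all elements are sorted alphabetically.
    """
    elements = sorted(f)
    if "C" in f:
        head = ["C"] + (["H"] if "H" in f else [])
        elements = head + [el for el in elements if el not in ("C", "H")]
    return "".join(el + (str(f[el]) if f[el] > 1 else "") for el in elements)


def average_mass(f: Formula) -> float:
    """Molecular weight in g/mol from conventional atomic weights."""
    return sum(n * ATOMIC_WEIGHTS[el] for el, n in f.items())


def monoisotopic_mass(f: Formula) -> float:
    """Exact mass in Da from most-abundant-isotope masses."""
    return sum(n * MONOISOTOPIC_MASSES[el] for el, n in f.items())


def element_mass_fractions(f: Formula) -> dict[str, float]:
    """Mass fraction of each element; fractions sum to 1."""
    if len(f) == 0:
        raise EmptyFormulaError("mass fractions are undefined for an empty formula")
    total = average_mass(f)
    return {el: n * ATOMIC_WEIGHTS[el] / total for el, n in f.items()}
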