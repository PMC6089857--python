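"""Shared fixtures and random-structure generators."""

from __future__ import annotations

import random

import pytest

from benchchem.chemgraph import Atom, Bond, BondDisplay, BondOrder, Molecule

# Elements the V2000 round-trip generator draws from (organic subset plus a
# few metals and the two pseudo labels).
_ELEMENTS = ["C", "C", "C", "N", "O", "S", "P", "F", "Cl", "Br",
             "Fe", "Pd", "Si", "B", "Pol", "Sur"]
_ORDERS = [BondOrder.SINGLE, BondOrder.SINGLE, BondOrder.DOUBLE,
           BondOrder.TRIPLE, BondOrder.AROMATIC, BondOrder.DATIVE]


def random_molecule(rng: random.Random, max_atoms: int = 20) -> Molecule:
    """A random connected-ish molecule within V2000 field widths.

    Coordinates are pre-rounded to 4 decimals (the writer's precision) so
    equality after a round trip is exact; bonds form a random tree plus a
    few extra edges.
    """
    n = rng.randint(1, max_atoms)
    atoms = []
    for _ in range(n):
        atoms.append(Atom(
            element=rng.choice(_ELEMENTS),
            charge=rng.choice([0, 0, 0, 1, -1]),
            isotope=rng.choice([None, None, None, 13, 15]),
            x=round(rng.uniform(-50, 50), 4),
            y=round(rng.uniform(-50, 50), 4),
            z=round(rng.uniform(-50, 50), 4),
        ))
    bonds = []
    pairs = set()
    for i in range(1, n):
        j = rng.randrange(i)
        order = rng.choice(_ORDERS)
        display = BondDisplay.ARROW if order is BondOrder.DATIVE else BondDisplay.PLAIN
        bonds.append(Bond(a=j, b=i, order=order, display=display))
        pairs.add(frozenset((i, j)))
    for _ in range(rng.randint(0, max(n // 3, 0))):
        i, j = rng.randrange(n), rng.randrange(n)
        if i == j or frozenset((i, j)) in pairs:
            continue
        order = rng.choice(_ORDERS)
        display = BondDisplay.ARROW if order is BondOrder.DATIVE else BondDisplay.PLAIN
        bonds.append(Bond(a=i, b=j, order=order, display=display))
        pairs.add(frozenset((i, j)))
    return Molecule(atoms=atoms, bonds=bonds, name=f"random-{n}")


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20260925)


@pytest.fixture
def peptoids():
    from benchchem.oligomer import peptoid_library
    return peptoid_library()
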