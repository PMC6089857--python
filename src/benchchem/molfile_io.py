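"""Molfile (CTfile) reading and writing, plus multi-record SDF reading.

Reads V2000 and V3000 connection tables; writes V2000 only. The one dialect
extension is the coordinative bond: bond type 9, officially a V3000 feature,
is backported into the V2000 bond block so that dative bonds survive the
round trip. On a type-9 bond line the first atom is the donor. Pseudo atoms
``Pol`` and ``Sur`` occupy the atom-symbol field directly (non-standard, but
round-trips cleanly).

Charges are serialized via ``M  CHG`` property lines and isotopes via
``M  ISO`` — exact integers, unlike the legacy atom-block charge column,
which is also understood on input for files written by other tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .chemgraph import Atom, Bond, BondDisplay, BondOrder, Molecule
from .errors import CapacityError, DialectError, ElementError, ParseError

_BOND_TYPE_TO_ORDER = {
    1: BondOrder.SINGLE,
    2: BondOrder.DOUBLE,
    3: BondOrder.TRIPLE,
    4: BondOrder.AROMATIC,
    9: BondOrder.DATIVE,
}
_ORDER_TO_BOND_TYPE = {v: k for k, v in _BOND_TYPE_TO_ORDER.items()}

# Legacy atom-block charge column codes (V2000): 1..7 excluding 4 (radical).
_CHARGE_CODES = {1: 3, 2: 2, 3: 1, 5: -1, 6: -2, 7: -3}


@dataclass(frozen=True)
class MolfileDialect:
    """Writer dialect. ``allow_dative`` enables the type-9 backport; output
    is always V2000."""

    allow_dative: bool = True
    version_out: str = "V2000"


@dataclass
class SdfRecord:
    molecule: Molecule
    properties: dict[str, str] = field(default_factory=dict)


def _int_field(line: str, start: int, end: int, lineno: int, what: str) -> int:
    raw = line[start:end].strip()
    try:
        return int(raw) if raw else 0
    except ValueError:
        raise ParseError(f"malformed {what} field {raw!r}", line=lineno) from None


def read_molfile(text: str) -> Molecule:
    """Parse a V2000 or V3000 molfile into a :class:`Molecule`."""
    lines = text.splitlines()
    if len(lines) < 4:
        raise ParseError("molfile shorter than header + counts line", line=len(lines))
    counts_line = lines[3]
    if "V3000" in counts_line:
        return _read_v3000(lines)
    return _read_v2000(lines)


def _read_v2000(lines: list[str]) -> Molecule:
    counts_line = lines[3]
    n_atoms = _int_field(counts_line, 0, 3, 4, "atom count")
    n_bonds = _int_field(counts_line, 3, 6, 4, "bond count")
    if len(lines) < 4 + n_atoms + n_bonds:
        raise ParseError(
            f"counts line declares {n_atoms} atoms and {n_bonds} bonds "
            "but the file is shorter", line=4)

    atoms: list[Atom] = []
    for i in range(n_atoms):
        lineno = 5 + i
        line = lines[4 + i]
        try:
            x = float(line[0:10])
            y = float(line[10:20])
            z = float(line[20:30])
        except ValueError:
            raise ParseError("malformed coordinate field", line=lineno) from None
        symbol = line[31:34].strip()
        if not symbol:
            raise ParseError("missing atom symbol", line=lineno)
        code = _int_field(line, 36, 39, lineno, "charge")
        charge = _CHARGE_CODES.get(code, 0)
        try:
            atoms.append(Atom(element=symbol, charge=charge, x=x, y=y, z=z))
        except ElementError as exc:
            raise ParseError(str(exc), line=lineno) from None

    bonds: list[Bond] = []
    for i in range(n_bonds):
        lineno = 5 + n_atoms + i
        line = lines[4 + n_atoms + i]
        a = _int_field(line, 0, 3, lineno, "bond atom")
        b = _int_field(line, 3, 6, lineno, "bond atom")
        t = _int_field(line, 6, 9, lineno, "bond type")
        if t not in _BOND_TYPE_TO_ORDER:
            raise ParseError(f"unknown bond type {t}", line=lineno)
        if not (1 <= a <= n_atoms and 1 <= b <= n_atoms):
            raise ParseError(f"bond references atom outside 1..{n_atoms}", line=lineno)
        order = _BOND_TYPE_TO_ORDER[t]
        display = BondDisplay.ARROW if order is BondOrder.DATIVE else BondDisplay.PLAIN
        bonds.append(Bond(a=a - 1, b=b - 1, order=order, display=display))

    # property block: M  CHG / M  ISO override, M  END terminates
    for j in range(4 + n_atoms + n_bonds, len(lines)):
        line = lines[j]
        if line.startswith("M  END"):
            break
        if line.startswith(("M  CHG", "M  ISO")):
            parts = line.split()
            try:
                n = int(parts[2])
                pairs = [(int(parts[3 + 2 * k]), int(parts[4 + 2 * k])) for k in range(n)]
            except (IndexError, ValueError):
                raise ParseError("malformed property line", line=j + 1) from None
            for idx, val in pairs:
                if not (1 <= idx <= n_atoms):
                    raise ParseError(f"property references atom {idx}", line=j + 1)
                if line.startswith("M  CHG"):
                    atoms[idx - 1].charge = val
                else:
                    atoms[idx - 1].isotope = val

    name = lines[0].strip()
    return Molecule(atoms=atoms, bonds=bonds, name=name)


def _read_v3000(lines: list[str]) -> Molecule:
    atoms: list[Atom] = []
    bonds: list[Bond] = []
    section = None
    declared: tuple[int, int] | None = None
    for j, raw in enumerate(lines, start=1):
        if not raw.startswith("M  V30"):
            continue
        body = raw[6:].strip()
        if body.startswith("COUNTS"):
            parts = body.split()
            try:
                declared = (int(parts[1]), int(parts[2]))
            except (IndexError, ValueError):
                raise ParseError("malformed V3000 COUNTS line", line=j) from None
        elif body.startswith("BEGIN"):
            section = body.split()[-1]
        elif body.startswith("END"):
            section = None
        elif section == "ATOM":
            parts = body.split()
            try:
                symbol = parts[1]
                x, y, z = float(parts[2]), float(parts[3]), float(parts[4])
            except (IndexError, ValueError):
                raise ParseError("malformed V3000 atom line", line=j) from None
            charge, isotope = 0, None
            for kv in parts[6:]:
                if kv.startswith("CHG="):
                    charge = int(kv[4:])
                elif kv.startswith("MASS="):
                    isotope = int(kv[5:])
            try:
                atoms.append(Atom(element=symbol, charge=charge, isotope=isotope,
                                  x=x, y=y, z=z))
            except ElementError as exc:
                raise ParseError(str(exc), line=j) from None
        elif section == "BOND":
            parts = body.split()
            try:
                t, a, b = int(parts[1]), int(parts[2]), int(parts[3])
            except (IndexError, ValueError):
                raise ParseError("malformed V3000 bond line", line=j) from None
            if t not in _BOND_TYPE_TO_ORDER:
                raise ParseError(f"unknown bond type {t}", line=j)
            order = _BOND_TYPE_TO_ORDER[t]
            display = BondDisplay.ARROW if order is BondOrder.DATIVE else BondDisplay.PLAIN
            bonds.append(Bond(a=a - 1, b=b - 1, order=order, display=display))
    if declared is None:
        raise ParseError("V3000 block lacks a COUNTS line", line=4)
    if declared != (len(atoms), len(bonds)):
        raise ParseError(
            f"V3000 COUNTS {declared} disagree with parsed ({len(atoms)}, {len(bonds)})",
            line=4)
    name = lines[0].strip()
    return Molecule(atoms=atoms, bonds=bonds, name=name)


def write_molfile(m: Molecule, dialect: MolfileDialect = MolfileDialect()) -> str:
    """Serialize a molecule as a fixed-width V2000 connection table."""
    if len(m.atoms) > 999 or len(m.bonds) > 999:
        raise CapacityError(
            f"V2000 capacity exceeded: {len(m.atoms)} atoms, {len(m.bonds)} bonds")
    out: list[str] = [m.name, "  benchchem", ""]
    out.append(f"{len(m.atoms):3d}{len(m.bonds):3d}  0  0  0  0  0  0  0  0999 V2000")
    for a in m.atoms:
        out.append(
            f"{a.x:10.4f}{a.y:10.4f}{a.z:10.4f} {a.element:<3s} 0  0  0  0  0"
            "  0  0  0  0  0  0  0")
    for b in m.bonds:
        if b.order is BondOrder.DATIVE and not dialect.allow_dative:
            raise DialectError(
                "dative bond present but the dialect does not allow type 9")
        t = _ORDER_TO_BOND_TYPE[b.order]
        out.append(f"{b.a + 1:3d}{b.b + 1:3d}{t:3d}  0")
    charged = [(i + 1, a.charge) for i, a in enumerate(m.atoms) if a.charge]
    for chunk_start in range(0, len(charged), 8):
        chunk = charged[chunk_start:chunk_start + 8]
        out.append("M  CHG" + f"{len(chunk):3d}"
                   + "".join(f"{i:4d}{c:4d}" for i, c in chunk))
    isotopic = [(i + 1, a.isotope) for i, a in enumerate(m.atoms) if a.isotope]
    for chunk_start in range(0, len(isotopic), 8):
        chunk = isotopic[chunk_start:chunk_start + 8]
        out.append("M  ISO" + f"{len(chunk):3d}"
                   + "".join(f"{i:4d}{v:4d}" for i, v in chunk))
    out.append("M  END")
    return "\n".join(out) + "\n"


def read_sdf(text: str, lenient: bool = False) -> list[SdfRecord]:
    """Parse an SDF: molfiles separated by ``$$$$``, each with tagged data.

    In strict mode (default) a malformed record raises :class:`ParseError`
    carrying its 0-based ``record_index``; in lenient mode bad records are
    skipped and the good ones returned.
    """
    records: list[SdfRecord] = []
    chunks: list[list[str]] = [[]]
    for line in text.splitlines():
        if line.strip() == "$$$$":
            chunks.append([])
        else:
            chunks[-1].append(line)
    # trailing blank chunk after the final $$$$ is not a record
    if chunks and not any(s.strip() for s in chunks[-1]):
        chunks.pop()

    for idx, chunk in enumerate(chunks):
        try:
            records.append(_parse_sdf_record(chunk, idx))
        except ParseError as exc:
            if lenient:
                continue
            exc.record_index = idx
            raise
    return records


def _parse_sdf_record(chunk: list[str], idx: int) -> SdfRecord:
    try:
        end = next(i for i, line in enumerate(chunk) if line.startswith("M  END"))
    except StopIteration:
        raise ParseError("record lacks an M  END line", record_index=idx) from None
    molecule = read_molfile("\n".join(chunk[:end + 1]))
    properties: dict[str, str] = {}
    tag: str | None = None
    values: list[str] = []
    for line in chunk[end + 1:]:
        if line.startswith(">"):
            if tag is not None:
                properties[tag] = "\n".join(values).strip()
            lo, hi = line.find("<"), line.rfind(">")
            if lo == -1 or hi <= lo:
                raise ParseError(f"malformed property header {line!r}", record_index=idx)
            tag = line[lo + 1:hi]
            if not tag:
                raise ParseError("empty property tag", record_index=idx)
            values = []
        elif tag is not None:
            values.append(line)
    if tag is not None:
        properties[tag] = "\n".join(values).strip()
    return SdfRecord(molecule=molecule, properties=properties)
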