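"""Moderated store of structure templates.

Mirrors the moderation workflow of a shared ELN template library: a
moderator manages named categories and imports common templates (singly or
in bulk from an SDF); every imported structure starts life as ``pending``
and only ``approved`` templates show up in the default listings. Any user
may additionally keep private custom templates — visible only to their
creator — each with a generated SVG icon. An abbreviation is stored as a
template record with ``kind="abbreviation"`` (a name→structure alias), and
monomer registrations use ``kind="monomer"`` with the same moderation
workflow.

Persistence is a single JSON file behind :meth:`TemplateStore.save` /
:meth:`TemplateStore.load`; the workflow semantics, not the backing store,
are the point.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from enum import Enum
from math import cos, pi, sin
from pathlib import Path

from .chemgraph import Atom, Bond, BondOrder, Molecule
from .errors import (
    DuplicateError,
    EmptyStructureError,
    NotFoundError,
    StateError,
    StorePermissionError,
)
from .molfile_io import read_molfile, read_sdf, write_molfile


class UserRole(Enum):
    MODERATOR = "moderator"
    USER = "user"


class TemplateStatus(Enum):
    PENDING = "pending"
    APPROVED = "approved"


@dataclass
class Category:
    id: int
    name: str
    icon: str | None = None


@dataclass
class TemplateRecord:
    id: int
    name: str
    category_id: int
    molfile: str
    status: TemplateStatus = TemplateStatus.PENDING
    owner: str = "system"
    kind: str = "template"  # template | abbreviation | monomer


@dataclass
class CustomTemplate:
    id: int
    owner: str
    name: str
    molfile: str
    svg_icon: str


def molecule_to_svg(m: Molecule, scale: float = 30.0, margin: float = 15.0) -> str:
    """Render a molecule as a minimal SVG icon: line segments for bonds,
    text labels for heteroatoms (double/triple bonds drawn as parallel
    lines). Coordinates come from the molecule's own layout."""
    if not m.atoms:
        raise EmptyStructureError("cannot render an empty molecule")
    xs = [a.x for a in m.atoms]
    ys = [a.y for a in m.atoms]
    x0, y0 = min(xs), min(ys)
    w = (max(xs) - x0) * scale + 2 * margin
    h = (max(ys) - y0) * scale + 2 * margin

    def px(a: Atom) -> tuple[float, float]:
        # SVG y axis points down
        return (margin + (a.x - x0) * scale, h - margin - (a.y - y0) * scale)

    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" '
        f'height="{h:.0f}" viewBox="0 0 {w:.0f} {h:.0f}">'
    ]
    for b in m.bonds:
        (xa, ya), (xb, yb) = px(m.atoms[b.a]), px(m.atoms[b.b])
        n = {BondOrder.DOUBLE: 2, BondOrder.TRIPLE: 3}.get(b.order, 1)
        dash = ' stroke-dasharray="4 3"' if b.order is BondOrder.DATIVE else ""
        length = max(((xb - xa) ** 2 + (yb - ya) ** 2) ** 0.5, 1e-9)
        ox, oy = -(yb - ya) / length * 3.0, (xb - xa) / length * 3.0
        for k in range(n):
            s = k - (n - 1) / 2.0
            parts.append(
                f'<line x1="{xa + s * ox:.1f}" y1="{ya + s * oy:.1f}" '
                f'x2="{xb + s * ox:.1f}" y2="{yb + s * oy:.1f}" '
                f'stroke="black" stroke-width="1.5"{dash}/>')
    for a in m.atoms:
        if a.element != "C":
            x, y = px(a)
            label = a.element
            if a.charge:
                label += ("+" if a.charge > 0 else "-") * abs(a.charge) \
                    if abs(a.charge) <= 2 else f"{a.charge:+d}"
            parts.append(
                f'<text x="{x:.1f}" y="{y:.1f}" font-size="12" '
                f'text-anchor="middle" dominant-baseline="middle" '
                f'fill="black">{label}</text>')
    parts.append("</svg>")
    return "".join(parts)


class TemplateStore:
    """In-memory template store with JSON persistence."""

    def __init__(self) -> None:
        self.categories: dict[int, Category] = {}
        self.templates: dict[int, TemplateRecord] = {}
        self.custom: dict[int, CustomTemplate] = {}
        self._next_id = 1

    def _new_id(self) -> int:
        i = self._next_id
        self._next_id += 1
        return i

    @property
    def is_empty(self) -> bool:
        return not (self.categories or self.templates or self.custom)

    # -- moderated operations ------------------------------------------------

    @staticmethod
    def _require_moderator(actor: UserRole) -> None:
        if actor is not UserRole.MODERATOR:
            raise StorePermissionError(
                "only a moderator can manage categories and common templates")

    def create_category(self, actor: UserRole, name: str) -> Category:
        self._require_moderator(actor)
        if not name or not name.strip():
            raise DuplicateError("category name must be non-empty")
        if any(c.name == name for c in self.categories.values()):
            raise DuplicateError(f"category {name!r} already exists")
        cat = Category(id=self._new_id(), name=name)
        self.categories[cat.id] = cat
        return cat

    def delete_category(self, actor: UserRole, category: str | int) -> None:
        self._require_moderator(actor)
        cat = self._category(category)
        del self.categories[cat.id]
        self.templates = {i: t for i, t in self.templates.items()
                          if t.category_id != cat.id}

    def _category(self, ref: str | int) -> Category:
        if isinstance(ref, int):
            if ref not in self.categories:
                raise NotFoundError(f"no category with id {ref}")
            return self.categories[ref]
        for c in self.categories.values():
            if c.name == ref:
                return c
        raise NotFoundError(f"no category named {ref!r}")

    def import_templates_sdf(
        self, actor: UserRole, sdf_text: str, category: str | int,
        lenient: bool = False, kind: str = "template",
    ) -> list[TemplateRecord]:
        """Bulk-import templates from an SDF; every record enters as pending."""
        self._require_moderator(actor)
        cat = self._category(category)
        out = []
        for rec in read_sdf(sdf_text, lenient=lenient):
            name = rec.properties.get("name") or rec.molecule.name or "unnamed"
            record = TemplateRecord(
                id=self._new_id(), name=name, category_id=cat.id,
                molfile=write_molfile(rec.molecule),
                status=TemplateStatus.PENDING, kind=kind)
            self.templates[record.id] = record
            out.append(record)
        return out

    def add_template(self, actor: UserRole, molecule: Molecule, name: str,
                     category: str | int, kind: str = "template") -> TemplateRecord:
        self._require_moderator(actor)
        if not molecule.atoms:
            raise EmptyStructureError("template structure must not be empty")
        cat = self._category(category)
        record = TemplateRecord(
            id=self._new_id(), name=name, category_id=cat.id,
            molfile=write_molfile(molecule), status=TemplateStatus.PENDING,
            kind=kind)
        self.templates[record.id] = record
        return record

    def approve_template(self, actor: UserRole, template_id: int) -> TemplateRecord:
        """Flip a record to approved; idempotent."""
        self._require_moderator(actor)
        if template_id not in self.templates:
            raise NotFoundError(f"no template with id {template_id}")
        record = self.templates[template_id]
        record.status = TemplateStatus.APPROVED
        return record

    def list_templates(self, category: str | int,
                       include_pending: bool = False) -> list[TemplateRecord]:
        """Category members ordered by name; pending ones hidden by default."""
        cat = self._category(category)
        rows = [t for t in self.templates.values()
                if t.category_id == cat.id
                and (include_pending or t.status is TemplateStatus.APPROVED)]
        return sorted(rows, key=lambda t: (t.name, t.id))

    # -- per-user custom templates -------------------------------------------

    def add_custom_template(self, user: str, molecule: Molecule,
                            name: str) -> CustomTemplate:
        if not molecule.atoms:
            raise EmptyStructureError("custom template structure must not be empty")
        record = CustomTemplate(
            id=self._new_id(), owner=user, name=name,
            molfile=write_molfile(molecule), svg_icon=molecule_to_svg(molecule))
        self.custom[record.id] = record
        return record

    def list_custom(self, user: str) -> list[CustomTemplate]:
        return sorted((c for c in self.custom.values() if c.owner == user),
                      key=lambda c: (c.name, c.id))

    def search_custom(self, user: str, query: str) -> list[CustomTemplate]:
        """Case-insensitive substring search over the user's own templates."""
        q = query.lower()
        return [c for c in self.list_custom(user) if q in c.name.lower()]

    def get_custom(self, user: str, template_id: int) -> CustomTemplate:
        record = self.custom.get(template_id)
        if record is None or record.owner != user:
            # non-owners cannot distinguish "absent" from "not yours"
            raise NotFoundError(f"no custom template with id {template_id}")
        return record

    def delete_custom(self, user: str, template_id: int) -> None:
        self.get_custom(user, template_id)
        del self.custom[template_id]

    # -- persistence ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        data = {
            "next_id": self._next_id,
            "categories": [asdict(c) for c in self.categories.values()],
            "templates": [dict(asdict(t), status=t.status.value)
                          for t in self.templates.values()],
            "custom": [asdict(c) for c in self.custom.values()],
        }
        Path(path).write_text(json.dumps(data, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TemplateStore":
        data = json.loads(Path(path).read_text())
        store = cls()
        store._next_id = data["next_id"]
        for c in data["categories"]:
            store.categories[c["id"]] = Category(**c)
        for t in data["templates"]:
            t = dict(t, status=TemplateStatus(t["status"]))
            store.templates[t["id"]] = TemplateRecord(**t)
        for c in data["custom"]:
            store.custom[c["id"]] = CustomTemplate(**c)
        return store


# -- bundled default fixture -------------------------------------------------

def _ring(elements: list[str], bond_orders: list[BondOrder]) -> Molecule:
    n = len(elements)
    atoms = [Atom(el, x=cos(2 * pi * k / n), y=sin(2 * pi * k / n))
             for k, el in enumerate(elements)]
    bonds = [Bond(k, (k + 1) % n, bond_orders[k % len(bond_orders)])
             for k in range(n)]
    return Molecule(atoms=atoms, bonds=bonds)


def _chain(elements: list[str],
           orders: list[BondOrder] | None = None) -> Molecule:
    atoms = [Atom(el, x=0.87 * k, y=0.5 * (k % 2)) for k, el in enumerate(elements)]
    orders = orders or [BondOrder.SINGLE] * (len(elements) - 1)
    bonds = [Bond(k, k + 1, orders[k]) for k in range(len(elements) - 1)]
    return Molecule(atoms=atoms, bonds=bonds)


def _default_fixture_molecules() -> list[tuple[str, str, Molecule]]:
    """(category, template name, structure) rows of the packaged fixture.

    Category names and member structures are the package's own small fixture
    set; every structure is drawn with explicit coordinates and kekulized
    bonds so it round-trips through the V2000 writer.
    """
    S, D = BondOrder.SINGLE, BondOrder.DOUBLE
    kek = [S, D]
    benzene = _ring(["C"] * 6, kek)
    cyclohexane = _ring(["C"] * 6, [S])
    pyridine = _ring(["N", "C", "C", "C", "C", "C"], kek)
    pyrrole = _ring(["N", "C", "C", "C", "C"], [S, D, S, D, S])
    thf = _ring(["O", "C", "C", "C", "C"], [S])
    glycol = _chain(["O", "C", "C", "O"])
    glycine = _chain(["N", "C", "C", "O"])
    glycine.bonds.append(Bond(2, len(glycine.atoms), D))
    glycine.atoms.append(Atom("O", x=glycine.atoms[2].x, y=glycine.atoms[2].y - 1.0))
    acetic = _chain(["C", "C", "O"])
    acetic.bonds.append(Bond(1, 3, D))
    acetic.atoms.append(Atom("O", x=acetic.atoms[1].x, y=acetic.atoms[1].y - 1.0))
    boc = _chain(["O", "C", "O", "C"])  # carbamate core O-C(=O)-O-C(CH3)3
    boc.bonds[1] = Bond(1, 2, D)
    for dx, dy in ((0.87, 1.0), (-0.87, 1.0), (0.0, 1.5)):
        i = len(boc.atoms)
        boc.atoms.append(Atom("C", x=boc.atoms[3].x + dx, y=boc.atoms[3].y + dy))
        boc.bonds.append(Bond(3, i, S))
    nitrobenzene = _ring(["C"] * 6, kek)
    n_i = len(nitrobenzene.atoms)
    nitrobenzene.atoms.append(Atom("N", charge=1, x=2.0, y=0.0))
    nitrobenzene.atoms.append(Atom("O", charge=-1, x=2.7, y=0.7))
    nitrobenzene.atoms.append(Atom("O", x=2.7, y=-0.7))
    nitrobenzene.bonds += [Bond(0, n_i, S), Bond(n_i, n_i + 1, S),
                           Bond(n_i, n_i + 2, D)]

    return [
        ("carbocycles", "cyclohexane", cyclohexane),
        ("aromatics", "benzene", benzene),
        ("heterocycles", "pyridine", pyridine),
        ("heterocycles", "pyrrole", pyrrole),
        ("solvents", "tetrahydrofuran", thf),
        ("linkers", "ethylene glycol", glycol),
        ("amino acids", "glycine", glycine),
        ("functional groups", "acetic acid", acetic),
        ("protecting groups", "carbamate (Boc core)", boc),
        ("ligands", "pyridine ligand", pyridine.copy()),
        ("ligands", "ethylenediamine", _chain(["N", "C", "C", "N"])),
        ("dyes", "nitrobenzene", nitrobenzene),
    ]


def load_default_fixture(store: TemplateStore) -> dict[str, int]:
    """Populate an empty store with the packaged default library: 10
    categories whose member templates are all approved. Returns counts."""
    if not store.is_empty:
        raise StateError("default fixture requires an empty store")
    rows = _default_fixture_molecules()
    for cat_name in dict.fromkeys(name for name, _, _ in rows):
        store.create_category(UserRole.MODERATOR, cat_name)
    for cat_name, tpl_name, molecule in rows:
        record = store.add_template(UserRole.MODERATOR, molecule, tpl_name, cat_name)
        store.approve_template(UserRole.MODERATOR, record.id)
    return {"categories": len(store.categories), "templates": len(store.templates)}
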