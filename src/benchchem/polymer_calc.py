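"""Stoichiometry for polymer-supported (solid-phase) chemistry.

A supported molecule is drawn with a single pseudo atom — ``Pol`` for a resin
bead or ``Sur`` for a surface — bonded to the defined (non-polymeric) part.
For identifier lookups the pseudo atom is substituted by a methyl group
(:func:`export_defined_part`). The calculators implement the four standard
solid-phase bookkeeping operations on a simple mass-balance model:

    resin mass   = inert support mass + loading-proportional fragment mass
    product mass = start mass + converted moles × (M_fp − M_fs)

where loading L is in mmol of functional sites per gram, M_fs / M_fp are the
average masses of the immobilized start/product fragments, and the number of
sites n_s = m_s · L (mmol) is conserved through the reaction.

The four calculations:

1. expected elemental composition of a loaded resin of known backbone
   composition (:func:`loaded_elemental_composition`);
2. yield from the product mass (:func:`yield_from_mass`);
3. yield from an elemental analysis of the product
   (:func:`yield_from_elemental_analysis`);
4. product loading assuming full conversion
   (:func:`loading_after_full_conversion`).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .chemgraph import (
    Atom,
    Formula,
    Molecule,
    average_mass,
    element_mass_fractions,
)
from .errors import (
    DegenerateMarkerError,
    DegenerateMassError,
    LoadingError,
    SupportModelError,
)
from .masses import ATOMIC_WEIGHTS

#: The four supported calculation modes, in the order they are documented.
CALCULATION_MODES: tuple[str, ...] = (
    "composition", "yield-mass", "yield-ea", "loading")


@dataclass(frozen=True)
class PolymerComposition:
    """Average composition of the support backbone.

    ``repeat_formula`` is the average repeat unit; ``crosslink_fraction`` is
    the mole fraction of repeat units replaced by the crosslinker (e.g. 0.01
    for a 1% DVB polystyrene); ``loading`` is in mmol of functional sites
    per gram of resin.
    """

    polymer_type: str
    repeat_formula: Formula
    loading: float
    crosslink_formula: Formula | None = None
    crosslink_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.loading <= 0:
            raise LoadingError(f"loading must be positive, got {self.loading}")
        if not 0.0 <= self.crosslink_fraction <= 1.0:
            raise LoadingError(
                f"crosslink fraction must be in [0, 1], got {self.crosslink_fraction}")
        if self.crosslink_fraction > 0 and self.crosslink_formula is None:
            raise LoadingError("crosslink fraction set without a crosslink formula")

    def backbone_mass_fractions(self) -> dict[str, float]:
        """Element mass fractions of the repeat/crosslink blend."""
        counts = {el: n * (1.0 - self.crosslink_fraction)
                  for el, n in self.repeat_formula.items()}
        if self.crosslink_formula is not None and self.crosslink_fraction > 0:
            for el, n in self.crosslink_formula.items():
                counts[el] = counts.get(el, 0.0) + n * self.crosslink_fraction
        total = sum(n * ATOMIC_WEIGHTS[el] for el, n in counts.items())
        return {el: n * ATOMIC_WEIGHTS[el] / total for el, n in counts.items()}


@dataclass(frozen=True)
class SupportedMolecule:
    """A molecule with exactly one singly-bonded pseudo atom, optionally
    annotated with the backbone composition."""

    molecule: Molecule
    composition: PolymerComposition | None = None

    def __post_init__(self) -> None:
        _find_support_atom(self.molecule)


@dataclass(frozen=True)
class ResinBatch:
    """A weighed portion of functionalized resin.

    ``fragment_formula`` is the formula of the immobilized non-polymeric
    part only (the defined part, support excluded).
    """

    mass: float
    loading: float
    fragment_formula: Formula

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise LoadingError(f"resin mass must be positive, got {self.mass}")
        if self.loading <= 0:
            raise LoadingError(f"loading must be positive, got {self.loading}")
        if self.loading * 1e-3 * average_mass(self.fragment_formula) >= 1.0:
            raise LoadingError(
                "fragment mass per gram exceeds 1 g: loading and fragment "
                "formula are inconsistent")

    @property
    def millimoles(self) -> float:
        return millimoles_on_resin(self.mass, self.loading)


@dataclass(frozen=True)
class YieldResult:
    """Yield of a polymer-supported reaction.

    ``yield_fraction`` is clamped to [0, 1]; ``yield_fraction_raw`` keeps the
    uncorrected value and ``clamped`` flags inputs that imply an impossible
    conversion (measurement noise) rather than hiding them.
    """

    yield_fraction: float
    yield_fraction_raw: float
    clamped: bool
    millimoles_start: float
    millimoles_product: float


def _find_support_atom(m: Molecule) -> int:
    pseudo = [i for i, a in enumerate(m.atoms) if a.is_pseudo]
    if len(pseudo) != 1:
        raise SupportModelError(
            f"supported molecule needs exactly one pseudo atom, found {len(pseudo)}")
    idx = pseudo[0]
    degree = sum(1 for b in m.bonds if idx in (b.a, b.b))
    if degree != 1:
        raise SupportModelError(
            f"support pseudo atom must have exactly one bond, found {degree}")
    return idx


def export_defined_part(s: SupportedMolecule) -> Molecule:
    """Substitute the support symbol with a methyl carbon.

    The pseudo atom becomes a carbon at the same position; its remaining
    valence is filled by the implicit-H model, i.e. a methyl group when the
    support was singly bonded. The result contains no pseudo atoms and is
    accepted by :func:`benchchem.chemgraph.molecular_formula`.
    """
    idx = _find_support_atom(s.molecule)
    out = s.molecule.copy()
    old = out.atoms[idx]
    out.atoms[idx] = Atom(element="C", x=old.x, y=old.y, z=old.z)
    return out


def millimoles_on_resin(mass: float, loading: float) -> float:
    """Functional sites on a resin portion, in mmol (= mass g × loading mmol/g)."""
    if mass <= 0 or loading <= 0:
        raise LoadingError("mass and loading must both be positive")
    return mass * loading


def loaded_elemental_composition(
    composition: PolymerComposition, fragment: Formula,
) -> dict[str, float]:
    """Calculation 1: expected elemental analysis of a loaded resin, in mass %.

    Per gram of resin the fragment contributes ``loading·10⁻³`` mol of its
    atoms; the remaining mass has the element fractions of the backbone
    blend. Percents sum to 100.
    """
    n = composition.loading * 1e-3  # mol fragment per g resin
    fragment_mass = n * average_mass(fragment)
    if fragment_mass >= 1.0:
        raise LoadingError(
            "loading × fragment mass exceeds 1 g per gram of resin")
    backbone_mass = 1.0 - fragment_mass
    grams: dict[str, float] = {
        el: backbone_mass * frac
        for el, frac in composition.backbone_mass_fractions().items()
    }
    for el, count in fragment.items():
        grams[el] = grams.get(el, 0.0) + n * count * ATOMIC_WEIGHTS[el]
    return {el: 100.0 * g for el, g in sorted(grams.items())}


def _yield_result(raw: float, n_s: float) -> YieldResult:
    clamped = min(max(raw, 0.0), 1.0)
    return YieldResult(
        yield_fraction=clamped,
        yield_fraction_raw=raw,
        clamped=clamped != raw,
        millimoles_start=n_s,
        millimoles_product=clamped * n_s,
    )


def yield_from_mass(
    start: ResinBatch, product_fragment: Formula, product_mass: float,
) -> YieldResult:
    """Calculation 2: yield from the weighed product mass.

    Inverts ``m_p = m_s + n_s·10⁻³·y·(M_fp − M_fs)``. Requires the fragment
    masses to differ, otherwise the mass balance carries no information.
    """
    if product_mass <= 0:
        raise LoadingError(f"product mass must be positive, got {product_mass}")
    m_fs = average_mass(start.fragment_formula)
    m_fp = average_mass(product_fragment)
    if m_fp == m_fs:
        raise DegenerateMassError(
            "product and start fragments have equal mass; yield is "
            "unobservable from the mass change")
    n_s = start.millimoles
    raw = (product_mass - start.mass) / (n_s * 1e-3 * (m_fp - m_fs))
    return _yield_result(raw, n_s)


def yield_from_elemental_analysis(
    start: ResinBatch,
    product_fragment: Formula,
    marker: str,
    measured_percent: float,
    composition: PolymerComposition | None = None,
) -> YieldResult:
    """Calculation 3: yield from the product's elemental analysis.

    Solves the closed-form linear equation

        p/100 = [n·(y·a_p + (1−y)·a_s)·A + S] / [m_s + n·y·(M_fp − M_fs)]

    for the conversion y, where n = n_s·10⁻³ mol, a_s/a_p are the marker
    counts in the start/product fragments, A the marker's atomic weight and
    S the marker mass contributed by the support backbone (zero unless a
    backbone ``composition`` is supplied).
    """
    if marker not in ATOMIC_WEIGHTS:
        raise DegenerateMarkerError(f"unknown marker element {marker!r}")
    a_s = start.fragment_formula.get(marker, 0)
    a_p = product_fragment.get(marker, 0)
    A = ATOMIC_WEIGHTS[marker]
    n_s = start.millimoles
    n = n_s * 1e-3
    m_fs = average_mass(start.fragment_formula)
    m_fp = average_mass(product_fragment)
    d_m = m_fp - m_fs

    S = 0.0
    if composition is not None:
        support_mass = start.mass - n * m_fs
        S = support_mass * composition.backbone_mass_fractions().get(marker, 0.0)

    p = measured_percent / 100.0
    denom = n * (p * d_m - A * (a_p - a_s))
    if denom == 0.0:
        raise DegenerateMarkerError(
            f"marker {marker} percent is insensitive to conversion")
    raw = (n * A * a_s + S - p * start.mass) / denom
    return _yield_result(raw, n_s)


def marker_percent_at_yield(
    start: ResinBatch,
    product_fragment: Formula,
    marker: str,
    y: float,
    composition: PolymerComposition | None = None,
) -> float:
    """Forward model for calculation 3: expected marker mass percent at
    conversion ``y``. The inverse of :func:`yield_from_elemental_analysis`."""
    a_s = start.fragment_formula.get(marker, 0)
    a_p = product_fragment.get(marker, 0)
    A = ATOMIC_WEIGHTS[marker]
    n = start.millimoles * 1e-3
    m_fs = average_mass(start.fragment_formula)
    m_fp = average_mass(product_fragment)
    S = 0.0
    if composition is not None:
        support_mass = start.mass - n * m_fs
        S = support_mass * composition.backbone_mass_fractions().get(marker, 0.0)
    marker_mass = n * (y * a_p + (1.0 - y) * a_s) * A + S
    total_mass = start.mass + n * y * (m_fp - m_fs)
    return 100.0 * marker_mass / total_mass


def product_mass_at_yield(
    start: ResinBatch, product_fragment: Formula, y: float,
) -> float:
    """Forward model for calculation 2: expected product mass at conversion ``y``."""
    d_m = average_mass(product_fragment) - average_mass(start.fragment_formula)
    return start.mass + start.millimoles * 1e-3 * y * d_m


def loading_after_full_conversion(start: ResinBatch, product_mass: float) -> float:
    """Calculation 4: product loading in mmol/g assuming full conversion.

    The n_s mmol of sites are conserved and now sit on ``product_mass``
    grams of resin.
    """
    if product_mass <= 0:
        raise LoadingError(f"product mass must be positive, got {product_mass}")
    return start.millimoles / product_mass


def batch_after_reaction(start: ResinBatch, product_fragment: Formula) -> ResinBatch:
    """The batch obtained at full conversion: same sites, new fragment, new mass."""
    m_p = product_mass_at_yield(start, product_fragment, 1.0)
    return replace(start, mass=m_p, loading=start.millimoles / m_p,
                   fragment_formula=product_fragment)
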