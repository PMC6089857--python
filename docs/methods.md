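# Methods

## Molecular graph and the implicit-hydrogen model

A molecule is an ordered atom list plus a bond list; atom indices are
0-based in memory and 1-based in molfiles. Elements are validated against a
bundled table (Z ≤ 92); two pseudo labels are additionally allowed, `Pol`
(polymer bead) and `Sur` (surface), which are excluded from all formula and
mass arithmetic until substituted.

Implicit hydrogens are filled to a target valence from the table
`{H:1, B:3, C:4, N:3, O:2, F:1, Si:4, P:3, S:2, Cl:1, Br:1, I:1}`; every
other element receives none. Charge shifts the target by `+charge` for the
nitrogen family (N, P, As, Sb, Bi) and by `−|charge|` for the oxygen family
(O, S, Se, Te), matching common V2000 semantics (ammonium → 4 H,
hydroxide → 1 H). A dative bond consumes one valence unit at the donor
(first atom of the bond) and none at the acceptor: an amine donating into a
metal or borane keeps the hydrogen count chemists expect. Aromatic bond
orders are rejected in formula computation with an instruction to kekulize
first — aromatic perception is out of scope and a silent guess would
produce wrong hydrogen counts. Structures are therefore stored kekulized
throughout (the bundled fixtures are drawn that way).

Masses come from a frozen table of conventional atomic weights and
most-abundant-isotope masses (the values distributed with mainstream
cheminformatics toolkits); nothing is fetched at run time. Any
self-consistent IUPAC table differs from another in the third decimal at
most, which is why mass assertions in the tests use 1e-3 g/mol tolerances
against values computed from this table.

## Molfile dialect

Reading accepts V2000 and V3000; writing always emits V2000 (fixed-width
columns, coordinates `%10.4f`, lines ≤ 80 chars, capacity 999 atoms/bonds).
Bond types map bijectively `{1,2,3,4,9} ↔ {single, double, triple,
aromatic, dative}`. The type-9 coordinative bond is a V3000 feature
backported into the V2000 bond block; the dashed-vs-arrow display of a
dative bond is an in-memory rendering hint only — both serialize to type 9
and deserialize as arrow, since the V2000 bond block has no field for the
distinction. Donor/acceptor orientation rides on atom order in the bond
line (first = donor), the format's only free degree of freedom. Pseudo
atoms occupy the atom-symbol field directly (`Pol`, `Sur`) — non-standard
but round-trip safe. Charges and isotopes are written as `M  CHG`/`M  ISO`
property lines; the legacy atom-block charge column is understood on input
for files from other tools. SDF records are split on `$$$$`; strict parsing
raises on the first malformed record with its index, lenient parsing (used
for bulk template import) skips bad records.

## Solid-phase stoichiometry

The mass-balance model: one gram of resin is an inert support plus
`L·10⁻³` mol of immobilized fragment; a reaction converts sites without
creating or destroying them, so product mass is
`m_p = m_s + n_s·10⁻³·y·(M_fp − M_fs)` with `n_s = m_s·L` mmol. All four
calculations are closed-form consequences:

1. **Composition** — fragment contributes `L·10⁻³·count·A_E` g of each
   element per gram; the remaining `1 − L·10⁻³·M_f` g follows the backbone
   blend. Crosslinking replaces a mole fraction of repeat units with
   crosslinker units; element fractions of the blend are mass-weighted over
   the average unit. Percents close to 100 by construction (asserted to
   1e-6).
2. **Yield from mass** — the linear inverse of the mass balance; undefined
   (raised as a degenerate-mass error) when `M_fp = M_fs`.
3. **Yield from elemental analysis** — the marker percent is a ratio of two
   affine functions of `y`, so the inverse is a single linear solve; it
   degenerates exactly when the marker is insensitive to conversion (zero
   denominator). Marker mass contributed by the support backbone is
   included only when a backbone composition is passed, since routine
   analyses of polystyrene resins have no backbone N/S/halogen; passing the
   composition matters for e.g. polyamide supports and shifts the solution
   accordingly.
4. **Loading at full conversion** — site conservation: `L_p = n_s / m_p`.

Yields outside [0, 1] arise from measurement noise; both the raw and the
clamped value are returned with a flag, because hiding impossible inputs
from a notebook user invites silent bookkeeping errors. `Pol` and `Sur`
structures are treated identically by every calculator — loading in mmol/g
is support-kind-agnostic. Kinetics, swelling and site–site interactions are
deliberately out of scope.

The parameter-recovery sweeps in the tests and the acceptance script draw
resin mass from U(0.1, 10) g, loading from U(0.1, 3) mmol/g and alkyl
fragments of 2–15 carbons — the range of ordinary bench-scale solid-phase
batches — and require the calculators to invert their forward models to
1e-9 (mass route) and 1e-6 (analysis route), i.e. to numerical precision.

## Oligomer assembly

Monomer templates are fragments whose primary and secondary attachment
atoms each hold at least one implicit hydrogen (an open valence). Assembly
concatenates deep copies of the fragments and adds one single bond per
junction, secondary atom of residue *i* → primary atom of residue *i+1* —
a single fixed convention keeps written files canonical. No atoms are
removed; each new bond simply consumes one implicit H on both sides, so
the assembled formula equals the monomer formula sum minus `2·(k−1)` H.
No condensation chemistry (leaving groups) is modelled: templates are
stored as the user draws them. `reversed` order reverses the monomer list
before assembly (the N↔C flip), not the individual monomers.

Layout translates each residue rigidly so its primary atom lands 1.0
molfile unit along +x from the previous residue's secondary atom —
deterministic, no force field. The bundled library holds seven peptoid
(N-substituted glycine) monomers under their side-chain abbreviations:
N2Ph (phenethyl), N1cPr (cyclopropylmethyl), N2iPr (isopentyl), N2Me
(propyl), N3m (methoxypropyl), N1ph (benzyl), N1ppg (propargyl). The
backbone is drawn as N–CH2–C(=O) with the side chain on nitrogen; the
side-chain structures are this package's fixture choices for those
abbreviations. Libraries can also be loaded from SDF with
`abbreviation` / `primary_atom` / `secondary_atom` (1-based) properties.

## Template store

Workflow semantics over a single JSON file: moderators manage categories
and common templates; every import (drawn, single molfile, or bulk SDF)
enters as *pending* and only *approved* records reach default listings,
ordered by name. Approval is idempotent. Custom templates are private to
their creator on every read path — non-owners get a not-found error rather
than a permission hint, so existence does not leak. Icons are generated as
minimal SVG (bond line segments, heteroatom labels, parallel lines for
multiple bonds, dashes for dative); PNG thumbnails are out of scope as
raster output adds a heavy dependency without test value. Abbreviations
and monomer registrations reuse the template record with a `kind` flag and
the same pending/approved workflow, chosen for uniformity. The default
fixture ships 10 categories with 12 small kekulized structures, all
approved; the category names and members are fixture choices — the count
of ten category groups is the normative part.

## Synthetic data in the tests

Randomly generated molecules (≤ 20 atoms, all five bond orders, charges,
isotopes, pseudo atoms, coordinates pre-rounded to the writer's 4-decimal
precision) exercise the round-trip guarantee; they are random graphs, not
chemically sensible structures, so passing says the serialization is
lossless, not that arbitrary real-world molfiles (Sgroups, rxnfiles,
queries) are supported — those features are explicitly out of scope.
Likewise the resin sweeps validate algebraic self-consistency of the
calculators; they cannot validate the mass-balance model against real
elemental analyses, which carry instrument error the model only
acknowledges through the clamp-and-flag mechanism.

## Numerical choices

- Degenerate inputs raise typed errors rather than returning NaN: equal
  fragment masses (calc 2), conversion-insensitive markers (calc 3),
  overloaded fragments (`L·10⁻³·M_f ≥ 1`).
- Equality of molecules after a round trip compares coordinates to 4
  decimals (the V2000 field precision) and everything else exactly.
- Text-mode CLI output is fixed to 4 decimals; JSON carries the same
  rounded values. Listings sort by (name, id) so output is stable.
- The acceptance script seeds one `random.Random` from `--seed` and reuses
  it sequentially; problem sizes (500 round-trip molecules, 1000 recovery
  draws, 200–300 sweep draws) keep the full run in seconds while making a
  counting violation or recovery error ≥ 1e-6 essentially impossible to
  miss.
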