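# benchchem

Headless cheminformatics for electronic-lab-notebook (ELN) style bench
workflows. The package provides, as a plain Python library plus a small CLI,
the computational core an ELN needs around a structure editor:

- **Molecular graphs and formula arithmetic** — atoms/bonds with 2D/3D
  coordinates, implicit-hydrogen completion under the common V2000 valence
  model, Hill formula strings, molecular weight and exact (monoisotopic)
  mass from a bundled element table.
- **Molfile I/O with a coordinative-bond dialect** — reads V2000 and V3000
  connection tables and multi-record SDF, writes V2000. Dative
  (coordinative) bonds, needed for organometallic structures, are encoded
  with bond type 9 — a V3000 feature backported into the V2000 bond block —
  and survive the round trip; the donor is the first atom of the bond line.
- **Solid-phase (polymer-supported) stoichiometry** — structures drawn with
  a `Pol` (resin bead) or `Sur` (surface) pseudo atom, methyl substitution
  of the support for identifier export, and the four standard calculations:
  expected elemental composition of a loaded resin, yield from product
  mass, yield from elemental analysis, and product loading at full
  conversion.
- **Oligomer assembly** — peptoid-style chains built from monomer templates
  with primary/secondary attachment atoms, driven by a hyphen-separated
  sequence string (e.g. `N2Ph-N1cPr-N2iPr-N2Me-N3m-N1ph-N1ppg`), in normal
  or reversed (N↔C) order; seven peptoid monomers are bundled.
- **A moderated template store** — named categories, bulk SDF import where
  every structure enters as *pending* and only *approved* templates appear
  in default listings, plus per-user private custom templates with
  generated SVG icons. Single-file JSON persistence.

## The model behind the resin calculators

A functionalized resin is treated as an inert support plus a
loading-proportional immobilized fragment. With start mass `m_s` (g),
loading `L` (mmol of sites per g) and fragment masses `M_fs`/`M_fp` (g/mol)
for the start/product fragments, the number of sites `n_s = m_s·L` (mmol)
is conserved and

```
m_p(y)   = m_s + n_s·10⁻³ · y · (M_fp − M_fs)                    (mass balance)
%E(y)    = 100 · [n_s·10⁻³·(y·a_p + (1−y)·a_s)·A_E + S_E] / m_p(y)   (marker E)
L_p      = n_s / m_p(1)                                       (full conversion)
```

The yield calculators are the exact algebraic inverses of these forward
models; `a_s`, `a_p` are marker-element counts in the two fragments, `A_E`
the atomic weight and `S_E` the (optional) marker mass contributed by the
support backbone. Yields outside [0, 1] are flagged and clamped, never
silently corrected. Composition (calculation 1) distributes each gram of
resin between `L·10⁻³` mol of fragment atoms and a backbone blend of repeat
and crosslinker units mixed by mole fraction.

## Worked example

A chloromethylated polystyrene resin loaded at 1.00 mmol/g
(`-CH2Cl` fragment on a `C8H8` backbone):

```
$ benchchem resin composition --repeat C8H8 --loading 1.0 --fragment CH2Cl
C  88.8937
Cl 3.5453
H  7.5610
```

Expected elemental analysis in mass percent: ~3.55 % Cl is the signature of
1.00 mmol/g of chloromethyl sites; the percents always close to 100.

Yield of an amination read off a nitrogen elemental analysis (start
fragment `C7H16`, product gains one N, measured 1.245 %N on 1.000 g of
1.00 mmol/g resin):

```
$ benchchem resin yield-ea --mass 1.0 --loading 1.0 --fragment C7H16 \
    --product-fragment C7H16N --marker N --percent 1.245
0.9000
```

i.e. 90 % of the sites converted. Loading after a mass gain at full
conversion (2.000 g at 0.80 mmol/g grows to 2.100 g):

```
$ benchchem resin loading --mass 2.0 --loading 0.8 --product-mass 2.1
0.7619
```

Building the seven-residue peptoid from the bundled monomer library:

```
$ benchchem oligo build --sequence "N2Ph-N1cPr-N2iPr-N2Me-N3m-N1ph-N1ppg" \
    --out peptoid.mol
63 atoms, 65 bonds, C48H69N7O8 872.1210
```

The written molfile carries a deterministic left-to-right chain layout.
Every number above is also available as JSON via `--format json`.

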