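# Methods

This note records the models implemented by `picontact`, the
conventions chosen where the underlying definitions are ambiguous, what
the synthetic generators do and do not emulate, and the package's known
limitations.

## Planar-group model

A *planar group* is the maximal conjugated heavy-atom set of an sp²
side chain or of a peptide amide. The registry (see
`structure_io.DEFAULT_REGISTRY`) defines, per residue type, the plane
atoms, the residue class and the formal charge:

| group | plane atoms | class | charge |
|---|---|---|---|
| backbone amide | C_i, O_i, N_{i+1} (+ H_{i+1} when present) | backbone | 0 |
| Phe / Tyr | CG, CD1, CD2, CE1, CE2, CZ | aromatic | 0 |
| Trp | CG, CD1, CD2, NE1, CE2, CE3, CZ2, CZ3, CH2 | aromatic | 0 |
| His | CG, ND1, CD2, CE1, NE2 | aromatic | 0 |
| Asn / Gln | CG/CD, OD1/OE1, ND2/NE2 | hydrophilic | 0 |
| Asp / Glu | CG/CD, OD1/OE1, OD2/OE2 | charged | −1 |
| Arg | CZ, NE, NH1, NH2 | charged | +1 |

Conventions and their rationale:

* **Amide hydrogen is optional.** X-ray structures routinely omit
  hydrogens; the plane fit needs only three atoms, so the amide plane
  falls back to C, O, N. When H is present it joins the projected atom
  set.
* **Tyr OH excluded** from the plane set (the hydroxyl oxygen is not
  part of the conjugated ring proper); the registry is data-driven and
  YAML-overridable, so including it is a one-line change.
* **Histidine is neutral aromatic**; HID/HIE/HIP/HSD/HSE/HSP names all
  map to His. Asp/Glu are deprotonated and Arg protonated, matching
  the class assignments at physiological pH.
* **Backbone amides require residue i+1**: N-terminal amides are never
  emitted, and completeness is judged per group — incomplete groups are
  skipped with a warning, never fabricated.
* **Alternate locations**: only blank or 'A' altlocs are kept;
  occupancies are ignored.

## The geometric criterion

A pair of planes is a pi–pi contact iff (i) after displacing each
plane's atoms 1.7 Å along its normal *toward the partner*, at least
`min_pairs = 2` cross-plane atom pairs are ≤ 1.5 Å apart, and (ii)
|n̂₁·n̂₂| ≥ 0.8. Numerical conventions:

* **Plane fit** is total least squares: the normal is the smallest
  right singular vector of the centered coordinates; degenerate
  (collinear) inputs raise rather than returning an arbitrary plane.
  The fitted normal's sign is arbitrary, hence:
* **Projection direction.** Each group's normal is oriented toward the
  other group's centroid before displacing. Projecting toward the
  partner is the only reading under which 1.7 Å — the carbon van der
  Waals radius — models surface contact; a `both_signs` option computes
  the minimum over all four sign combinations for sensitivity checks.
  When the two centroids coincide the direction is undefined and the
  normals are pointed away from each other, so coincident planes
  project *through* one another symmetrically.
* **Angle rule uses |dot|** because fitted normals are sign-ambiguous
  and the stated angular range (0–~36°) is unsigned.
* **Ties pass**: the rules are ≤ and ≥, so a pair distance of exactly
  the cutoff or a dot of exactly 0.8 qualifies.
* **Pair counting** counts all unordered cross-group atom pairs; two
  qualifying pairs may share an atom (the rule constrains pair
  membership, not disjointness). For 1.39 Å rings this means a
  perfectly stacked cofacial pair has 18 close pairs, not 6 — adjacent
  ring atoms are themselves within 1.5 Å.
* **Exclusions** (configurable): pairs sharing an atom, backbone amides
  of adjacent peptide units (sharing a residue), and a side chain
  against its own residue's amides. Covalently coupled planes are not
  noncovalent contacts; the defaults are conservative and logged.

Analytic consequences used as test oracles: cofacial aligned rings flip
from contact to non-contact exactly at separation 2×1.7 + 1.5 = 4.9 Å,
and tilted rings flip between 36° (cos 36° ≈ 0.809) and 37°
(cos 37° ≈ 0.799). All three thresholds and the pair count are
parameters because contact counts are sensitive to these hard cutoffs.

## Fragment capping

Caps never move input atoms; added hydrogens are the only new
coordinates. Bond lengths are idealized standards: C–H 1.09 Å, N–H
1.01 Å. Side chains keep every atom from Cβ outward plus existing
side-chain hydrogens, and gain one hydrogen along the severed Cβ→Cα
bond. Backbone amides become N-methylacetamide: the flanking Cα atoms
stay at their crystallographic positions and are completed to methyls
(three hydrogens each, tetrahedral, azimuth anchored to existing α
hydrogens or else staggered relative to the amide plane); the amide
hydrogen is reused when present, otherwise placed along the sp²
bisector. The resulting valence table (Phe → C7H8, Tyr → C7H8O, Trp →
C9H9N, His → C4H6N2 in the Nε-H tautomer, Asp → C2H3O2⁻, Glu →
C3H5O2⁻, Asn → C2H5NO, Gln → C3H7NO, Arg → C4H12N3⁺, backbone →
C3H7NO) is asserted in the tests. Dimer geometry optimization and
alignment are out of scope — fragments are written as they sit in the
structure.

## Decomposition bookkeeping and ternary composition

The module performs arithmetic over externally supplied components
only; no quantum chemistry happens here. The canonical unit is kJ/mol
(kcal/mol inputs are converted by 4.184 on read). Identities enforced
at machine precision: total = frozen + dispersion + orbital; gas-phase
records carry no solvation correction and ε = 1; solvation replaces
every term except dispersion, which is copied unchanged (the continuum
is assumed not to affect it). The solvation correction is carried on
the electrostatic/frozen side of the ledger, so it enters the signed
vertex in *both* ternary variants ("frz" = elec + Pauli + solv;
"elst" = elec + solv). Nonelectrostatic solvation terms are accepted
as an optional field but excluded by default, matching an
electrostatics-only continuum. A zero composition denominator raises
rather than returning a point.

Classification rules, evaluated in order with first match winning:

1. both monomers charged → **ion–ion** (monopole electrostatics
   dominates regardless of the remaining balance);
2. exactly one charged → **ion–pi**;
3. neutral pi contact with repulsive gas-phase electrostatics →
   **Hunter–Sanders**;
4. neutral, attractive electrostatics but repulsive frozen energy
   (|ΔE_Pauli| > |ΔE_elec|) → **vdW/CFH**;
5. otherwise **indeterminate** (e.g. a neutral pair whose frozen energy
   is attractive).

The HS/CFH boundary is the *sign* of gas-phase electrostatics; no
magnitude threshold exists in the underlying definitions, so none is
invented. The headline Hunter–Sanders fraction is computed over all
pi contacts pooled across the BBBB/SCBB/SCSC subsets (per-subset
fractions are also reported) and rounded to the nearest integer
percent. Neutral contacts with attractive frozen energy are reported
as indeterminate rather than silently folded into CFH.

## Synthetic generators

All generators are pure functions of their seeds.

* **Geometries** are regular n-gons (default benzene-like hexagons,
  C–C 1.39 Å) at controlled separation, lateral offset and tilt, plus
  a seeded random motif; each group carries its exact analytic normal
  for oracle comparison. Benchmark frames plant cofacial pairs at
  3.5 Å among decoys spaced 30 Å apart with random orientations, so
  ground truth is unambiguous.
* **Decomposition records** are drawn per class from truncated-uniform
  families constrained to (a) the published per-subset total-energy
  envelopes (neutral aromatic −23…−2, hydrophilic −41…+5,
  charged–charged −463…+298, aromatic–hydrophilic −24…+13 kJ/mol) and
  (b) the qualitative dominance orderings: neutral stacks are
  dispersion-dominant with mildly attractive electrostatics outweighed
  by Pauli repulsion; the HS-like class has repulsive electrostatics;
  ion–ion is electrostatics-dominant of either sign; ion–pi balances
  orbital and dispersion terms with a modest frozen energy. The PCM
  transform scales electrostatics to 12–30 % and polarization to
  8–25 % of their gas values, reduces charge transfer to 60–80 %, and
  leaves Pauli repulsion and dispersion untouched — chosen so the
  dielectric-screening property (the orbital share of every ion–pi
  record shrinks in solvent) holds by construction, as it should for
  a high dielectric.

What passing tests on these fixtures show: the detector, bookkeeping
and classifier are exact on inputs whose ground truth is known. What
they do not show: agreement with any particular empirical distribution
of protein-fragment energetics — the generator reproduces envelopes and
orderings, not the full spread, correlations or geometry–energy
coupling of real dimers. Analyses of the authors' deposited
protein-fragment database run through the same code path
(`read_eda_json` → `summarize`) when that data is available locally.

## Problem sizes

The test suite and the acceptance script run at the sizes that make
their checks conclusive while staying quick: 1,000 randomized dimers
for brute-force equivalence (both outcomes well represented), a
10,000-record mixed suite for the exact normalization and bookkeeping
identities, 500 records for label recovery, and 20-ring frames with 5
planted contacts for detection. All are seeds-in, numbers-out.

## Known limitations

* PDB input only (no mmCIF); nucleic-acid and ligand pi systems are
  out of scope.
* Geometric subtyping of contacts (T-shaped vs parallel-displaced
  classes) is not performed; the criterion is binary by design.
* The capping geometry uses idealized bond lengths and tetrahedral
  methyls; it does not energy-minimize fragments.
* The JSON adapter for foreign decomposition schemas is alias-table
  driven; genuinely novel layouts need a one-line alias addition, not
  code changes.
* The idealized residue builder produces hydrogen-complete, chemically
  sensible geometry for fixtures, not Ramachandran-realistic
  conformers.
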