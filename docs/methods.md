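# Methods

## Energy model

The package evaluates the classical AMBER potential: harmonic bonds
k_b(l−l_0)² and angles k_a(θ−θ_0)², a four-slot cosine series for proper
torsions Σ_{i=1..4} k_{d,i}(1+cos(i·φ−A_i))/N where slot *i* carries
periodicity *i* and N is the path-multiplicity divisor, the out-of-plane
(improper) term k_i(1−cos(P(σ−A))), and Lennard-Jones plus Coulomb
nonbonded terms over **all** atom pairs — no cutoff, no periodic boundary
conditions, vacuum electrostatics with fixed point charges.  Units
throughout: kcal/mol, Å, degrees in parameter tables, elementary charge.

The Coulomb prefactor 1/(4πε₀) is fixed at 332.063712827427
kcal·mol⁻¹·Å·e⁻².  The 1-4 scale factors are 0.5 (Lennard-Jones) and
1/1.2 (Coulomb, computed as `1.0/1.2` in double precision); 1-2 and 1-3
pairs are fully excluded.  Pair classification uses the *minimal* covalent
path length (breadth-first search truncated at depth 3), so ring closures
take the shorter path: opposite atoms of a four-membered ring are 1-3, not
1-5.  This matches standard AMBER exclusion-list construction.

## Geometry kernels

Bend angles come from the clamped arccosine of the normalized dot product
(the clamp guards |cos θ| overshooting 1 by floating-point noise near
collinearity).  Dihedrals are *signed* angles in (−π, π] computed from the
two plane normals (cross products of consecutive bond vectors) with the
sign taken from the central-bond axis via an atan2 formulation.  A signed
angle is strictly more general than the unsigned plane-angle; for the
cosine series with phase offsets 0° or 180° (the overwhelmingly common
AMBER convention, and the only phases in the built-in palette) the energy
is even in φ, so the sign convention cannot change any result and a
quadruple and its reversal score identically.  Impropers are evaluated as
the dihedral of the four atoms in listed order with the central atom kept
third.  Degrees→radians conversion happens exactly once, inside the
kernels, so parameter tables stay byte-faithful to their source.

Collinear torsion axes and zero-length angle arms raise evaluation errors
naming the offending atoms; they are geometry defects, not recoverable
states.

## Term enumeration

Bonded terms are derived from covalent connectivity alone: every bond
(i<j once), every two-bond path as an angle (canonical orientation i<k),
every simple four-atom path as a proper torsion (deduplicated under
reversal; ring-closing paths included), and every atom with exactly three
neighbours as an improper candidate.  For a candidate centre the neighbour
orderings (sorted by index, then lexicographic permutations) are tried
against the improper table, whose keys are orientation-insensitive in the
three non-central positions; the first match is emitted with the centre
third.  A candidate without parameters produces a warning and is skipped —
missing impropers are advisory, whereas missing bond/angle/torsion
parameters abort the calculation with an error naming the type sequence,
since those terms are never optional in a consistent topology.

## Parameter handling

Parameters live in type-keyed tables parsed from either a Gaussian-style
MM record block (`VDW`, `HrmStr1`, `HrmBnd1`, `AmbTrs`, `ImpTrs`) or a
PRMTOP file.  Lookup keys are canonicalized (bond/angle/torsion symmetric
under reversal); duplicate records after canonicalization keep the first
occurrence and record a warning — deterministic behaviour was preferred
over silent summation of conflicting records.  Wildcard atom types are not
supported.

From PRMTOP, per-type (R, ε) are recovered by inverting the diagonal
Lennard-Jones coefficients: ε = B²/(4A), D = (2A/B)^(1/6), R = D/2;
degenerate diagonals (zero A and/or B) yield R = ε = 0 with a warning.
Off-diagonal coefficients are *recomputed* from per-type values through
Lorentz–Berthelot, so topologies carrying NBFIX-style pair-specific edits
will diverge — a documented limitation.  Charges are stored in PRMTOP
premultiplied by 18.2223 and are divided out on read so the fixed Coulomb
prefactor applies to charges in e.  Torsion entries sharing a type
quadruple are merged into the four periodicity slots; per-dihedral
SCEE/SCNB sections are ignored in favour of the global 1/1.2 and 0.5
factors.  Written parameter blocks use fixed-point with four decimals
whenever that representation is exact (the conventional appearance) and
full `repr` precision otherwise, which makes parse∘write the identity.

## Partitioning

A fragment scheme is a total map atom → label built from disjoint user
selections; unselected atoms form the reserved remainder `X`, and empty
fragments are dropped.  Each bonded term and each nonbonded pair is
evaluated exactly once and accumulated into the bucket keyed by the sorted
set of distinct labels among its atoms (so `1−2` and `2−1` are one
bucket).  A scaled 1-4 pair is routed by its two end atoms only.  No term
can span more than four labels because no term has more than four atoms.
Buckets that receive no terms are omitted rather than printed as zero.
Because the partition reuses the same per-term and per-pair values the
total-energy path produces, conservation — total equals the sum of all
buckets — holds to summation-reordering error only, observed ≤ 1e-12
relative and asserted at 1e-9 kcal/mol absolute in the tests.

## Determinism and parallel reduction

Bonded terms accumulate in enumeration order; the nonbonded pair loop runs
in ascending (i, j) order.  The worker count only controls how the pair
range is chunked into partial sums, which are combined in worker-index
order, so any worker count yields the same result to tight tolerance and
repeated runs are byte-identical.  Reports print energies with six fixed
decimals; JSON/CSV carry the same numbers at full precision.

## Synthetic systems and the oracle

The fixture generator produces five recipes — chain (the canonical
1-2/1-3/1-4 ladder), ring, star, two disconnected molecules, and a seeded
random molecule — fully parameterized from a palette anchored on the
canonical printed records: bonds 340 kcal/mol/Å² at 1.09 Å, angles
50 kcal/mol/rad² at 120.0001°, torsions with a single two-fold
4.75 kcal/mol term at 180° phase, impropers 1.1 kcal/mol with period 2,
and per-type LJ values spread around (R = 1.1 Å, ε = 0.0157 kcal/mol).
Improper records exist only for centres of one atom type so that other
three-coordinated centres exercise the missing-parameter warning path.

The random recipe grows a seeded random tree, placing each atom 1.0–1.6 Å
from its parent inside a 20 Å box with a 0.8 Å minimum pair separation,
and closes rings only between atoms closer than 2 Å.  Bonding atoms at
chemically sensible distances keeps every class total at a magnitude
(≤ ~10⁵ kcal/mol) where the 1e-9 kcal/mol comparison tolerances are
meaningful in double precision.  Positions are quantized to 0.001 Å so
the PDB, inpcrd and in-memory coordinates agree exactly, and the PRMTOP
writer uses wide `3E24.16` float sections so file round trips are
lossless (the reader honours any declared `%FORMAT`, so standard `5E16.8`
files read fine).

What the fixtures do *not* emulate: real force-field diversity (wildcard
types, multi-term torsions beyond one slot per quadruple in the palette,
10-12 hydrogen-bond terms), solvent, periodic boxes, and realistic
conformational ensembles.  Passing tests therefore demonstrate correctness
of the energy algebra, enumeration, classification and partition routing —
not agreement with any production force field on real biomolecules.

`brute_force_energy` is the package's independent oracle: naive scalar
loops, separate geometry formulas (atan2 bend angles, projection-based
dihedrals), networkx shortest paths for pair classification, and exact
`math.fsum` accumulation so the oracle adds no rounding noise of its own.
It shares no evaluation code with the engine; agreement within
1e-9 kcal/mol per term class is asserted across all recipes.

## Acceptance quantities

`scripts/acceptance.py` recomputes, from the canonical records alone:
the magnitude of the minimum of the HP–HP pair potential (numerical
minimization over r ∈ (0, 10] Å with seeded multi-start brackets; the
analytic value is ε_ij, here 0.0157 kcal/mol at r = D_ij = 2.2 Å) and the
bond length minimizing the CT–HC harmonic term (analytically l_0 =
1.0900 Å).  Both use problem size n = 1 (a single pair / bond term).

## Known limitations

- No forces, minimization, Ewald/PME, cutoffs, neighbour lists, implicit
  solvent, or per-atom (as opposed to per-fragment) decomposition.
- NBFIX-like off-diagonal LJ edits in a PRMTOP are not honoured.
- Impropers are only generated for exactly-three-coordinated centres; a
  four-coordinated centre contributes no out-of-plane term.
- Trajectory formats (DCD/NetCDF) are out of scope; multi-frame ASCII
  restart files and multi-model PDBs are supported via a frame index.
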