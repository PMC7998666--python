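# Methods

## Scope and model

`famsec` operates strictly downstream of electronic-structure computation.
Its inputs are the three data products a QTAIM/IQA workflow emits per
stationary point ("snapshot"): net atomic charges Q(A) in e, the unordered
pairwise interaction table (Vcl, VXC) in kcal/mol (or hartree, converted on
input), and thermochemistry (E, E_ZPVE, H, G at one temperature T). The
toolkit never computes wavefunctions, basin integrals, or thermal
corrections, and never locates stationary points; those are assumptions
about the inputs, not steps it performs.

Three modelling conventions fix the arithmetic:

1. **Single counting.** Every unordered atom pair contributes once. A
   fragment-pair energy is the plain sum over crossing pairs with no halving
   and no double counting. This makes two identities exact rather than
   approximate: additivity, E(F1∪F2, F3) = E(F1,F3) + E(F2,F3) for disjoint
   fragments, and completeness, the partitioned interfragment sums plus all
   intra-fragment sums reconstruct the whole-table sum.
2. **Sparse tables are legal.** A pair absent from the table contributes
   exactly 0 and is excluded from the reported pair count; a strict mode
   turns absence into an error for workflows where the table is known to be
   dense.
3. **Sign convention.** Attractive interactions are negative throughout;
   "strongest attractive" means most negative total.

Percent character is 100·Vcl/(Vcl+VXC) and 100·VXC/(Vcl+VXC); it is
undefined (an error, not a NaN) when the total is zero.

## Reaction-energy profiles

A pathway is an ordered sequence of role-annotated steps (reactant set,
adduct, ts, intermediate, product), each carrying a *composition*: the list
of isolated species it contains. The relative value of a step for a term is

    rel(step, term) = value(step, term) − Σ_{s ∈ composition} value(s, term),

with the reference summed in composition order. This referencing makes the
profile continuous across a reagent addition: before water joins the
reference is E(1)+E(2); from the water-adduct step onward it is
E(1)+E(2)+E(H2O), and differences of relative values across the segment
boundary are physically meaningful association energies. Gauge invariance —
shifting a species' absolute energy moves every step of its segment
identically and leaves no observable unchanged quantity altered — holds by
construction and is property-tested.

Temperature is metadata. Records computed at different temperatures cannot
be mixed in one profile (an integrity error naming the offenders); the
bundled case-study fixtures use 195.15 K, the low-temperature condition
under which organolithium chemistry is run.

Barriers are forward differences rel(ts) − rel(predecessor). A negative
barrier is allowed but flagged (it indicates inconsistent inputs), and
barriers below 1.5 kcal/mol (configurable) are flagged "negligible" — the
magnitude class of the hydrolysis-stage humps. Pathway comparison requires
identical role structures, sorts by the first forward barrier, and reports
pathways within 0.1 kcal/mol (configurable) of each other as comparable,
since differences at that scale are below the method's meaningful
resolution.

Step-to-step deltas evaluate one named quantity (intra-fragment covalent
sum, interfragment energy, single pair total, fragment charge) on two
snapshots with consistent atom labeling and subtract. The canonical use is
the covalent integrity of the benzene ring, pyrazine ring and full
quinoxaline moiety between the adduct and transition-state stages.

## Fragments

Fragment specs are comma-separated atom labels and serial ranges. A range
such as `N1-H15` spans *serials* 1–15 regardless of element, because
chemically meaningful fragments (a ring plus its hydrogens) cross element
boundaries; this is the only reading under which the bundled library's
printed sets come out right. Ranges are expanded to explicit label sets at
load time, so downstream energetics never re-parses notation. The pyrazine
fragment `P` is encoded as the literal set {N1,C2,C3,N4,C5,C10,H11}.
Validation offers disjointness and partition checks that return reports
(overlapping pairs, uncovered atoms) rather than raising.

At the transition-state stage of the case study, lithium is mid-transfer
between its acetylide carbon and a ring nitrogen; analyses at that stage
treat Li as a separate entity via a three-block split {molecule 1}, {Li27},
{R = molecule 2 minus Li} rather than assigning it to either molecule. This
is an operational reporting choice, selected per step role.

## Geometry

Distances are Euclidean; torsions use the right-hand (IUPAC) convention
with range (−180°, 180°], computed as atan2 of the standard
normal-vector construction. Under this convention the signed torsion is
invariant under full atom-order reversal and flips sign under mirror
reflection — both are tested, the former cross-checked against an
independent geometry library during development. Three collinear atoms
(cross-product norm < 1e-10 Å²) make the torsion undefined and raise a
degenerate-geometry error.

Van-der-Waals contacts use strict inequality d < r_A + r_B, reporting the
margin (r_A + r_B) − d; a pair exactly at the radii sum is *not* a contact.
The bundled radii are the Bondi (1964) compilation with the conventional
group-1/2 extensions (Li 1.81 Å); the table is an explicit argument so any
other set can be swapped in — contact classifications are therefore tested
as properties, not as literature value matches.

## Synthetic data

The snapshot generator is deliberately schematic, not an IQA emulation. It
draws coordinates uniformly in a box (default 10 Å), charges from a normal
distribution (default σ = 0.3 e) shifted uniformly to hit the target total
charge exactly, and sets

    Vcl(A,B) = k_C · Q(A)·Q(B) / d(A,B),   k_C = 332.0637 kcal·Å/(mol·e²)
    VXC(A,B) = −s · exp(−d/λ),             s = 10 kcal/mol, λ = 2 Å defaults

The defaults give pair energies of the magnitude real tables show for
valence contacts (tens of kcal/mol at bonding distances, decaying with
separation). What the generated tables share with real IQA output — and what
makes them valid test instruments — is structure: exact symmetry,
completeness, charge balance, and the sign law Vcl > 0 ⇔ Q(A)·Q(B) > 0.
What they lack is everything quantum: no shell structure, no exchange
channels beyond a radial decay, no correlation between charge and position.
Passing tests therefore certify the *bookkeeping* (sums, deltas, profiles,
I/O) on arbitrary consistent inputs; they say nothing about the physical
accuracy of any upstream decomposition.

The pathway generator plants known relative energies behind arbitrary
per-species reference constants. Binary floating point cannot round-trip an
arbitrary double through `rel + ref` and back when the sum changes binade,
so the generator commits to planted values quantized to a 2⁻²⁰ kcal/mol
grid (≈ 1e-6, far below any chemically meaningful resolution; requests are
honoured to within half a grid step) and draws integer references in
[−512, 512). Both the addition here and the subtraction in the profile
builder are then exact, and the rebuilt profile reproduces the committed
planted values bit-for-bit — a zero-tolerance recovery property rather than
an approximate one. Planted magnitudes must stay below 1024 kcal/mol for
this guarantee; larger requests are rejected.

All generation is deterministic under a seed (numpy `default_rng`); the
generator algorithm is versioned with the package and changing it is a
breaking change.

## Worked-example fixtures

The fixture bundle embeds the case study's printed observables: the charges
Q(Li27) = +0.9463 e, Q(N1) = −1.1164 e, Q(N4) = −1.1211 e; the Li–C pair
(−90.9, −16.0) kcal/mol; the Li···N4 total −185 kcal/mol at 5 % covalent
character (the component split (−175.75, −9.25) is derived from those two
facts); distances d(Li,C2) = 2.04 Å, d(Li,C28) = 2.06 Å, d(Li,N4) = 2.15 Å;
intermediate stabilities +1.1 / −4.9 kcal/mol; addition barriers 36.8 / 36.7
kcal/mol at C5/C10; the −15 kcal/mol water-adduct formation; ~1 kcal/mol
hydrolysis barriers; and the 24.7 kcal/mol barrier of the alternative
proton-to-C16 path. Where only one number constrains a fixture, the
remaining degrees of freedom are synthetic and marked as such: the 28-atom
adduct structure places only the three lithium-contact atoms meaningfully,
the C3···C28 snapshots carry totals in the classical slot, and the
unreported profile values (adduct depths, C5/C10 intermediates, product
stabilities, the C2/C3 barriers of 18 and 16 kcal/mol) are shaped to the
reported trends (adduct ordering 3b < 3c ≈ 3d < 3a, RP-C3 lowest barrier,
products stabilized, the alternative product most stable). Fixture profile
energies use all four terms with identical planted values per step,
consistent with the reported near-coincidence of the term profiles.

## Numerical choices

- Units pinned: 1 hartree = 627.5094740631 kcal/mol, 1 kcal = 4.184 kJ
  (thermochemical). All internal energies are kcal/mol.
- Pair storage order: lexicographic by (element symbol, serial); ranking
  ties break on that canonical order, making ranked output deterministic.
- Oracle tolerances in tests are 1e-9 kcal/mol for summation identities
  (accumulated rounding over ≤ tens of pairs), exact equality where the
  arithmetic is exact by design (symmetry, antisymmetry, planted recovery).
- Duplicate pair rows with identical values deduplicate silently; with
  different values they are an integrity error, never a silent overwrite.
- Human-readable CLI tables print one decimal in kcal/mol; machine CSV
  output uses `repr` round-tripping so no precision is lost.

## Limitations

- The full FAMSEC term set (self-energy deformation, localized/molecular
  composites) is out of scope; only pairwise-derived quantities are
  computed.
- The simplified `.sum` dialect is a documented two-section subset
  (docs/formats.md), not the vendor format.
- Fragment definitions are manual; there is no automatic ring/substituent
  perception.
- The synthetic generator's physics is schematic by design (see above);
  conclusions about real systems require real IQA input.
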