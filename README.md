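# famsec

Fragment-attributed energy decomposition and reaction-energy profiles for
QTAIM/IQA post-processing.

## What problem this solves

When a reaction can proceed through several competing pathways, computed
energy barriers tell you *which* pathway wins but not *why*. The
REP-FAMSEC style of analysis answers the "why" by attributing the energy of
a molecular system, and its change between consecutive mechanism steps, to
chemically meaningful fragments — a ring, a substituent, a single metal
atom — using the Interacting Quantum Atoms (IQA) decomposition of the
electron density into pairwise interatomic energies.

`famsec` is the post-processing toolkit for that workflow. It consumes what
the quantum-chemistry stack produces — QTAIM net atomic charges Q(A),
pairwise IQA interaction energies, and per-structure thermochemistry — and
computes everything downstream of it. It performs no electronic-structure
computation itself. The bundled case study is the nucleophilic addition of
lithium phenylacetylide to 2-phenylquinoxaline, a system with four candidate
attack sites (C2, C3, C5, C10) and a hydrolysis stage where a water molecule
joins mid-profile.

## The quantities at the core

Every IQA atom pair {A, B} carries a classical (coulombic) component and an
exchange-correlation (covalent) component,

    E_int(A,B) = Vcl(A,B) + VXC(A,B),

and a fragment-pair interaction is the single-counted sum over crossing
pairs,

    E_int(F1,F2) = Σ_{A∈F1} Σ_{B∈F2} [ Vcl(A,B) + VXC(A,B) ],

with the percentage character 100·Vcl/E and 100·VXC/E separating ionic from
covalent contacts. Intra-fragment covalent sums Σ VXC over a ring's internal
pairs probe how intact its bonding framework remains, and their step-to-step
deltas (adduct → transition state) show which ring pays for an attack at a
given site. Reaction-energy profiles (REPs) express each step's E, E_ZPVE,
H and G relative to the summed energies of the isolated species the step
contains, so barriers are simple differences and a reagent joining
mid-profile (water at the hydrolysis stage) just extends the reference.

## Worked example

```python
from famsec import pair_total, percent_character, read_pair_table

table = read_pair_table("A,B,Vcl,VXC\nLi27,C28,-90.9,-16.0\n")
rec = table.get("Li27", "C28")
print(pair_total(rec))          # -106.9
print(percent_character(rec))   # (85.03..., 14.96...)
```

The lithium–acetylide-carbon contact totals −106.9 kcal/mol and is 85 %
classical / 15 % covalent: a strong, predominantly ionic bond. Profiles work
the same way from thermochemistry records:

```python
from famsec import build_profile, worked_example_fixtures

bundle = worked_example_fixtures()
rep = build_profile(bundle["pathways"]["RP-C3"], bundle["thermo"])
print(rep.relative("5b", "E"))   # -4.9  (intermediate below the reactants)
```

Each script in `examples/` exercises one capability end to end and prints
the numbers it computes:

- `pair_decomposition.py` — Vcl/VXC split and percent character of one pair
- `fragment_energetics.py` — interfragment sums, ranking, fragment charges
- `reaction_profile.py` — REP assembly, barriers, pathway comparison
- `geometry_diagnostics.py` — distances, vdW contacts, change reports
- `synthetic_pathway.py` — planted pathways recovered exactly

A `famsec` console command wraps the same library functions
(`famsec decompose|profile|geom|fixtures|report`; see `famsec --help`).

## The fragment library

`quinoxaline_fragment_library()` bundles the sixteen named fragments of the
case-study system (quinoxaline moiety `Q`, phenyl substituents `Ph1`/`Ph2`,
benzene and pyrazine rings `Bn`/`P`, nitrogen and electrophilic-carbon sets
`N`/`C`, the organolithium fragments `L`/`A`/`R`, and the site-environment
fragments `G1`/`G2`, `F1`–`F4`), expanded to explicit atom-label sets over
the 40-atom two-reactant universe (water optional).

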