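# File formats

All native carriers are UTF-8 text, comma-delimited with a required header
row and `.` as the decimal separator. Atom labels are element symbol plus
1-based serial (`Li27`, `C28`), case-sensitive.

## XYZ (standard)

Count line, comment line (becomes the structure label when non-empty), then
one `element x y z` line per atom in Å. Serials are assigned 1..N in file
order on read.

## atoms.csv

```
label,element,Q,E_self
N1,N,-1.1164,
Li27,Li,0.9463,
```

`Q` is the net atomic charge in e; `E_self` (kcal/mol) is optional and may
be empty. Duplicate labels are an integrity error.

## pairs.csv

```
A,B,Vcl,VXC
Li27,C28,-90.9,-16.0
```

One row per unordered pair; `(A,B)` and `(B,A)` are the same pair. A
duplicate listing with identical values is deduplicated; with different
values it is an integrity error. Energies are kcal/mol by default; pass
`units="hartree"` to convert on read.

## thermo.csv

```
label,E,E_ZPVE,H,G,T,units
3b,-458.0,-457.0,-456.5,-456.0,195.15,kcal/mol
```

Empty energy cells mark a term explicitly absent. `T` is in kelvin and
`units` applies to the energy columns of that row.

## Simplified .sum dialect

A two-section plain-text dialect for AIMAll-style per-atom and pairwise
data, with energies in hartree. See `docs/example.sum` for an annotated
example. The atomic section is mandatory, the pairwise section optional:

```
[Atomic Properties]
Atom  q(A)
Li1   0.9000
[IQA Pairwise]
A    B    Vcl        VXC
Li1  C2   -0.144857  -0.025497
```

Columns are whitespace-separated; an optional third column in the atomic
section is the atomic self-energy in hartree. This is a documented subset —
full vendor output is out of scope.

## fragments.yaml

```yaml
universe: quinoxaline+water   # or quinoxaline, from-atoms, or a label list
fragments:
  L: "Li27,C28,C29"
  Q: "N1-H15"
```

Specs are comma-separated labels and serial ranges (`X<i>-Y<j>` spans all
serials i..j regardless of element).

## pathway.yaml

```yaml
thermo: thermo.csv            # path relative to this file
pathways:                     # or a single top-level pathway block
  - pathway: RP-C3
    steps:
      - {label: "3b", role: adduct, composition: ["1", "2"]}
      - {label: "4b", role: ts, composition: ["1", "2"]}
      - {label: "5b", role: intermediate, composition: ["1", "2"]}
```

Roles are `reactant_set`, `adduct`, `ts`, `intermediate`, `product`;
`composition` lists the isolated species whose summed thermochemistry
defines the step's reference zero.
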