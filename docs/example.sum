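# Annotated example of the simplified .sum dialect read by famsec.
# Lines starting with '#' and blank lines are ignored.
#
# The file has two sections introduced by fixed bracketed headers. The
# atomic section is mandatory; the pairwise section may be absent.
# All energies are in hartree and are converted to kcal/mol on input
# (1 hartree = 627.5094740631 kcal/mol).

# --- per-atom properties: label, net atomic charge q(A) in e, and an
#     optional atomic self-energy in hartree as a third column ---
[Atomic Properties]
Atom  q(A)
Li1   0.9000
C2   -0.4500
C3   -0.4500

# --- unordered IQA pairwise interaction energies: the classical
#     (coulombic) component Vcl and the exchange-correlation (covalent)
#     component VXC; each unordered pair appears once ---
[IQA Pairwise]
A    B    Vcl        VXC
Li1  C2   -0.144857  -0.025497
Li1  C3   -0.060000  -0.004000
C2   C3   -0.250000  -0.180000
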