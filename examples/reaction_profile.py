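"""Build and compare reaction-energy profiles for the case-study pathways.

The worked-example fixtures encode the nucleophilic-addition pathways of the
2-phenylquinoxaline + lithium phenylacetylide system (attack at C2, C3, C5,
C10) followed by hydrolysis after a water molecule joins. The profile builder
turns absolute thermochemistry into relative energies versus the isolated
reactants and extracts forward barriers.
"""

from famsec import build_profile, pathway_compare, worked_example_fixtures

bundle = worked_example_fixtures()
reps = {
    name: build_profile(steps, bundle["thermo"])
    for name, steps in bundle["pathways"].items()
    if name in ("RP-C2", "RP-C3", "RP-C5", "RP-C10")
}

print("relative E_ZPVE (kcal/mol) along RP-C3:")
print(reps["RP-C3"].frame[["role", "composition", "E_ZPVE"]].to_string())

print("\nbarrier comparison:")
table = pathway_compare(reps, term="E_ZPVE")
print(table[["pathway", "barrier", "product_rel"]].to_string(index=False))

gap = reps["RP-C2"].relative("5a", "E") - reps["RP-C3"].relative("5b", "E")
print(f"\nintermediate 5a lies {gap:.1f} kcal/mol above 5b:")
print(
    "attack at the ring nitrogens' neighbours C5/C10 faces ~37 kcal/mol\n"
    "barriers, while C2 and C3 are accessible and C3 gives the more stable\n"
    "intermediate — the pathway the experiment observes."
)
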