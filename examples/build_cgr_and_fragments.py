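"""Build a Condensed Graph of Reaction and enumerate its fragments.

A nitrobenzene -> aniline hydrogenation is parsed from an atom-mapped
reaction SMILES; superposing the two sides gives a single pseudomolecule in
which the two N-O bonds appear as broken ("order -> 0") dynamic bonds and
the nitrogen's formal charge change (+1 -> 0) is recorded.  Fragments are
linear atom/bond paths of 2-4 atoms; those crossing a dynamic bond describe
the transformation itself.
"""

from condrank import build_cgr, dynamic_bond_count, enumerate_fragments, parse_reaction_smiles
from condrank.cgr import dump

LINE = (
    "[O:1]=[N+:2]([O-:3])[c:4]1[cH:5][cH:6][cH:7][cH:8][cH:9]1"
    ">[H][H]>[NH2:2][c:4]1[cH:5][cH:6][cH:7][cH:8][cH:9]1"
)

rxn = parse_reaction_smiles(LINE)
cgr = build_cgr(rxn)

print("CGR bonds (atom-atom [order_before>order_after]):")
print(dump(cgr))
print(f"\ndynamic bonds: {dynamic_bond_count(cgr)} "
      "(the two N-O bonds broken by the reduction)")

fragments = enumerate_fragments(cgr)
dynamic = {f: c for f, c in fragments.items() if "[" in f}
print(f"\n{len(fragments)} distinct fragments, {len(dynamic)} involving a "
      "dynamic bond or charge; examples:")
for frag in sorted(dynamic)[:5]:
    print(f"  {frag}  (count {dynamic[frag]})")
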