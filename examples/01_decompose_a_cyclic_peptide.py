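"""Decompose a cyclic peptide into capped residue-level substructures.

Builds cyclo(Ala)6 and a disulfide-bridged hexapeptide, identifies the
macrocycle bonds that can be cut (backbone amides, S-S), and prints the
capped fragments in ring order.
"""

from cyclicppb import decompose, parse_peptide
from cyclicppb.synthetic import generate_peptide

for name, smiles in [
    ("cyclo(Ala)6", generate_peptide(6, alphabet=("A",), seed=0)),
    ("disulfide hexapeptide", generate_peptide(6, seed=1, disulfide=True)),
]:
    peptide = parse_peptide(name, smiles)
    print(f"\n{name}: {smiles}")
    kinds = [b.kind for b in peptide.cleavable_bonds]
    print(f"  {len(kinds)} cleavable bonds on the macrocycle "
          f"({kinds.count('backbone_amide')} amide, {kinds.count('disulfide')} S-S)")
    for sub in decompose(peptide):
        print(f"  position {sub.position}: {sub.capped_smiles}")

# Each fragment is one residue with its cut ends chemically completed:
# methyl on the amide nitrogen, aldehyde at the carbonyl, thiol at sulfur.
# The fragments partition the peptide's heavy atoms, so nothing is lost.
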