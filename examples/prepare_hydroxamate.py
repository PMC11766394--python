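"""Deprotonate the hydroxamic acid group of HDAC inhibitor ligands.

The hydroxamic acid zinc-binding group R-C(=O)-N(H)-OH loses its
hydroxyl proton in the enzyme active site; docking the anionic
hydroxamate form reproduces experimental affinities better than the
neutral form.  This script locates the group and emits the charged
SMILES the docking pipeline consumes.
"""

from zincbias import deprotonate_hydroxamic, find_hydroxamic_groups

ligands = {
    "acetohydroxamic acid": "CC(=O)NO",
    "SAHA skeleton": "ONC(=O)CCCCCCC(=O)Nc1ccccc1",
    "benzohydroxamic acid": "ONC(=O)c1ccccc1",
}

for name, smiles in ligands.items():
    matches = find_hydroxamic_groups(smiles)
    deprot = deprotonate_hydroxamic(smiles)
    print(f"{name}:")
    print(f"  matches (C, N, O indices): {matches}")
    print(f"  {smiles}  ->  {deprot}")

print("\nEach ligand gains one negative charge on the hydroxyl oxygen;")
print("the anilide amide of the SAHA skeleton is correctly left untouched.")
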