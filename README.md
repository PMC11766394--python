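# zincbias

A toolkit for bias-guided molecular docking of zinc metalloproteins,
built around histone deacetylase (HDAC)-style catalytic sites.

Standard docking engines treat the catalytic Zn²⁺ of HDAC enzymes as a
bare divalent cation and miss its coordination chemistry, which is why
hydroxamic acid inhibitors — whose zinc-binding group chelates the
metal — are poorly posed and poorly scored. Bias docking fixes this by
adding attractive potential wells ("bias sites") at the positions the
ligand's zinc-binding atoms should occupy. `zincbias` covers the
desk-side half of that workflow:

- **Zinc-site detection** — parse PDB/PDBQT structures and find each
  Zn²⁺ with its first-shell protein donors (N/O/S within a cutoff,
  default 2.6 Å).
- **Bias prediction** — compute the vacant coordination vertex and
  place mono- or bidentate acceptor bias sites there; write
  bias parameter files (BPF) for a biased AutoDock run.
- **Ligand preparation** — detect hydroxamic acid groups
  (R–C(=O)–N(H)–OH) in SMILES and emit the O-deprotonated hydroxamate
  anion used for docking.
- **Docking-log analysis** — parse clustering histograms from
  AutoDock4-style logs and select the representative binding free
  energy per run.
- **Evaluation** — convert ΔG to K_i and pK_i, regress calculated
  against experimental pK_i, tally pose-rank accuracy, and compute
  masked in-place RMSD for re-docking validation.
- **Synthetic fixtures** — zinc sites and docking logs with known
  ground truth, plus an embedded 26-row experimental/calculated pK_i
  reference table for hydroxamate inhibitors of HDAC2/4/8.

## The model

**Vacant coordination vertex.** Let û₁…ûₙ be unit vectors from the
zinc toward its n protein donors. The vacant direction is

    v = −(û₁ + … + ûₙ) / |û₁ + … + ûₙ|

For two histidines and one aspartate at ideal tetrahedral positions
this completes the tetrahedron exactly: v makes 109.471° with every
occupied direction. Bias sites are placed at distance r (default
2.1 Å) along v — one site (monodentate) or a symmetric pair subtending
a bite angle θ (default 76°, giving O···O ≈ 2.59 Å as in bidentate
hydroxamate chelation).

**Energy to affinity.** A docking score ΔG (kcal/mol) converts to an
inhibition constant and pK_i via

    K_i = exp(ΔG / RT),   pK_i = −log₁₀ K_i [M]

with R = 0.0019872036 kcal/(K·mol) and T = 310 K. The representative
ΔG of a run is the mean binding energy of the most populated cluster;
clusters within 90 % of the top population are averaged unweighted.

## Worked example

```
$ python examples/predict_bias_sites.py
coordinating residues: [('HIS', 100, 'A'), ('HIS', 101, 'A'), ('ASP', 102, 'A')]
Zn-donor distances (A): [2.1, 2.1, 2.1]
vacant axis: [-0.577 -0.577  0.577]  (vs ground truth: 0.00e+00 deg off)

bias parameter file:
#x y z Vset r type
8.517 8.517 9.900 -2.00 0.80 acc
9.572 9.572 12.011 -2.00 0.80 acc
```

The detected shell is 2 His + 1 Asp at 2.1 Å; the vacant axis is the
fourth tetrahedral vertex, and the two emitted bias lines are
acceptor wells (−2.00 kcal/mol, radius 0.8 Å) 2.1 Å from the zinc and
76° apart — where the two hydroxamate oxygens of a chelating inhibitor
belong. The other scripts in `examples/` demonstrate ligand
deprotonation, docking-log analysis, the correlation replay and
masked RMSD, each printing and explaining its numbers.

The same operations are available from the shell:

```
zincbias find-sites site.pdb
zincbias predict-bias site.pdb -o site.bpf
zincbias deprotonate ligands.smi -o ligands_deprot.smi
zincbias analyze-dlg run1.dlg run2.dlg -o energies.tsv
zincbias reproduce
```

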