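# Methods

## Scope

`zincbias` implements the desk-side half of a bias-docking workflow
for zinc metalloproteins: everything up to writing the bias parameter
file consumed by a biased AutoDock run, and everything after the run
produces its log. Running AutoGrid/AutoDock themselves, protein
preparation (protonation, rotamer assignment, minimization) and 3D
conformer generation are external steps and are deliberately out of
scope.

## Zinc-site detection

Structures are read from fixed-column PDB or PDBQT text (ATOM/HETATM
records only; coordinates from columns 31–54, element from columns
77–78 when present, otherwise inferred from the atom name). The
parser is written in-package because PDBQT's trailing charge/type
columns and the line-numbered error contract are not served by the
general-purpose structure readers. Note that in PDBQT files columns
77–78 hold the AutoDock atom type; for the elements relevant here
(C/N/O/S/Zn) the type string coincides with the element symbol, and
exotic types (e.g. aromatic carbon `A`) are outside the supported
donor chemistry.

A zinc site is every atom with element Zn plus all protein atoms with
element in {N, O, S} within a cutoff, default **2.6 Å** — first-shell
Zn–N/O bonds run 1.9–2.3 Å, so 2.6 Å gives margin without reaching
the second shell. Water oxygens are excluded by default. Detection is
purely geometric: the identities of the coordinating residues are
reported but never required to be any particular His/Asp combination,
because crystallographic zinc shells vary and the code should not
arbitrate. Sites with fewer than two donors are returned flagged
(`insufficient_coordination`) rather than dropped.

## Vacant-axis rule

With unit vectors û₁…ûₙ from zinc to donors, the vacant coordination
direction is v = −Σûᵢ/|Σûᵢ|. This is exact for ideal geometry
completion (tetrahedral, trigonal-bipyramidal or octahedral with one
vertex missing) and degrades linearly under coordinate noise. A
resultant of norm ≤ 1e-6 (e.g. a perfectly linear trans pair) leaves
the axis undefined and is a hard error.

**Agreement with a direct search.** An independent criterion for the
vacant direction is the point on the sphere maximizing the minimum
angle to the occupied directions (found by brute force over ~10⁵
near-uniform directions). The two agree exactly at ideal tetrahedral
geometry, but the max-min optimum is the spherical circumcenter of
the donor antipodes and amplifies per-donor perturbations by roughly
1.6×: measured over random near-tetrahedral sets, the divergence
between the rules is ≤ 1.8° when each donor is within ~1° of ideal,
~7° at 5° distortion, and up to ~23° at 15°. The resultant rule is
the normative one; the brute-force search is only a cross-check in
its narrow agreement regime.

## Bias placement

Monodentate mode places one acceptor site at zinc + r·v. Bidentate
mode places two sites at zinc + r·(cos(θ/2)·v ± sin(θ/2)·w), so both
are exactly r from the zinc and subtend the bite angle θ at it.

Defaults, all configurable and recorded in the JSON sidecar:

| parameter | default | rationale |
|---|---|---|
| bond length r | 2.1 Å | center of the typical Zn–O coordination range |
| bite angle θ | 76° | gives O···O ≈ 2.59 Å, typical of bidentate hydroxamate chelation |
| well depth (Vset) | −2.00 kcal/mol | moderate attractive bias; exposed for tuning |
| radius | 0.8 Å | sub-bond-length sphere so the bias is positionally specific |

The in-plane direction w is the unit vector perpendicular to v that
bisects the widest azimuthal gap among the occupied directions
projected onto the plane normal to v — the least sterically hindered
orientation for the second chelating oxygen. Exact gap ties (which
occur at perfectly symmetric geometry) are broken by choosing the
candidate with the lexicographically smallest (x, y, z); this makes
placement deterministic, at the cost of frame dependence in the
measure-zero tied case. BPF output is plain text: one comment header,
then `x y z Vset r type` per site (coordinates to 3 decimals, energy
and radius to 2, type ∈ {acc, don, map}).

## Hydroxamate preparation

Hydroxamic acid groups are matched with the SMARTS pattern
`[CX3](=[OX1])[NX3;H1][OX2H1]` (carbonyl carbon bonded to an N–H
bearing an O–H). Deprotonation removes the hydroxyl proton and sets
the oxygen's formal charge to −1 — the O-dissociated tautomer, not
the N–H one — for every match, returning canonical SMILES. Heavy-atom
count is conserved; the net charge drops by the number of matches;
applying the operation twice is an error because the anion no longer
matches the protonated pattern.

## Docking-log analysis

The clustering-histogram parser accepts both minimal fixtures and
real AutoDock4 logs: it seeks the `CLUSTERING HISTOGRAM` header, skips
intervening column-header/separator lines, then reads pipe-separated
rows (rank | lowest ΔG | run | mean ΔG | population). A pipe row that
starts numerically but fails to parse before any valid row is an
error with its line number; after at least one valid row, the first
non-conforming line ends the section.

The representative ΔG of a run is the mean binding energy of the most
populated cluster. "Similarly populated" clusters — population ≥ 90 %
of the largest, the `similar_frac` parameter — are averaged
unweighted. An exact-tie-only rule would almost never trigger the
averaging branch on real histograms, which is why the threshold is a
fraction.

## Thermodynamics and correlation

K_i = exp(ΔG/RT) with R = 0.0019872036 kcal/(K·mol), T = 310 K,
yields K_i in molar units when ΔG is in kcal/mol; the nanomolar form
is a ×10⁹ reporting conversion. pK_i is the negative decimal log of
the molar K_i. These conventions make the embedded table's
experimental K_i and pK_i columns mutually consistent at 2 decimals
for all 26 rows.

Correlations are ordinary least squares of calculated on experimental
pK_i (scipy), with R² the squared Pearson correlation — identical to
the OLS coefficient of determination for a simple linear fit — and
are reported rounded to 2 decimals. Series averages are arithmetic
means of the rounded per-isoform R².

Pose accuracy is the percentage of runs in which the correctly
zinc-coordinated pose ranks first; the improvement statistic is the
relative gain, 100·(a−b)/b. The embedded rank tallies (25/26 rank-1
for the deprotonated series, 20/26 for the protonated) come from the
published totals; regenerating them requires actual docking runs.

## RMSD

Re-docking RMSD is computed in place — poses and reference share the
receptor frame, so no superposition — over heavy atoms paired
one-to-one by atom name, after removing any atoms whose name or
serial is in the user-supplied exclusion mask (for ligand portions
outside the binding site). Unpaired atoms are a hard error listing
the orphans, rather than a silent intersection; symmetry-equivalent
atom permutations are not considered. A Kabsch-superposed variant
exists behind a flag for conformer comparison but is not the
re-docking convention.

## Synthetic data

`make_zinc_site` emits a zinc at a fixed origin plus donors at the
ideal vertices of the chosen geometry (tetrahedral default:
NE2/HIS ×2 + OD1/ASP, the canonical HDAC-style shell), each direction
independently perturbed by a random rotation with angle ~ N(0, σ)
about a uniformly random axis, where σ is the `angular_jitter`
parameter in degrees. Each residue also gets a non-coordinating
carbon so detection must genuinely filter by element and distance.
The manifest records the jitter-free vacant axis; under σ = 5° the
detected axis deviates from it by ≈ 4.3° on average (the resultant
partially averages out per-donor noise). The generator emulates
coordination geometry only — no side-chain context, occupancy,
B-factors or crystallographic error model — so passing tests
demonstrate geometric correctness of the pipeline, not robustness to
real crystallographic artifacts.

`make_dlg` wraps stated (mean ΔG, lowest ΔG, population) rows in a
realistic log skeleton, deterministically for a fixed seed. The
embedded reference table ships as TSV package data so the correlation
replay runs offline and bit-identically.

## Numerical choices and limitations

- Unit-vector norms and bias distances are exact to 1e-9; rigid-
  motion equivariance of placements holds to 1e-6 Å (generic
  geometry; see the tie-break note above).
- Degenerate inputs fail loudly: zero resultant, < 2 donors,
  non-positive K_i, empty cluster lists, constant-x regressions.
- Coordinates are written at PDB precision (3 decimals), which bounds
  fixture round-trip fidelity at ~5×10⁻⁴ Å.
- The toolkit predicts where zinc-coordinating bias sites belong; it
  does not modify grid maps, score poses, or validate that a docking
  engine honors the bias — those remain properties of the external
  docking run.
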