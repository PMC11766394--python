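"""Hydroxamic acid detection and O-deprotonation of SMILES ligands.

Hydroxamic acid, R–C(=O)–N(H)–OH, is the canonical zinc-binding group
of HDAC inhibitors.  In the enzyme active site the hydroxyl oxygen is
deprotonated, turning the group into a bidentate hydroxamate chelator;
this module produces that N–O⁻ form (the N–H tautomer is deliberately
not touched).  Conformer generation and file-format conversion for
docking are downstream of this module and out of its scope.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .errors import ChemistryError

__all__ = [
    "ProtonationState",
    "find_hydroxamic_groups",
    "deprotonate_hydroxamic",
    "read_smi",
    "write_smi",
]

# carbonyl carbon — N(H) — O(H); indices map to (C, N, O_hydroxyl)
HYDROXAMIC_SMARTS = "[CX3](=[OX1])[NX3;H1][OX2H1]"
_PATTERN = Chem.MolFromSmarts(HYDROXAMIC_SMARTS)


@dataclass(frozen=True)
class ProtonationState:
    """Label plus net formal-charge change relative to the neutral form."""

    label: str  # "protonated" | "deprotonated"
    formal_charge_delta: int

    def __post_init__(self) -> None:
        if self.label not in ("protonated", "deprotonated"):
            raise ValueError(f"unknown protonation label {self.label!r}")
        if self.label == "protonated" and self.formal_charge_delta != 0:
            raise ValueError("protonated form must have zero charge delta")
        if self.label == "deprotonated" and self.formal_charge_delta >= 0:
            raise ValueError("deprotonated form must lower the net charge")


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemistryError(f"unparseable SMILES: {smiles!r}")
    return mol


def find_hydroxamic_groups(smiles: str) -> list[tuple[int, int, int]]:
    """Locate hydroxamic acid groups in a molecule.

    Returns one (carbonyl C, amide N, hydroxyl O) atom-index triple per
    match.  N-substituted amides (no N–H) and already-deprotonated
    N–O⁻ groups do not match.
    """
    mol = _parse(smiles)
    # SMARTS atom order: C, carbonyl O, N, hydroxyl O
    return [(m[0], m[2], m[3]) for m in mol.GetSubstructMatches(_PATTERN)]


def deprotonate_hydroxamic(smiles: str) -> str:
    """Remove the hydroxamic O–H proton from every matching group.

    Each hydroxyl oxygen loses one hydrogen and gains formal charge −1;
    no other atom changes.  Returns the canonical SMILES of the
    resulting hydroxamate anion.  Raises :class:`ChemistryError` when
    the molecule has no (remaining) protonated hydroxamic group, which
    also makes the operation a safe idempotence guard.
    """
    mol = _parse(smiles)
    matches = mol.GetSubstructMatches(_PATTERN)
    if not matches:
        raise ChemistryError("no hydroxamic acid group found")
    rw = Chem.RWMol(mol)
    for match in matches:
        oxygen = rw.GetAtomWithIdx(match[3])
        oxygen.SetNumExplicitHs(0)
        oxygen.SetNoImplicit(True)
        oxygen.SetFormalCharge(-1)
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def read_smi(text: str) -> list[tuple[str, str]]:
    """Read .smi text: one 'SMILES [name]' per line; '#' comments allowed."""
    records = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else ""
        records.append((smiles, name))
    return records


def write_smi(records: list[tuple[str, str]]) -> str:
    """Serialize (smiles, name) pairs back to .smi text."""
    lines = [f"{smi}\t{name}".rstrip() for smi, name in records]
    return "\n".join(lines) + "\n" if lines else ""
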