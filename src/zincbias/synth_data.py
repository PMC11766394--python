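"""Synthetic zinc sites, synthetic docking logs, and the reference table.

Fixtures with known ground truth: :func:`make_zinc_site` emits a PDB
text of a zinc ion plus donor atoms at ideal coordination vertices
(optionally angularly jittered) together with a manifest recording the
true vacant axis, so bias prediction can be validated end to end.
:func:`make_dlg` emits a parseable clustering-histogram log from a
stated cluster list.  :func:`load_reference_table` exposes the
embedded 26-row experimental/calculated pKi table for HDAC2/4/8
hydroxamate inhibitors.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ZincbiasError

__all__ = [
    "LigandRecord",
    "SiteSpec",
    "make_zinc_site",
    "make_dlg",
    "load_reference_table",
    "reference_dataframe",
]

_SQ3 = 1.0 / math.sqrt(3.0)

#: ideal unit directions per coordination geometry, in a fixed vertex order.
#: A site with n_ligands donors occupies the first n vertices; the
#: manifest's vacant axis is the negative normalized resultant of those.
GEOMETRIES: dict[str, np.ndarray] = {
    "tetrahedral": np.array(
        [[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]], dtype=float
    ) * _SQ3,
    "trigonal_bipyramidal": np.array(
        [
            [1.0, 0.0, 0.0],
            [-0.5, math.sqrt(3) / 2, 0.0],
            [-0.5, -math.sqrt(3) / 2, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, 0.0, -1.0],
        ]
    ),
    "octahedral_vacant": np.array(
        [
            [1.0, 0.0, 0.0],
            [-1.0, 0.0, 0.0],
            [0.0, 1.0, 0.0],
            [0.0, -1.0, 0.0],
            [0.0, 0.0, 1.0],
            [0.0, 0.0, -1.0],
        ]
    ),
}

# donor atoms assigned to successive vertices; the 3-ligand tetrahedral
# default reproduces the canonical HDAC-style 2 His + 1 Asp shell
_DONOR_CYCLE = [
    ("NE2", "HIS", "N"),
    ("NE2", "HIS", "N"),
    ("OD1", "ASP", "O"),
    ("OD2", "ASP", "O"),
    ("OE1", "GLU", "O"),
    ("SG", "CYS", "S"),
]


@dataclass(frozen=True)
class LigandRecord:
    """One reference-table row: identity, experimental affinity, and the
    docking-calculated pKi for each protonation series."""

    isoform: str
    name: str
    ki_nM: float
    pki_exp: float
    pki_dps: float  # deprotonated (hydroxamate) series
    pki_ps: float  # protonated (hydroxamic acid) series


@dataclass(frozen=True)
class SiteSpec:
    """Parameters of a synthetic zinc coordination site."""

    n_ligands: int = 3
    bond_length: float = 2.1
    geometry: str = "tetrahedral"
    angular_jitter: float = 0.0  # sd of per-donor angular noise, degrees
    seed: int = 0

    def __post_init__(self) -> None:
        if self.geometry not in GEOMETRIES:
            raise ZincbiasError(f"unknown geometry {self.geometry!r}")
        nmax = len(GEOMETRIES[self.geometry])
        if not 2 <= self.n_ligands <= min(5, nmax):
            raise ZincbiasError(
                f"n_ligands must be in [2, {min(5, nmax)}] for {self.geometry}"
            )
        if self.angular_jitter < 0:
            raise ZincbiasError("angular_jitter must be non-negative")


def _jitter_direction(d: np.ndarray, sigma_rad: float, rng: np.random.Generator) -> np.ndarray:
    """Apply a small random rotation (angle ~ N(0, sigma), uniformly random
    axis) to unit vector d — the standard model of isotropic angular noise."""
    if sigma_rad == 0.0:
        return d
    angle = rng.normal(0.0, sigma_rad)
    axis = rng.normal(size=3)
    n = np.linalg.norm(axis)
    if n < 1e-12:
        axis, n = np.array([0.0, 0.0, 1.0]), 1.0
    axis /= n
    rotated = (
        d * math.cos(angle)
        + np.cross(axis, d) * math.sin(angle)
        + axis * np.dot(axis, d) * (1.0 - math.cos(angle))
    )
    return rotated / np.linalg.norm(rotated)


def make_zinc_site(spec: SiteSpec = SiteSpec()) -> tuple[str, dict]:
    """Generate PDB text of a synthetic zinc site plus its manifest.

    The zinc sits at (10, 10, 10); donor atoms sit at ``bond_length``
    along the first ``n_ligands`` ideal vertices of the chosen
    geometry, each direction independently perturbed by a random
    rotation with angular sd ``angular_jitter``.
    Each donor residue also gets a non-coordinating CB carbon further
    out, so detection must genuinely filter by element and distance.

    The manifest records the jitter-free ground truth: the vacant axis
    (negative normalized resultant of the ideal occupied directions),
    the zinc position, and the atom count.  Output is deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    ideal = GEOMETRIES[spec.geometry][: spec.n_ligands]
    resultant = ideal.sum(axis=0)
    norm = np.linalg.norm(resultant)
    true_axis = (-resultant / norm) if norm > 1e-9 else None

    origin = np.array([10.0, 10.0, 10.0])
    jitter_rad = math.radians(spec.angular_jitter)

    lines = []
    serial = 1
    lines.append(
        f"HETATM{serial:5d} ZN   ZN  A 200    "
        f"{origin[0]:8.3f}{origin[1]:8.3f}{origin[2]:8.3f}  1.00  0.00          ZN"
    )
    serial += 1
    n_atoms = 1
    for i, d in enumerate(ideal):
        name, resname, element = _DONOR_CYCLE[i % len(_DONOR_CYCLE)]
        dj = _jitter_direction(d, jitter_rad, rng)
        pos = origin + spec.bond_length * dj
        resid = 100 + i
        lines.append(
            f"ATOM  {serial:5d}  {name:<3s} {resname} A{resid:4d}    "
            f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00           {element}"
        )
        serial += 1
        cb = origin + 4.5 * dj
        lines.append(
            f"ATOM  {serial:5d}  CB  {resname} A{resid:4d}    "
            f"{cb[0]:8.3f}{cb[1]:8.3f}{cb[2]:8.3f}  1.00  0.00           C"
        )
        serial += 1
        n_atoms += 2
    lines.append("END")

    manifest = {
        "atom_count": n_atoms,
        "zinc_xyz": origin.tolist(),
        "vacant_axis": None if true_axis is None else true_axis.tolist(),
        "geometry": spec.geometry,
        "n_ligands": spec.n_ligands,
        "bond_length": spec.bond_length,
        "angular_jitter_deg": spec.angular_jitter,
        "seed": spec.seed,
    }
    return "\n".join(lines) + "\n", manifest


def make_dlg(
    clusters: list[tuple[float, float, int]], seed: int = 0, ligand_name: str = "LIG"
) -> str:
    """Emit DLG-dialect text with the given (mean_dg, lowest_dg, size) rows.

    Ranks follow input order; run ids are drawn deterministically from
    ``seed``.  The output carries realistic header/separator lines so
    it exercises the same parsing path as a real AutoDock4 log.
    """
    if not clusters:
        raise ZincbiasError("at least one cluster is required")
    for mean_dg, lowest_dg, size in clusters:
        if size < 1:
            raise ZincbiasError("cluster size must be >= 1")
        if lowest_dg > mean_dg:
            raise ZincbiasError("cluster lowest energy cannot exceed its mean")
    rng = np.random.default_rng(seed)
    total = sum(int(c[2]) for c in clusters)

    out = [
        f"Docking log for ligand {ligand_name} ({total} runs)",
        "",
        "\tCLUSTERING HISTOGRAM",
        "\t____________________",
        "",
        "________________________________________________________________________________",
        "     |           |     |           |     |",
        "Clus | Lowest    | Run | Mean      | Num | Histogram",
        "-ter | Binding   |     | Binding   | in  |",
        "Rank | Energy    |     | Energy    | Clus|    5    10   15   20   25   30   35",
        "_____|___________|_____|___________|_____|____:____|____:____|____:____|____:___",
    ]
    for rank, (mean_dg, lowest_dg, size) in enumerate(clusters, start=1):
        run_id = int(rng.integers(1, max(2, total + 1)))
        bar = "#" * min(int(size), 40)
        out.append(
            f"{rank:4d} |{lowest_dg:10.2f} |{run_id:4d} |{mean_dg:10.2f} |{int(size):4d} |{bar}"
        )
    out.append("_____|___________|_____|___________|_____|______________________________________")
    out.append("")
    return "\n".join(out) + "\n"


def reference_dataframe() -> pd.DataFrame:
    """The embedded reference table as a pandas DataFrame."""
    ref = importlib.resources.files("zincbias.data") / "hdac_reference_pki.tsv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


def load_reference_table() -> list[LigandRecord]:
    """All 26 embedded rows (10 HDAC2 + 6 HDAC4 + 10 HDAC8)."""
    df = reference_dataframe()
    return [
        LigandRecord(
            isoform=r.isoform,
            name=r.name,
            ki_nM=float(r.ki_nM),
            pki_exp=float(r.pki_exp),
            pki_dps=float(r.pki_dps),
            pki_ps=float(r.pki_ps),
        )
        for r in df.itertuples(index=False)
    ]
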