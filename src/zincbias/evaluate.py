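"""Thermodynamic conversions, correlation statistics and pose metrics.

Docking scores (binding free energies, kcal/mol) convert to inhibition
constants via Ki = exp(ΔG / RT) and onward to pKi = −log10(Ki in M).
Calculated pKi series are compared with experimental ones by ordinary
least squares, summarized by R² (the squared Pearson correlation).
Pose quality is measured by rank tallies (how often the correctly
zinc-coordinated pose ranks first) and by in-place RMSD — no
superposition, since docked poses and the crystal reference share the
receptor frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ZincbiasError
from .struct_io import Atom3D

__all__ = [
    "ThermoConstants",
    "RegressionResult",
    "PoseRankTally",
    "dg_to_ki",
    "ki_to_pki",
    "dg_to_pki",
    "regress",
    "average_r2",
    "pose_accuracy",
    "relative_improvement",
    "masked_rmsd",
]

#: gas constant in kcal/(K·mol)
GAS_CONSTANT_KCAL = 0.0019872036
#: physiological temperature used for all conversions, K
DEFAULT_TEMPERATURE = 310.0


@dataclass(frozen=True)
class ThermoConstants:
    R: float = GAS_CONSTANT_KCAL
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be positive")

    @property
    def rt(self) -> float:
        return self.R * self.T


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    n: int


@dataclass
class PoseRankTally:
    """Counts of the rank position (1..4 or "absent") of the correctly
    zinc-coordinated pose, over a set of docking runs."""

    counts: dict[int | str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def dg_to_ki(dg: float, c: ThermoConstants = ThermoConstants()) -> float:
    """Inhibition constant in molar units: Ki = exp(ΔG / RT)."""
    if not math.isfinite(dg):
        raise ZincbiasError("binding free energy must be finite")
    return math.exp(dg / c.rt)


def ki_to_pki(ki_nM: float) -> float:
    """pKi = −log10 of the molar Ki, given Ki in nanomolar."""
    if not ki_nM > 0:
        raise ZincbiasError("Ki must be positive")
    return -math.log10(ki_nM * 1e-9)


def dg_to_pki(dg: float, c: ThermoConstants = ThermoConstants()) -> float:
    """Calculated pKi from a binding free energy in kcal/mol."""
    return -math.log10(dg_to_ki(dg, c))


def regress(x, y) -> RegressionResult:
    """Ordinary least squares of calculated (y) on experimental (x) pKi.

    R² is the squared Pearson correlation, identical to the OLS
    coefficient of determination for a simple linear fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ZincbiasError("x and y must have the same length")
    if x.size < 3:
        raise ZincbiasError("regression requires n >= 3 points")
    if np.ptp(x) == 0:
        raise ZincbiasError("x has zero variance; regression undefined")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r2=float(fit.rvalue) ** 2,
        n=int(x.size),
    )


def average_r2(values) -> float:
    """Arithmetic mean of a list of R² values."""
    values = list(values)
    if not values:
        raise ZincbiasError("no R² values to average")
    return float(np.mean(values))


def pose_accuracy(t: PoseRankTally) -> float:
    """Percent of runs whose correct pose ranked first: 100·n₁/total."""
    if t.total < 1:
        raise ZincbiasError("empty pose tally")
    return 100.0 * t.counts.get(1, 0) / t.total


def relative_improvement(a: float, b: float) -> float:
    """Relative gain of accuracy a over baseline b, in percent of b."""
    if b <= 0:
        raise ZincbiasError("baseline must be positive")
    return 100.0 * (a - b) / b


def _index_by_name(atoms: list[Atom3D], exclude: set) -> dict[str, list[Atom3D]]:
    """Group heavy atoms by atom name, dropping excluded names/serials."""
    groups: dict[str, list[Atom3D]] = {}
    for a in atoms:
        if a.element.upper() == "H":
            continue
        if a.name in exclude or a.serial in exclude:
            continue
        groups.setdefault(a.name, []).append(a)
    return groups


def masked_rmsd(
    ref: list[Atom3D],
    pose: list[Atom3D],
    exclude: set | None = None,
    superpose: bool = False,
) -> float:
    """In-place RMSD between two conformations of the same ligand.

    Heavy atoms are paired one-to-one by atom name after removing any
    whose name or serial is in ``exclude`` (the mask for ligand parts
    outside the binding site).  By default there is no superposition —
    the docking convention when poses share the receptor frame; pass
    ``superpose=True`` for a Kabsch-fitted RMSD instead.
    """
    exclude = exclude or set()
    ga = _index_by_name(ref, exclude)
    gb = _index_by_name(pose, exclude)

    orphans = sorted(set(ga) ^ set(gb))
    mism = [n for n in set(ga) & set(gb) if len(ga[n]) != len(gb[n])]
    if orphans or mism:
        raise ZincbiasError(
            "unmatched atoms after exclusion: " + ", ".join(orphans + sorted(mism))
        )
    if not ga:
        raise ZincbiasError("no atom pairs left after exclusion")

    pa, pb = [], []
    for name in ga:
        for a, b in zip(ga[name], gb[name]):
            pa.append(a.xyz)
            pb.append(b.xyz)
    pa = np.array(pa)
    pb = np.array(pb)

    if superpose:
        ca, cb = pa.mean(axis=0), pb.mean(axis=0)
        pa = pa - ca
        pb = pb - cb
        # Kabsch alignment of pose onto reference
        h = pb.T @ pa
        u, _, vt = np.linalg.svd(h)
        d = np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        pb = pb @ rot

    return float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1))))
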