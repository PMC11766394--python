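"""Docking-log clustering histograms and representative-energy selection.

AutoDock4 logs (.dlg) tabulate pose clusters in a CLUSTERING HISTOGRAM
section: rank, lowest binding energy, run, mean binding energy, and
cluster population.  The representative binding free energy of a run
is the mean binding energy of the most populated cluster; when several
clusters have similar populations (within a configurable fraction of
the largest), their mean energies are averaged unweighted.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import ParseError, ZincbiasError

__all__ = ["ClusterRecord", "DockingResult", "parse_dlg", "representative_dg"]

#: clusters whose population is at least this fraction of the largest
#: cluster's population count as "similarly populated" and are averaged.
DEFAULT_SIMILAR_FRAC = 0.9

_NUMERIC_START = re.compile(r"^[+-]?[\d.]")


@dataclass(frozen=True)
class ClusterRecord:
    """One clustering-histogram row."""

    rank: int
    lowest_dg: float  # kcal/mol, best energy in the cluster
    run_id: int
    mean_dg: float  # kcal/mol, cluster mean binding energy
    size: int  # number of poses in the cluster

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("cluster size must be >= 1")
        if self.mean_dg < self.lowest_dg - 1e-9:
            raise ValueError("cluster mean cannot be below cluster minimum")


@dataclass
class DockingResult:
    """Clusters of one ligand's docking run plus its selected energy."""

    ligand_name: str
    clusters: list[ClusterRecord] = field(default_factory=list)
    representative_dg: float | None = None


def _try_row(line: str) -> ClusterRecord | None:
    """Parse a pipe-separated histogram data row, or None if wrong shape."""
    fields = [f.strip() for f in line.split("|")]
    if len(fields) < 5:
        return None
    try:
        return ClusterRecord(
            rank=int(fields[0]),
            lowest_dg=float(fields[1]),
            run_id=int(fields[2]),
            mean_dg=float(fields[3]),
            size=int(fields[4]),
        )
    except ValueError:
        return None


def parse_dlg(text: str) -> list[ClusterRecord]:
    """Extract the clustering histogram rows from DLG text.

    Everything before the line containing "CLUSTERING HISTOGRAM" is
    ignored.  Column-header and separator lines between the section
    header and the first data row are skipped; a pipe row that starts
    numerically but fails to parse before any valid row is a hard
    error with its line number.  After at least one data row, the
    first non-conforming row terminates the section (real logs follow
    the histogram with a separator and an RMSD table).
    """
    lines = text.splitlines()
    start = None
    for i, line in enumerate(lines):
        if "CLUSTERING HISTOGRAM" in line:
            start = i + 1
            break
    if start is None:
        raise ParseError("no clustering histogram")

    records: list[ClusterRecord] = []
    for lineno, raw in enumerate(lines[start:], start=start + 1):
        rec = _try_row(raw)
        if rec is not None:
            records.append(rec)
            continue
        if records:
            break  # end of section
        stripped = raw.strip()
        if "|" in raw and _NUMERIC_START.match(stripped):
            raise ParseError(f"line {lineno}: malformed clustering histogram row")
        # header / separator / blank before the data: skip
    if not records:
        raise ParseError("clustering histogram contains no data rows")
    return records


def representative_dg(
    clusters: list[ClusterRecord], similar_frac: float = DEFAULT_SIMILAR_FRAC
) -> float:
    """Representative binding free energy (kcal/mol) of one docking run.

    Let S be the largest cluster population.  All clusters with
    population >= similar_frac * S form the "similar set"; the result
    is the unweighted mean of their mean binding energies.  With one
    dominant cluster this reduces to that cluster's mean energy.
    """
    if not clusters:
        raise ZincbiasError("no clusters: cannot select a representative energy")
    if not 0.0 < similar_frac <= 1.0:
        raise ValueError("similar_frac must lie in (0, 1]")
    top = max(c.size for c in clusters)
    similar = [c.mean_dg for c in clusters if c.size >= similar_frac * top]
    return sum(similar) / len(similar)
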