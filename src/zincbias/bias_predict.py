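"""Vacant-coordination-axis prediction and bias-site placement.

A zinc first shell occupies some vertices of an (approximately)
tetrahedral polyhedron; the ligand zinc-binding group must occupy the
remaining vertex.  The vacant axis is computed as the negative
normalized resultant of the unit vectors from the zinc toward each
donor atom — a rule that completes an ideal tetrahedron exactly and
degrades gracefully under coordinate noise.  Bias sites (attractive
potential wells for the docking engine) are placed along that axis,
either as one monodentate point or as a bidentate pair subtending a
configurable bite angle, and written to a bias parameter file (BPF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import GeometryError, ParseError
from .struct_io import ZnSite

__all__ = [
    "CoordinationModel",
    "BiasSite",
    "coordination_model",
    "vacant_axis",
    "place_bias_sites",
    "write_bpf",
    "read_bpf",
]

#: default Zn–O bias distance in Å (center of the typical Zn–O range).
DEFAULT_BOND_LENGTH = 2.1
#: default O–Zn–O bite angle in degrees for bidentate hydroxamate
#: chelation, giving an O···O separation of ~2.59 Å.
DEFAULT_BITE_ANGLE = 76.0
#: default bias well depth (kcal/mol, negative = attractive) and radius (Å).
DEFAULT_ENERGY = -2.00
DEFAULT_RADIUS = 0.8

_KIND_TOKENS = {"acceptor": "acc", "donor": "don", "map": "map"}
_TOKEN_KINDS = {v: k for k, v in _KIND_TOKENS.items()}


@dataclass(frozen=True)
class CoordinationModel:
    """Unit directions from a zinc toward each donor, plus their sum."""

    origin: np.ndarray
    unit_dirs: np.ndarray  # (n, 3), rows of norm 1
    resultant: np.ndarray  # (3,), sum of rows


@dataclass(frozen=True)
class BiasSite:
    """One bias point: position, well depth, radius and interaction kind."""

    xyz: np.ndarray
    energy: float
    radius: float
    kind: str = "acceptor"

    def __post_init__(self) -> None:
        if self.kind not in _KIND_TOKENS:
            raise ValueError(f"unknown bias kind {self.kind!r}")
        if not self.radius > 0:
            raise ValueError("radius must be positive")
        object.__setattr__(self, "xyz", np.asarray(self.xyz, dtype=float))


def coordination_model(site: ZnSite) -> CoordinationModel:
    """Build the unit-vector model of a site's occupied coordination.

    Requires at least two ligating atoms; under-coordinated sites carry
    too little geometric information to define a vacant direction.
    """
    if len(site.ligating_atoms) < 2:
        raise GeometryError("insufficient coordination sphere")
    origin = np.asarray(site.zinc.xyz, dtype=float)
    dirs = np.array([a.xyz - origin for a in site.ligating_atoms], dtype=float)
    norms = np.linalg.norm(dirs, axis=1)
    if np.any(norms == 0):
        raise GeometryError("ligating atom coincides with zinc")
    dirs = dirs / norms[:, None]
    return CoordinationModel(origin=origin, unit_dirs=dirs, resultant=dirs.sum(axis=0))


def vacant_axis(m: CoordinationModel, eps: float = 1e-6) -> np.ndarray:
    """Unit vector pointing into the vacant coordination vertex.

    Returns -resultant/|resultant|.  A (near-)zero resultant — e.g. a
    perfectly linear trans pair — leaves the vacant direction undefined.
    """
    norm = float(np.linalg.norm(m.resultant))
    if norm <= eps:
        raise GeometryError("degenerate coordination; vacant axis undefined")
    return -m.resultant / norm


def _gap_bisector(m: CoordinationModel, v: np.ndarray) -> np.ndarray:
    """Unit vector perpendicular to ``v`` bisecting the widest azimuthal
    gap among occupied directions projected onto the plane normal to v.

    Ties between equally wide gaps resolve to the candidate with the
    lexicographically smallest (x, y, z).  If every occupied direction
    is parallel to v (no usable projection) the same lexicographic rule
    picks among an axis-aligned candidate set.
    """
    # orthonormal basis (e1, e2) of the plane perpendicular to v
    seed = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(seed, v)) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    e1 = seed - np.dot(seed, v) * v
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(v, e1)

    proj = m.unit_dirs - np.outer(m.unit_dirs @ v, v)
    norms = np.linalg.norm(proj, axis=1)
    usable = norms > 1e-9
    if not np.any(usable):
        candidates = [e1, -e1, e2, -e2]
        return min(candidates, key=lambda c: tuple(np.round(c, 12)))

    ang = np.arctan2(proj[usable] @ e2, proj[usable] @ e1)
    ang = np.sort(ang)
    # circular gaps between consecutive azimuths
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * math.pi]]))
    best = np.max(gaps)
    mids = []
    for i, g in enumerate(gaps):
        if g >= best - 1e-12:
            mid = ang[i] + g / 2.0
            mids.append(math.cos(mid) * e1 + math.sin(mid) * e2)
    return min(mids, key=lambda c: tuple(np.round(c, 12)))


def place_bias_sites(
    site: ZnSite,
    mode: str = "bidentate",
    bond_length: float = DEFAULT_BOND_LENGTH,
    bite_angle: float = DEFAULT_BITE_ANGLE,
    energy: float = DEFAULT_ENERGY,
    radius: float = DEFAULT_RADIUS,
) -> list[BiasSite]:
    """Place acceptor bias sites for the ligand zinc-binding group.

    ``monodentate`` puts one site at ``zinc + bond_length * v`` where v
    is the vacant axis.  ``bidentate`` puts two sites at
    ``zinc + bond_length * (cos(a/2) v ± sin(a/2) w)`` with a the bite
    angle and w the in-plane gap bisector, so both sites sit exactly
    ``bond_length`` from the zinc and subtend the bite angle at it.
    """
    if mode not in ("monodentate", "bidentate"):
        raise GeometryError(f"unknown placement mode {mode!r}")
    if not 0.0 < bite_angle < 180.0:
        raise GeometryError("bite_angle must lie in (0, 180) degrees")
    if bond_length <= 0:
        raise GeometryError("bond_length must be positive")

    m = coordination_model(site)
    v = vacant_axis(m)
    origin = m.origin

    if mode == "monodentate":
        return [BiasSite(xyz=origin + bond_length * v, energy=energy, radius=radius)]

    w = _gap_bisector(m, v)
    half = math.radians(bite_angle) / 2.0
    sites = []
    for sign in (+1.0, -1.0):
        d = math.cos(half) * v + sign * math.sin(half) * w
        sites.append(BiasSite(xyz=origin + bond_length * d, energy=energy, radius=radius))
    return sites


def write_bpf(sites: Iterable[BiasSite]) -> str:
    """Serialize bias sites to BPF text.

    One header comment then one whitespace-separated line per site:
    x y z to 3 decimals, energy and radius to 2, kind as acc/don/map.
    Output order equals input order.
    """
    lines = ["#x y z Vset r type"]
    for s in sites:
        if not np.all(np.isfinite(s.xyz)):
            raise ValueError("non-finite bias coordinate")
        x, y, z = s.xyz
        lines.append(
            f"{x:.3f} {y:.3f} {z:.3f} {s.energy:.2f} {s.radius:.2f} {_KIND_TOKENS[s.kind]}"
        )
    return "\n".join(lines) + "\n"


def read_bpf(text: str) -> list[BiasSite]:
    """Parse BPF text; inverse of :func:`write_bpf` on its own output."""
    sites = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 6:
            raise ParseError(f"line {lineno}: expected 6 fields, got {len(fields)}")
        try:
            x, y, z, e, r = (float(f) for f in fields[:5])
        except ValueError as exc:
            raise ParseError(f"line {lineno}: unparseable numeric field") from exc
        kind = _TOKEN_KINDS.get(fields[5])
        if kind is None:
            raise ParseError(f"line {lineno}: unknown bias type token {fields[5]!r}")
        sites.append(BiasSite(xyz=np.array([x, y, z]), energy=e, radius=r, kind=kind))
    return sites
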