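"""Inter-loop anchor distances and residue contact-occupancy maps.

The ligand-recognising apical loops of an Ig domain (CDR1-3) communicate
through transient residue contacts.  This module measures per-frame
C-alpha anchor distances between loops, counts heavy-atom contacts between
residues of different regions, and applies the persistence filter that
keeps only contacts present in strictly more than a chosen fraction of
frames (default 10%).

Default regions use the TREM2 Ig-domain crystal numbering: CDR1 40-47
(anchor His43), CDR2 67-78 (anchor Leu72), CDR3 115-120 (anchor Ser116).
The contact criterion (minimum heavy-atom distance <= 4.5 Å) is the common
persistent-contact convention and is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .descriptors import SeriesSummary
from .trajio import Trajectory

__all__ = [
    "RegionSet",
    "ContactMap",
    "anchor_distance_series",
    "contact_occupancy",
    "filter_contacts",
    "DEFAULT_CONTACT_CUTOFF",
    "DEFAULT_MIN_OCCUPANCY",
]

DEFAULT_CONTACT_CUTOFF = 4.5   # Å, heavy-atom minimum distance
DEFAULT_MIN_OCCUPANCY = 0.10   # strict > filter

_DEFAULT_REGIONS = {"CDR1": (40, 47), "CDR2": (67, 78), "CDR3": (115, 120)}
_DEFAULT_ANCHORS = {"CDR1": 43, "CDR2": 72, "CDR3": 116}


@dataclass
class RegionSet:
    """Named non-overlapping residue ranges with one anchor residue each."""

    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_REGIONS)
    )
    anchors: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_ANCHORS))

    def __post_init__(self) -> None:
        spans = []
        for name, (lo, hi) in self.regions.items():
            if hi < lo:
                raise ValueError(f"region {name} has descending range")
            spans.append((lo, hi, name))
        spans.sort()
        for (_, hi1, n1), (lo2, _, n2) in zip(spans, spans[1:]):
            if lo2 <= hi1:
                raise ValueError(f"regions {n1} and {n2} overlap")
        for name, resid in self.anchors.items():
            if name not in self.regions:
                raise ValueError(f"anchor for unknown region {name}")
            lo, hi = self.regions[name]
            if not lo <= resid <= hi:
                raise ValueError(f"anchor {resid} outside region {name} ({lo}-{hi})")

    @classmethod
    def from_dict(cls, d: dict) -> "RegionSet":
        regions = {k: tuple(v) for k, v in d.get("regions", _DEFAULT_REGIONS).items()}
        anchors = dict(d.get("anchors", _DEFAULT_ANCHORS))
        return cls(regions, anchors)


@dataclass
class ContactMap:
    """Residue-pair contact occupancies between two regions.

    Occupancy is the exact rational (frames-in-contact / total frames).
    """

    region_a: str
    region_b: str
    pairs: pd.DataFrame  # columns: res_i, res_j, occupancy
    n_frames: int
    cutoff: float


def _ca_index(traj: Trajectory, resid: int) -> int:
    for i, a in enumerate(traj.topology.atoms):
        if a.residue_seq == resid and a.name == "CA":
            return i
    raise ValueError(f"residue {resid} has no CA atom")


def anchor_distance_series(traj: Trajectory, res_a: int, res_b: int) -> SeriesSummary:
    """Per-frame C-alpha to C-alpha distance between two anchor residues (Å)."""
    ia, ib = _ca_index(traj, res_a), _ca_index(traj, res_b)
    d = np.linalg.norm(traj.coords[:, ia, :] - traj.coords[:, ib, :], axis=1)
    return SeriesSummary(d, traj.times.copy(), label=f"d({res_a},{res_b})")


def _heavy_indices_by_residue(traj: Trajectory, lo: int, hi: int) -> dict[int, np.ndarray]:
    out: dict[int, list[int]] = {}
    for i, a in enumerate(traj.topology.atoms):
        if lo <= a.residue_seq <= hi and a.element.upper() != "H":
            out.setdefault(a.residue_seq, []).append(i)
    return {r: np.array(ix) for r, ix in out.items()}


def contact_occupancy(
    traj: Trajectory,
    region_a: tuple[int, int],
    region_b: tuple[int, int],
    cutoff: float = DEFAULT_CONTACT_CUTOFF,
    names: tuple[str, str] = ("A", "B"),
) -> ContactMap:
    """Fraction of frames each inter-region residue pair is in contact.

    A pair is in contact in a frame when the minimum heavy-atom distance is
    <= ``cutoff``.  Regions must be disjoint residue ranges.
    """
    (lo_a, hi_a), (lo_b, hi_b) = region_a, region_b
    if not (hi_a < lo_b or hi_b < lo_a):
        raise ValueError("regions must be disjoint")
    atoms_a = _heavy_indices_by_residue(traj, lo_a, hi_a)
    atoms_b = _heavy_indices_by_residue(traj, lo_b, hi_b)
    if not atoms_a or not atoms_b:
        raise ValueError("empty region (no heavy atoms in range)")

    rows = []
    cut2 = cutoff**2
    for ra, ia in sorted(atoms_a.items()):
        for rb, ib in sorted(atoms_b.items()):
            diff = traj.coords[:, ia, None, :] - traj.coords[:, None, ib, :]
            min_d2 = (diff**2).sum(axis=3).reshape(traj.n_frames, -1).min(axis=1)
            k = int((min_d2 <= cut2).sum())
            rows.append({"res_i": ra, "res_j": rb, "occupancy": k / traj.n_frames})
    return ContactMap(names[0], names[1], pd.DataFrame(rows), traj.n_frames, cutoff)


def filter_contacts(
    cmap: ContactMap, min_occupancy: float = DEFAULT_MIN_OCCUPANCY
) -> ContactMap:
    """Keep pairs whose occupancy strictly exceeds ``min_occupancy``.

    The inequality is strict: a pair present in exactly 10% of frames is
    dropped by the default filter.
    """
    kept = cmap.pairs[cmap.pairs["occupancy"] > min_occupancy].reset_index(drop=True)
    return ContactMap(cmap.region_a, cmap.region_b, kept, cmap.n_frames, cmap.cutoff)
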