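"""Backbone hydrogen-bond based secondary-structure assignment and occupancy.

Implements the Kabsch–Sander electrostatic hydrogen-bond model and its
pattern rules: an n-turn is a hydrogen bond from the carbonyl of residue i
to the amide of residue i+n; two consecutive 4-turns define an alpha-helix
(H), two consecutive 3-turns a 3-10 helix (G), and bridge patterns define
beta structure (E).  Amide hydrogens are reconstructed geometrically when
absent so that heavy-atom-only trajectories are fully supported.

Occupancy summaries report, per residue and per named region, the fraction
of frames spent in alpha-helix, 3-10 helix, strand and everything else —
the quantities usually plotted as secondary-structure occupancy bars.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajio import Topology, Trajectory

__all__ = [
    "SSTimeline",
    "hbond_energy",
    "assign_ss",
    "assign_timeline",
    "occupancy",
    "HBOND_CUTOFF_KCAL",
]

#: Kabsch–Sander coupling constant, kcal/mol·Å (q1·q2·f = 0.084·332).
_KS_COUPLING = 0.084 * 332.0
#: A hydrogen bond is declared when E < -0.5 kcal/mol.
HBOND_CUTOFF_KCAL = -0.5
#: Energy cap applied when atoms clash (r < 0.5 Å).
_CLASH_CAP = -9.9
_CLASH_DIST = 0.5
#: Chain break declared when the peptide C-N distance exceeds this (Å).
_BREAK_DIST = 2.5

_BACKBONE = ("N", "CA", "C", "O")
_H_NAMES = ("H", "HN", "H1")


def hbond_energy(n_pos, h_pos, c_pos, o_pos) -> float:
    """Kabsch–Sander electrostatic energy of an N-H...O=C pair (kcal/mol).

    ``E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)``.  Clashing
    geometries (any distance < 0.5 Å) are capped at -9.9 kcal/mol.
    """
    n_pos, h_pos = np.asarray(n_pos, float), np.asarray(h_pos, float)
    c_pos, o_pos = np.asarray(c_pos, float), np.asarray(o_pos, float)
    r_on = np.linalg.norm(o_pos - n_pos)
    r_ch = np.linalg.norm(c_pos - h_pos)
    r_oh = np.linalg.norm(o_pos - h_pos)
    r_cn = np.linalg.norm(c_pos - n_pos)
    if min(r_on, r_ch, r_oh, r_cn) < _CLASH_DIST:
        return _CLASH_CAP
    e = _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    return max(e, _CLASH_CAP)


def _collect_residues(top: Topology) -> list[dict]:
    """Group backbone atom indices by (chain, resseq), in atom order."""
    res: dict[tuple[str, int], dict] = {}
    for i, a in enumerate(top.atoms):
        key = (a.chain_id, a.residue_seq)
        entry = res.setdefault(key, {"key": key, "name": a.residue_name})
        if a.name in _BACKBONE and a.name not in entry:
            entry[a.name] = i
        elif a.name in _H_NAMES and "H" not in entry:
            entry["H"] = i
    return list(res.values())


def _reconstruct_h(n, ca, c_prev) -> np.ndarray:
    """Place the amide H 1.0 Å from N, opposite the C(i-1)/CA bisector."""
    d1 = n - c_prev
    d2 = n - ca
    d1 /= np.linalg.norm(d1)
    d2 /= np.linalg.norm(d2)
    h_dir = d1 + d2
    norm = np.linalg.norm(h_dir)
    if norm < 1e-8:  # pathological straight geometry
        h_dir = d1
        norm = 1.0
    return n + h_dir / norm


def _segments(residues: list[dict], coords: np.ndarray) -> np.ndarray:
    """Segment index per residue; breaks at chain change, gaps or missing
    backbone atoms, or peptide C-N distance > 2.5 Å."""
    n_res = len(residues)
    seg = np.zeros(n_res, dtype=int)
    current = 0
    for i in range(n_res):
        if i == 0:
            seg[i] = current
            continue
        prev, cur = residues[i - 1], residues[i]
        new_segment = (
            prev["key"][0] != cur["key"][0]
            or not all(k in prev for k in _BACKBONE)
            or not all(k in cur for k in _BACKBONE)
        )
        if not new_segment:
            d = np.linalg.norm(coords[cur["N"]] - coords[prev["C"]])
            new_segment = d > _BREAK_DIST
        if new_segment:
            current += 1
        seg[i] = current
    return seg


def _hbond_matrix(residues, seg, coords) -> np.ndarray:
    """HB[i, j] is True when C=O of residue i accepts from N-H of residue j.

    The donor's own residue and its peptide-bond partner (j = i + 1 within a
    segment) are excluded; prolines have no amide H and never donate.
    """
    n_res = len(residues)
    hb = np.zeros((n_res, n_res), dtype=bool)

    h_pos: list[np.ndarray | None] = [None] * n_res
    for j, r in enumerate(residues):
        if r["name"] == "PRO":
            continue
        if "H" in r:
            h_pos[j] = coords[r["H"]]
        elif all(k in r for k in ("N", "CA")) and j > 0 and seg[j] == seg[j - 1] \
                and "C" in residues[j - 1]:
            h_pos[j] = _reconstruct_h(
                coords[r["N"]], coords[r["CA"]], coords[residues[j - 1]["C"]]
            )

    for i, acc in enumerate(residues):
        if "C" not in acc or "O" not in acc:
            continue
        c_i, o_i = coords[acc["C"]], coords[acc["O"]]
        for j, don in enumerate(residues):
            if j == i or (j == i + 1 and seg[j] == seg[i]):
                continue
            if h_pos[j] is None or "N" not in don:
                continue
            n_j = coords[don["N"]]
            if np.linalg.norm(o_i - n_j) > 5.2:  # bonds beyond this are > -0.5
                continue
            e = hbond_energy(n_j, h_pos[j], c_i, o_i)
            hb[i, j] = e < HBOND_CUTOFF_KCAL
    return hb


def assign_ss(frame_coords: np.ndarray, top: Topology) -> np.ndarray:
    """Assign one secondary-structure label per residue for one frame.

    Returns an array over residues (order of :meth:`Topology.residues`) with
    labels in {H, G, E, T, C}.  Conflicts resolve with priority
    H > E > G > T > C.  Pi-helix turns are folded into T.
    """
    coords = np.asarray(frame_coords, float)
    residues = _collect_residues(top)
    n_res = len(residues)
    seg = _segments(residues, coords)
    hb = _hbond_matrix(residues, seg, coords)

    def turn(n: int, i: int) -> bool:
        j = i + n
        return j < n_res and seg[i] == seg[j] and hb[i, j]

    is_h = np.zeros(n_res, bool)
    is_g = np.zeros(n_res, bool)
    is_e = np.zeros(n_res, bool)
    is_t = np.zeros(n_res, bool)

    # minimal helices: two consecutive n-turns
    for i in range(1, n_res):
        if turn(4, i - 1) and turn(4, i):
            is_h[i:min(i + 4, n_res)] = True
        if turn(3, i - 1) and turn(3, i):
            is_g[i:min(i + 3, n_res)] = True

    # bridges (parallel and antiparallel); ladder vs isolated not separated
    def hbx(i: int, j: int) -> bool:
        return 0 <= i < n_res and 0 <= j < n_res and hb[i, j]

    for i in range(n_res):
        for j in range(i + 1, n_res):
            if seg[i] == seg[j] and j - i < 3:
                continue
            para = (hbx(i - 1, j) and hbx(j, i + 1)) or \
                   (hbx(j - 1, i) and hbx(i, j + 1))
            anti = (hbx(i, j) and hbx(j, i)) or \
                   (hbx(i - 1, j + 1) and hbx(j - 1, i + 1))
            if para or anti:
                is_e[i] = is_e[j] = True

    for n in (3, 4, 5):
        for i in range(n_res):
            if turn(n, i):
                is_t[i + 1:i + n] = True

    labels = np.full(n_res, "C", dtype="<U1")
    labels[is_t] = "T"
    labels[is_g] = "G"
    labels[is_e] = "E"
    labels[is_h] = "H"
    return labels


@dataclass
class SSTimeline:
    """Per-frame, per-residue secondary-structure labels."""

    residue_ids: list[tuple[str, int]]
    labels: np.ndarray  # T x R, single characters

    @property
    def n_frames(self) -> int:
        return self.labels.shape[0]

    def to_text(self) -> str:
        """One row per frame, one character per residue."""
        return "\n".join("".join(row) for row in self.labels)


def assign_timeline(traj: Trajectory) -> SSTimeline:
    """Assign secondary structure for every frame of a trajectory."""
    residue_ids = traj.topology.residues()
    rows = [assign_ss(traj.coords[t], traj.topology) for t in range(traj.n_frames)]
    return SSTimeline(residue_ids, np.array(rows))


def occupancy(
    timeline: SSTimeline,
    regions: dict[str, tuple[int, int]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Per-residue and (optionally) per-region class occupancy fractions.

    Classes are alpha-helix H, 3-10 helix G, strand E, and "other" (turns,
    bends, coil).  Per-residue fractions sum to 1 by construction.  Region
    occupancy is the mean over the region's residues; both fractions and
    percentages are reported.
    """
    t, r = timeline.labels.shape
    if t == 0 or r == 0:
        raise ValueError("empty timeline")
    classes = ("H", "G", "E")
    data = {}
    for cls in classes:
        data[f"frac_{cls}"] = (timeline.labels == cls).sum(axis=0) / t
    data["frac_other"] = 1.0 - sum(data[f"frac_{c}"] for c in classes)
    per_res = pd.DataFrame(data)
    per_res.insert(0, "chain", [c for c, _ in timeline.residue_ids])
    per_res.insert(1, "resid", [s for _, s in timeline.residue_ids])

    per_region = None
    if regions is not None:
        resids = np.array(per_res["resid"])
        rows = []
        for name, (lo, hi) in regions.items():
            mask = (resids >= lo) & (resids <= hi)
            if not mask.any():
                raise ValueError(f"region {name} ({lo}-{hi}) outside topology")
            row = {"region": name}
            for cls in ("H", "G", "E", "other"):
                frac = float(per_res.loc[mask, f"frac_{cls}"].mean())
                row[f"frac_{cls}"] = frac
                row[f"pct_{cls}"] = 100.0 * frac
            rows.append(row)
        per_region = pd.DataFrame(rows)
    return per_res, per_region
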