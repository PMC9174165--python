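"""Structure/trajectory containers, multi-model PDB I/O and atom selections.

The trajectory container is deliberately minimal: a topology (atom metadata),
a ``T x N x 3`` coordinate array in angstrom, and a strictly increasing time
axis in nanoseconds.  Coordinates are orthogonal angstrom with no periodic
box; frames are assumed to contain a single pre-imaged solute, which is the
normal situation after solvent stripping.  Residue numbering is taken
verbatim from the input file so that region definitions expressed in the
crystal-structure numbering (e.g. CDR1 = residues 40-47 of the TREM2 Ig
domain) apply without re-indexing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    EmptySelectionError,
    EmptySliceError,
    FormatError,
    SelectionError,
    StructuralMismatchError,
)

__all__ = [
    "Atom",
    "Topology",
    "Trajectory",
    "AtomIndexSet",
    "read_multi_model_pdb",
    "write_multi_model_pdb",
    "select",
    "slice_time",
    "concat",
    "DEFAULT_DT_NS",
]

#: Default frame spacing when a file carries no time information (ns).
#: Matches a 100 ps trajectory save interval.
DEFAULT_DT_NS = 0.1

BACKBONE_NAMES = ("N", "CA", "C", "O")

#: Standard atomic masses for mass-weighted descriptors (u).
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971,
}


@dataclass(frozen=True)
class Atom:
    name: str
    element: str
    residue_seq: int
    residue_name: str
    chain_id: str


@dataclass
class Topology:
    """Ordered atom metadata shared by every frame of a trajectory."""

    atoms: list[Atom]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def mass(self, i: int) -> float:
        return ATOMIC_MASSES.get(self.atoms[i].element.upper(), 12.011)

    def masses(self, indices=None) -> np.ndarray:
        idx = range(self.n_atoms) if indices is None else indices
        return np.array([self.mass(i) for i in idx], dtype=float)

    def residues(self) -> list[tuple[str, int]]:
        """Unique (chain_id, residue_seq) keys in atom order."""
        seen: dict[tuple[str, int], None] = {}
        for a in self.atoms:
            seen.setdefault((a.chain_id, a.residue_seq), None)
        return list(seen)

    def __eq__(self, other) -> bool:
        return isinstance(other, Topology) and self.atoms == other.atoms


@dataclass
class Trajectory:
    """A topology plus T frames of coordinates (angstrom) and times (ns)."""

    topology: Topology
    coords: np.ndarray  # T x N x 3, angstrom
    times: np.ndarray   # T, ns, strictly increasing
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(f"coords must be T x N x 3, got {self.coords.shape}")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise StructuralMismatchError(
                f"coords hold {self.coords.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if len(self.times) != self.coords.shape[0]:
            raise ValueError("times length must equal the number of frames")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms


@dataclass
class AtomIndexSet:
    """A sorted, duplicate-free set of atom indices with a human label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.ndim != 1:
            raise ValueError("indices must be one-dimensional")
        if len(np.unique(idx)) != len(idx):
            raise ValueError("indices must be unique")
        if np.any(np.diff(idx) < 0):
            idx = np.sort(idx)
        self.indices = idx

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


# ---------------------------------------------------------------------------
# multi-model PDB I/O
# ---------------------------------------------------------------------------

def _parse_atom_line(line: str, lineno: int) -> tuple[Atom, np.ndarray]:
    try:
        name = line[12:16].strip()
        altloc = line[16]
        resname = line[17:20].strip()
        chain = line[21].strip() or "A"
        resseq = int(line[22:26])
        icode = line[26]
        xyz = np.array(
            [float(line[30:38]), float(line[38:46]), float(line[46:54])]
        )
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise FormatError(f"unparseable ATOM record at line {lineno}: {exc}") from exc
    if icode.strip():
        raise FormatError(f"insertion code {icode!r} at line {lineno} not supported")
    if altloc not in (" ", "A"):
        return None, None  # skipped alternate location
    if not element:
        # fall back on the first letter of the atom name
        element = re.sub(r"[^A-Za-z]", "", name)[:1].upper()
    return Atom(name, element, resseq, resname, chain), xyz


def read_multi_model_pdb(path, dt_ns: float = DEFAULT_DT_NS) -> Trajectory:
    """Read a multi-model PDB file into a :class:`Trajectory`.

    Frames are ordered by MODEL number; a file without MODEL records is
    treated as a single frame.  Times default to ``frame_index * dt_ns``.
    Alternate locations other than ' '/'A' are dropped; insertion codes are
    rejected so that ``(chain, residue_seq)`` is an unambiguous residue key.
    """
    frames: list[list[np.ndarray]] = []
    atom_meta: list[list[Atom]] = []
    current_xyz: list[np.ndarray] | None = None
    current_atoms: list[Atom] | None = None
    in_model = False

    def close_model() -> None:
        nonlocal current_xyz, current_atoms
        if current_xyz is not None and current_xyz:
            frames.append(current_xyz)
            atom_meta.append(current_atoms)
        current_xyz, current_atoms = None, None

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            rec = line[:6].strip()
            if rec == "MODEL":
                close_model()
                current_xyz, current_atoms = [], []
                in_model = True
            elif rec == "ENDMDL":
                close_model()
            elif rec in ("ATOM", "HETATM"):
                if current_xyz is None:
                    if in_model:
                        continue  # between models; stray record ignored
                    current_xyz, current_atoms = [], []
                atom, xyz = _parse_atom_line(line, lineno)
                if atom is None:
                    continue
                current_atoms.append(atom)
                current_xyz.append(xyz)
    close_model()

    if not frames:
        raise FormatError(f"no ATOM records found in {path}")

    n0 = len(frames[0])
    for k, (meta, xyz) in enumerate(zip(atom_meta, frames)):
        if len(xyz) != n0:
            raise StructuralMismatchError(
                f"model {k + 1} has {len(xyz)} atoms, expected {n0}"
            )
        if meta != atom_meta[0]:
            raise StructuralMismatchError(
                f"model {k + 1} atom records differ from model 1"
            )

    coords = np.array(frames)
    times = np.arange(len(frames), dtype=float) * dt_ns
    return Trajectory(Topology(atom_meta[0]), coords, times)


def write_multi_model_pdb(traj: Trajectory, path) -> None:
    """Write a trajectory as a standard fixed-column multi-model PDB."""
    if traj.n_frames == 0:
        raise ValueError("cannot write an empty trajectory")
    if not np.all(np.isfinite(traj.coords)):
        raise ValueError("coordinates must be finite")
    if np.any(np.abs(traj.coords) >= 10000.0):
        raise ValueError(
            "coordinate overflows the %8.3f PDB field; refusing to truncate"
        )
    with open(path, "w") as fh:
        for m in range(traj.n_frames):
            fh.write(f"MODEL     {m + 1:4d}\n")
            for i, atom in enumerate(traj.topology.atoms):
                x, y, z = traj.coords[m, i]
                name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
                fh.write(
                    f"ATOM  {i + 1 if i < 99999 else 99999:5d} {name}"
                    f" {atom.residue_name:>3s} {atom.chain_id:1s}"
                    f"{atom.residue_seq:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.00:6.2f}{0.00:6.2f}          "
                    f"{atom.element:>2s}\n"
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_RANGE_RE = re.compile(r"^(-?\d+)-(-?\d+)$")


def _parse_resid_spec(spec: str) -> set[int]:
    out: set[int] = set()
    for part in spec.split(","):
        part = part.strip()
        if not part:
            continue
        m = _RANGE_RE.match(part)
        if m:
            lo, hi = int(m.group(1)), int(m.group(2))
            if hi < lo:
                raise SelectionError(f"descending residue range {part!r}")
            out.update(range(lo, hi + 1))
        else:
            try:
                out.add(int(part))
            except ValueError as exc:
                raise SelectionError(f"bad residue token {part!r}") from exc
    if not out:
        raise SelectionError(f"empty residue specification {spec!r}")
    return out


def _clause_mask(top: Topology, tokens: list[str]) -> np.ndarray:
    if not tokens:
        raise SelectionError("empty selection clause")
    head, rest = tokens[0].lower(), tokens[1:]
    if head == "all":
        if rest:
            raise SelectionError("'all' takes no arguments")
        return np.ones(top.n_atoms, bool)
    if head == "backbone":
        if rest:
            raise SelectionError("'backbone' takes no arguments")
        return np.array([a.name in BACKBONE_NAMES for a in top.atoms])
    if head == "name":
        if not rest:
            raise SelectionError("'name' needs at least one atom name")
        wanted = {t.strip() for tok in rest for t in tok.split(",") if t.strip()}
        return np.array([a.name in wanted for a in top.atoms])
    if head == "resid":
        if not rest:
            raise SelectionError("'resid' needs a range or list")
        wanted = _parse_resid_spec(",".join(rest))
        return np.array([a.residue_seq in wanted for a in top.atoms])
    raise SelectionError(f"unknown selection token {head!r}")


def select(traj_or_top, expr: str) -> AtomIndexSet:
    """Resolve a selection expression against a trajectory's topology.

    Grammar: clauses joined by ``and``; a clause is one of ``all``,
    ``backbone`` (N, CA, C, O), ``name NAME[,NAME...]`` or
    ``resid A-B[,C,...]``.  The result preserves atom order and depends only
    on topology, never on frame coordinates.
    """
    top = traj_or_top.topology if isinstance(traj_or_top, Trajectory) else traj_or_top
    expr = expr.strip()
    if not expr:
        raise SelectionError("empty selection expression")
    mask = np.ones(top.n_atoms, bool)
    for clause in re.split(r"\s+and\s+", expr):
        mask &= _clause_mask(top, clause.split())
    indices = np.flatnonzero(mask)
    if len(indices) == 0:
        raise EmptySelectionError(f"selection {expr!r} matched no atoms")
    return AtomIndexSet(indices, label=expr)


# ---------------------------------------------------------------------------
# slicing and concatenation
# ---------------------------------------------------------------------------

def slice_time(traj: Trajectory, t_start: float, t_stop: float) -> Trajectory:
    """Keep frames with ``t_start <= t <= t_stop`` (times preserved)."""
    if not t_start < t_stop:
        raise ValueError("t_start must be < t_stop")
    mask = (traj.times >= t_start) & (traj.times <= t_stop)
    if not mask.any():
        raise EmptySliceError(
            f"slice [{t_start}, {t_stop}] ns contains no frames "
            f"(trajectory spans [{traj.times[0]}, {traj.times[-1]}] ns)"
        )
    return Trajectory(
        traj.topology, traj.coords[mask].copy(), traj.times[mask].copy(),
        metadata=dict(traj.metadata),
    )


def concat(trajs: list[Trajectory]) -> Trajectory:
    """Concatenate replicas onto one strictly increasing time axis.

    Times are re-indexed by cumulative offset; the original (replica, time)
    of every frame is retained under ``metadata['provenance']``.
    """
    if not trajs:
        raise ValueError("need at least one trajectory")
    top = trajs[0].topology
    for k, t in enumerate(trajs[1:], 2):
        if t.topology != top:
            raise StructuralMismatchError(f"trajectory {k} topology differs from 1")
    coords = np.concatenate([t.coords for t in trajs], axis=0)
    times, provenance = [], []
    offset = 0.0
    for rep, t in enumerate(trajs):
        dt = np.median(np.diff(t.times)) if t.n_frames > 1 else DEFAULT_DT_NS
        shifted = t.times - t.times[0] + offset
        times.append(shifted)
        offset = shifted[-1] + dt
        provenance.extend((rep, float(orig)) for orig in t.times)
    return Trajectory(
        top, coords, np.concatenate(times), metadata={"provenance": provenance}
    )
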