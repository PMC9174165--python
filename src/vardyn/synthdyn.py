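"""Synthetic structures, trajectories and predictor call tables.

Every analysis stage in this package is exercised against ensembles with a
known ground truth: Gaussian ensembles with a prescribed 3N x 3N covariance
(so cross-correlations and principal components are known by construction),
drifting ensembles (emulating pre-equilibration relaxation), two-state
switching ensembles (emulating a free-energy landscape with two basins),
ideal-torsion peptides (geometric ground truth for secondary-structure
assignment), and Bernoulli predictor call tables with tunable per-tool
deleterious probabilities.

All generators draw from a single ``numpy.random.default_rng(seed)`` stream
per call and are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import secstruct
from .consensus import CallTable
from .trajio import Atom, Topology, Trajectory, DEFAULT_DT_NS

__all__ = [
    "EnsembleSpec",
    "TwoStateSpec",
    "CallTableSpec",
    "gen_gaussian_ensemble",
    "gen_drift_ensemble",
    "gen_two_state_ensemble",
    "build_ideal_peptide",
    "gen_call_table",
    "gen_trem2_like_call_table",
    "ca_topology",
]

# ideal backbone geometry (Å / degrees): standard peptide values
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

#: (phi, psi) in degrees per secondary-structure code.
TORSIONS = {
    "H": (-57.0, -47.0),    # alpha helix
    "G": (-49.0, -26.0),    # 3-10 helix
    "E": (-119.0, 113.0),   # beta strand
    "C": (-75.0, 150.0),    # polyproline-II-like irregular coil
}


def ca_topology(n_atoms: int, start_resid: int = 1) -> Topology:
    """A minimal one-CA-per-residue topology for coordinate-only ensembles."""
    return Topology(
        [Atom("CA", "C", start_resid + i, "ALA", "A") for i in range(n_atoms)]
    )


def _times(n_frames: int) -> np.ndarray:
    return np.arange(n_frames, dtype=float) * DEFAULT_DT_NS


# ---------------------------------------------------------------------------
# Gaussian / drift / two-state ensembles
# ---------------------------------------------------------------------------

@dataclass
class EnsembleSpec:
    reference: np.ndarray        # N x 3, Å
    covariance: np.ndarray       # 3N x 3N, Å², symmetric PSD
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, float)
        self.covariance = np.asarray(self.covariance, float)
        n3 = self.reference.size
        if self.covariance.shape != (n3, n3):
            raise ValueError("covariance must be 3N x 3N")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


def gen_gaussian_ensemble(spec: EnsembleSpec, topology: Topology | None = None) -> Trajectory:
    """Frames drawn i.i.d. from N(reference, covariance) in 3N space.

    Raises ``ValueError`` when the covariance is not positive semidefinite
    (eigenvalues below -1e-8).
    """
    w, v = np.linalg.eigh(spec.covariance)
    if w.min() < -1e-8:
        raise ValueError(f"covariance not PSD (min eigenvalue {w.min():.3g})")
    rng = np.random.default_rng(spec.seed)
    n3 = spec.reference.size
    a = v * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((spec.n_frames, n3))
    flat = spec.reference.reshape(-1) + z @ a.T
    coords = flat.reshape(spec.n_frames, -1, 3)
    top = topology or ca_topology(coords.shape[1])
    return Trajectory(top, coords, _times(spec.n_frames))


def gen_drift_ensemble(
    reference: np.ndarray,
    drift_per_frame: np.ndarray,
    noise_sigma: float,
    n_frames: int,
    seed: int,
    topology: Topology | None = None,
) -> Trajectory:
    """frame k = reference + k * drift + isotropic Gaussian noise.

    Emulates the slow relaxation seen before a simulation equilibrates, on
    top of stationary thermal jitter.
    """
    reference = np.asarray(reference, float)
    drift = np.asarray(drift_per_frame, float)
    if drift.shape != reference.shape:
        raise ValueError("drift_per_frame must match reference shape")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    k = np.arange(n_frames, dtype=float)[:, None, None]
    coords = reference[None] + k * drift[None]
    if noise_sigma > 0:
        coords = coords + noise_sigma * rng.standard_normal(coords.shape)
    top = topology or ca_topology(reference.shape[0])
    return Trajectory(top, coords, _times(n_frames))


@dataclass
class TwoStateSpec:
    ref_a: np.ndarray     # N x 3, Å
    ref_b: np.ndarray     # N x 3, Å
    p_a: float            # fraction of frames in state A, in (0, 1)
    noise_sigma: float    # Å
    n_frames: int
    seed: int

    def __post_init__(self) -> None:
        self.ref_a = np.asarray(self.ref_a, float)
        self.ref_b = np.asarray(self.ref_b, float)
        if self.ref_a.shape != self.ref_b.shape:
            raise ValueError("ref_a and ref_b must have the same shape")
        if not 0.0 < self.p_a < 1.0:
            raise ValueError("p_a must lie strictly in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")


def gen_two_state_ensemble(spec: TwoStateSpec, topology: Topology | None = None) -> Trajectory:
    """Bernoulli switching between two reference conformations plus jitter.

    The per-frame state labels (True = state A) are recorded under
    ``metadata['state_labels']`` so downstream basin statistics can be
    verified against the generating truth.
    """
    rng = np.random.default_rng(spec.seed)
    in_a = rng.random(spec.n_frames) < spec.p_a
    coords = np.where(in_a[:, None, None], spec.ref_a[None], spec.ref_b[None])
    if spec.noise_sigma > 0:
        coords = coords + spec.noise_sigma * rng.standard_normal(coords.shape)
    top = topology or ca_topology(spec.ref_a.shape[0])
    traj = Trajectory(top, coords, _times(spec.n_frames))
    traj.metadata["state_labels"] = in_a
    return traj


# ---------------------------------------------------------------------------
# ideal-geometry peptides
# ---------------------------------------------------------------------------

def _place_atom(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d given bond c-d, angle b-c-d and torsion a-b-c-d."""
    theta = np.deg2rad(angle_deg)
    phi = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = bond * (-np.cos(theta) * bc + np.sin(theta) * (np.cos(phi) * m + np.sin(phi) * n))
    return c + d


def _build_backbone(pattern: str) -> np.ndarray:
    """NeRF chain growth of an N/CA/C/O backbone from per-residue torsions."""
    n_res = len(pattern)
    phis = np.empty(n_res)
    psis = np.empty(n_res)
    for i, code in enumerate(pattern):
        phi, psi = TORSIONS[code]
        if code == "C":
            # deterministic irregularity so coil never locks into a repeat
            phi += 10.0 * np.sin(1.7 * i)
            psi += 12.0 * np.cos(2.3 * i)
        phis[i], psis[i] = phi, psi

    coords = np.zeros((n_res, 4, 3))  # N, CA, C, O per residue
    a111 = np.deg2rad(_A_N_CA_C)
    coords[0, 0] = (0.0, 0.0, 0.0)
    coords[0, 1] = (_B_N_CA, 0.0, 0.0)
    coords[0, 2] = coords[0, 1] + _B_CA_C * np.array(
        [-np.cos(a111), np.sin(a111), 0.0]
    )
    for i in range(1, n_res):
        n_prev, ca_prev, c_prev = coords[i - 1, 0], coords[i - 1, 1], coords[i - 1, 2]
        coords[i, 0] = _place_atom(n_prev, ca_prev, c_prev, _B_C_N, _A_CA_C_N, psis[i - 1])
        coords[i, 1] = _place_atom(ca_prev, c_prev, coords[i, 0], _B_N_CA, _A_C_N_CA, 180.0)
        coords[i, 2] = _place_atom(c_prev, coords[i, 0], coords[i, 1], _B_CA_C, _A_N_CA_C, phis[i])
    for i in range(n_res):
        coords[i, 3] = _place_atom(
            coords[i, 0], coords[i, 1], coords[i, 2], _B_C_O, _A_CA_C_O, psis[i] + 180.0
        )
    return coords


def _principal_align(coords: np.ndarray) -> np.ndarray:
    """Center a backbone and rotate its principal axes onto x/y/z."""
    flat = coords.reshape(-1, 3)
    center = flat.mean(axis=0)
    centered = flat - center
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    if np.linalg.det(vt) < 0:
        vt[2] *= -1.0
    aligned = centered @ vt.T
    # orient the strand axis from first to last residue along +x
    if aligned.reshape(coords.shape)[-1, 1, 0] < aligned.reshape(coords.shape)[0, 1, 0]:
        aligned[:, 0] *= -1.0
        aligned[:, 1] *= -1.0
    return aligned.reshape(coords.shape)


def _chain_topology(n_res: int, chain_id: str, start_resid: int = 1) -> list[Atom]:
    atoms = []
    for i in range(n_res):
        resid = start_resid + i
        for name, elem in (("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")):
            atoms.append(Atom(name, elem, resid, "ALA", chain_id))
    return atoms


def _pair_strand(chain_a: np.ndarray, antiparallel: bool) -> np.ndarray:
    """Place a duplicate strand next to ``chain_a`` so the two form an
    inter-chain hydrogen-bonded sheet.

    The partner is a rigid copy (rotated 180 degrees about the strand axis
    and, for antiparallel pairing, about the sheet normal) whose in-plane
    offset is chosen by a deterministic grid search that maximises the
    number of Kabsch–Sander inter-chain hydrogen bonds.
    """
    n_res = chain_a.shape[0]

    def transformed(flip_x: bool, reverse: bool, dx: float, dy: float) -> np.ndarray:
        b = chain_a.copy().reshape(-1, 3)
        if flip_x:      # rotate about x: flips the pleat to face chain A
            b[:, 1] *= -1.0
            b[:, 2] *= -1.0
        if reverse:     # rotate about z: antiparallel orientation
            b[:, 0] *= -1.0
            b[:, 1] *= -1.0
        b[:, 0] += dx
        b[:, 1] += dy
        return b.reshape(chain_a.shape)

    top = Topology(_chain_topology(n_res, "A") + _chain_topology(n_res, "B"))
    best, best_score = None, (-1, 0.0)
    for flip_x in (False, True):
        for dx in np.arange(-3.5, 3.51, 0.25):
            for dy in np.arange(3.6, 6.01, 0.1):
                cand = transformed(flip_x, antiparallel, dx, dy)
                frame = np.concatenate([chain_a.reshape(-1, 3), cand.reshape(-1, 3)])
                labels = secstruct.assign_ss(frame, top)
                n_e = int((labels == "E").sum())
                if n_e > best_score[0]:
                    best_score = (n_e, dy)
                    best = cand
    if best is None or best_score[0] == 0:
        raise RuntimeError("could not find a hydrogen-bonded strand pairing")
    return best


def build_ideal_peptide(
    n_res: int,
    ss_pattern: str,
    paired: bool | None = None,
) -> Trajectory:
    """Single-frame poly-alanine backbone built from ideal torsions.

    Codes: H alpha-helix (-57, -47), G 3-10 helix (-49, -26), E beta strand
    (-119, 113), C extended irregular coil.  A single-character pattern is
    tiled to ``n_res``.  When the pattern is all-E (or ``paired=True``) a
    duplicate antiparallel strand is added as chain B so that Kabsch–Sander
    bridge patterns can form; isolated strands have no partners and are never
    assigned E.
    """
    if n_res < 4:
        raise ValueError("n_res must be >= 4")
    if len(ss_pattern) == 1:
        ss_pattern = ss_pattern * n_res
    if len(ss_pattern) != n_res:
        raise ValueError("ss_pattern length must equal n_res (or be one code)")
    bad = set(ss_pattern) - set(TORSIONS)
    if bad:
        raise ValueError(f"unknown secondary-structure code(s): {sorted(bad)}")

    coords = _principal_align(_build_backbone(ss_pattern))
    if paired is None:
        paired = set(ss_pattern) == {"E"}

    if paired:
        chain_b = _pair_strand(coords, antiparallel=True)
        atoms = _chain_topology(n_res, "A") + _chain_topology(n_res, "B")
        frame = np.concatenate([coords.reshape(-1, 3), chain_b.reshape(-1, 3)])
    else:
        atoms = _chain_topology(n_res, "A")
        frame = coords.reshape(-1, 3)
    return Trajectory(Topology(atoms), frame[None], np.array([0.0]))


# ---------------------------------------------------------------------------
# predictor call tables
# ---------------------------------------------------------------------------

@dataclass
class CallTableSpec:
    n_snps: int
    n_tools: int
    p_deleterious: np.ndarray  # per-SNP per-tool deleterious probability
    seed: int

    def __post_init__(self) -> None:
        p = np.asarray(self.p_deleterious, float)
        if p.ndim == 0:
            p = np.full(self.n_snps, float(p))
        if p.shape == (self.n_snps,):
            p = np.repeat(p[:, None], self.n_tools, axis=1)
        if p.shape != (self.n_snps, self.n_tools):
            raise ValueError("p_deleterious must broadcast to n_snps x n_tools")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.p_deleterious = p


def gen_call_table(spec: CallTableSpec) -> tuple[CallTable, np.ndarray]:
    """Seeded Bernoulli deleterious calls plus the ground-truth vote counts."""
    rng = np.random.default_rng(spec.seed)
    calls = (rng.random((spec.n_snps, spec.n_tools)) < spec.p_deleterious)
    calls = calls.astype(float)
    table = CallTable(
        snp_ids=[f"snp{i:04d}" for i in range(spec.n_snps)],
        tool_names=[f"tool{k:02d}" for k in range(spec.n_tools)],
        calls=calls,
    )
    return table, calls.sum(axis=1).astype(int)


#: The 17 deleteriousness predictors aggregated in the consensus vote.
PREDICTOR_NAMES = [
    "SIFT", "PolyPhen", "Condel", "CADD", "DANN", "FATHMM", "M-CAP",
    "MetaLR", "MutPred", "MutationAssessor", "PROVEAN", "VEST3",
    "fathmm-MKL", "MuPro", "iStable", "PhD-SNP", "SNAP2",
]

#: High-risk TREM2 variants reaching the consensus threshold.
HIGH_RISK_SNPS = {
    "rs549402254": "W50S",
    "rs749358844": "R52C",
    "rs1409131974": "D104G",
}


def gen_trem2_like_call_table(seed: int = 0, n_snps: int = 228) -> tuple[CallTable, np.ndarray]:
    """Synthetic stand-in for the TREM2 228-SNP x 17-predictor call matrix.

    No public machine-readable per-tool call matrix exists for the TREM2
    missense variants, so this generator plants the known consensus outcome
    as ground truth: the three high-risk variants rs549402254 (W50S),
    rs749358844 (R52C) and rs1409131974 (D104G) receive 15 or more
    deleterious calls out of 17 tools, and every other variant is capped
    below 15.  All other structure (which tools call which benign variant
    deleterious) is seeded-random.  Returns the table and the ground-truth
    vote counts.
    """
    rng = np.random.default_rng(seed)
    n_tools = len(PREDICTOR_NAMES)
    high_risk = list(HIGH_RISK_SNPS)
    if n_snps < len(high_risk):
        raise ValueError("n_snps must be at least the number of planted SNPs")

    others = []
    while len(others) < n_snps - len(high_risk):
        rsid = f"rs{rng.integers(10_000_000, 2_000_000_000)}"
        if rsid not in HIGH_RISK_SNPS and rsid not in others:
            others.append(rsid)
    snp_ids = high_risk + others

    calls = np.zeros((n_snps, n_tools))
    for row, votes in enumerate((17, 16, 15)):  # planted high-risk counts
        on = rng.choice(n_tools, size=votes, replace=False)
        calls[row, on] = 1.0
    for row in range(len(high_risk), n_snps):
        votes = int(np.clip(rng.binomial(n_tools, rng.beta(2.0, 3.0)), 0, 14))
        on = rng.choice(n_tools, size=votes, replace=False)
        calls[row, on] = 1.0

    table = CallTable(snp_ids=snp_ids, tool_names=list(PREDICTOR_NAMES), calls=calls)
    return table, calls.sum(axis=1).astype(int)
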