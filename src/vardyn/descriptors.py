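"""Ensemble descriptors: superposition, RMSD, Rg, SASA, RMSF, B-factors.

Conventions follow common MD-analysis practice: RMSD is measured against
the first frame of a run after least-squares (Kabsch) superposition on the
backbone; RMSF is measured about the iteratively converged mean structure;
SASA uses Shrake–Rupley sphere-point counting with a 1.4 Å water probe and
a deterministic spiral point lattice; B-factors derive from RMSF via the
isotropic relation B = (8 pi^2 / 3) RMSF^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .errors import DegenerateGeometryError, EmptySelectionError
from .trajio import AtomIndexSet, Trajectory

__all__ = [
    "SeriesSummary",
    "SuperpositionResult",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "radius_of_gyration",
    "rg_series",
    "sasa",
    "sasa_series",
    "rmsf",
    "rmsf_to_bfactor",
    "superpose_trajectory",
    "VDW_RADII",
    "BFACTOR_FACTOR",
]

#: Per-element van der Waals radii for SASA (Å); community defaults.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "H": 1.20}
_DEFAULT_RADIUS = 1.70
DEFAULT_PROBE = 1.4

#: B = (8 pi^2 / 3) * RMSF^2
BFACTOR_FACTOR = 8.0 * np.pi**2 / 3.0


@dataclass
class SeriesSummary:
    """A per-frame descriptor series with a kernel-density summary.

    The density uses a Gaussian kernel with Silverman's bandwidth on a
    512-point grid and integrates to 1 (trapezoidal) within 1e-3.
    """

    values: np.ndarray
    times: np.ndarray | None = None
    label: str = ""
    _density: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    def quantiles(self, q=(0.25, 0.5, 0.75)) -> np.ndarray:
        return np.quantile(self.values, q)

    @property
    def density(self) -> tuple[np.ndarray, np.ndarray]:
        """(grid, pdf) covering [min, max] of the series."""
        if self._density is None:
            v = self.values
            if v.std() == 0.0:
                # degenerate series: narrow analytic Gaussian at the value
                bw = 1e-3
                grid = np.linspace(v[0] - 6 * bw, v[0] + 6 * bw, 512)
                pdf = np.exp(-0.5 * ((grid - v[0]) / bw) ** 2) / (bw * np.sqrt(2 * np.pi))
            else:
                kde = gaussian_kde(v, bw_method="silverman")
                bw = np.sqrt(kde.covariance[0, 0])
                grid = np.linspace(v.min() - 5 * bw, v.max() + 5 * bw, 512)
                pdf = kde(grid)
            self._density = (grid, pdf)
        return self._density


@dataclass
class SuperpositionResult:
    rotation: np.ndarray      # 3 x 3 proper rotation
    translation: np.ndarray   # 3-vector, Å
    rmsd_min: float           # Å


def _as_indices(sel) -> np.ndarray | slice:
    if sel is None:
        return slice(None)
    if isinstance(sel, AtomIndexSet):
        if len(sel) == 0:
            raise EmptySelectionError("empty selection")
        return sel.indices
    return np.asarray(sel, int)


def kabsch_superpose(
    mobile: np.ndarray, ref: np.ndarray, weights: np.ndarray | None = None
) -> SuperpositionResult:
    """Weighted least-squares rigid fit of ``mobile`` onto ``ref``.

    Returns the proper rotation R and translation t minimising the weighted
    RMSD of ``R x + t`` to ``ref``; reflections are corrected.
    """
    mobile = np.asarray(mobile, float)
    ref = np.asarray(ref, float)
    if mobile.shape != ref.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and ref must both be N x 3")
    n = mobile.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 atoms to superpose")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    if w.shape != (n,) or w.min() < 0 or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    com_m = w @ mobile
    com_r = w @ ref
    xm = mobile - com_m
    xr = ref - com_r
    sv = np.linalg.svd(xr * w[:, None], compute_uv=False)
    if sv[1] < 1e-8:
        raise DegenerateGeometryError("reference geometry is (near-)collinear")

    h = (xm * w[:, None]).T @ xr
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rot = vt.T @ corr @ u.T
    trans = com_r - rot @ com_m
    fitted = mobile @ rot.T + trans
    rmsd = float(np.sqrt((w * ((fitted - ref) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(rot, trans, rmsd)


def apply_superposition(coords: np.ndarray, result: SuperpositionResult) -> np.ndarray:
    return coords @ result.rotation.T + result.translation


def rmsd_series(
    traj: Trajectory,
    ref: np.ndarray | None = None,
    sel=None,
    superpose: bool = True,
) -> SeriesSummary:
    """Per-frame RMSD (Å) to a reference over a selection.

    The reference defaults to the first frame.  With ``superpose`` each
    frame is first least-squares fitted to the reference on the selection.
    """
    idx = _as_indices(sel)
    ref_sel = (traj.coords[0] if ref is None else np.asarray(ref, float))[idx]
    vals = np.empty(traj.n_frames)
    for t in range(traj.n_frames):
        mob = traj.coords[t][idx]
        if superpose:
            vals[t] = kabsch_superpose(mob, ref_sel).rmsd_min
        else:
            vals[t] = np.sqrt(((mob - ref_sel) ** 2).sum(axis=1).mean())
    return SeriesSummary(vals, traj.times.copy(), label="rmsd")


def radius_of_gyration(
    coords: np.ndarray, weights: np.ndarray | None = None
) -> float | np.ndarray:
    """Rg = sqrt(sum w_i |r_i - r_cm|^2 / sum w_i); vectorized over frames."""
    coords = np.asarray(coords, float)
    single = coords.ndim == 2
    c = coords[None] if single else coords
    n = c.shape[1]
    if n == 0:
        raise EmptySelectionError("empty selection")
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    com = np.einsum("j,tjk->tk", w, c)
    sq = ((c - com[:, None, :]) ** 2).sum(axis=2)
    rg = np.sqrt(np.einsum("j,tj->t", w, sq))
    return float(rg[0]) if single else rg


def rg_series(traj: Trajectory, sel=None, mass_weighted: bool = False) -> SeriesSummary:
    idx = _as_indices(sel)
    coords = traj.coords[:, idx, :]
    weights = None
    if mass_weighted:
        indices = range(traj.n_atoms) if isinstance(idx, slice) else idx
        weights = traj.topology.masses(indices)
    return SeriesSummary(
        radius_of_gyration(coords, weights), traj.times.copy(), label="rg"
    )


def _spiral_points(n: int) -> np.ndarray:
    """Deterministic golden-ratio spiral lattice on the unit sphere."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.column_stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)]
    )


def sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe: float = DEFAULT_PROBE,
    n_points: int = 960,
) -> tuple[np.ndarray, float]:
    """Shrake–Rupley solvent-accessible surface area of one frame (Å²).

    Each atom's solvent-expanded sphere (radius r_i + probe) is sampled at
    ``n_points`` spiral-lattice points; a point is accessible when it lies
    outside every neighbour's expanded sphere.  Returns (per-atom, total).
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if n_points < 32:
        raise ValueError("n_points < 32 is below the accuracy floor")
    if radii.min() <= 0:
        raise ValueError("radii must be positive")
    n = coords.shape[0]
    pts = _spiral_points(n_points)
    expanded = radii + probe
    per_atom = np.empty(n)
    # neighbour prefilter: atoms farther than r_i + r_j + 2*probe cannot bury
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    for i in range(n):
        sphere = coords[i] + expanded[i] * pts
        cut = (expanded[i] + expanded) ** 2
        nbrs = np.flatnonzero((d2[i] < cut) & (np.arange(n) != i))
        if len(nbrs) == 0:
            frac = 1.0
        else:
            dist2 = ((sphere[:, None, :] - coords[nbrs][None, :, :]) ** 2).sum(axis=2)
            buried = (dist2 < expanded[nbrs][None, :] ** 2).any(axis=1)
            frac = 1.0 - buried.mean()
        per_atom[i] = frac * 4.0 * np.pi * expanded[i] ** 2
    return per_atom, float(per_atom.sum())


def element_radii(traj: Trajectory, sel=None) -> np.ndarray:
    idx = _as_indices(sel)
    atoms = traj.topology.atoms
    which = range(len(atoms)) if isinstance(idx, slice) else idx
    return np.array(
        [VDW_RADII.get(atoms[i].element.upper(), _DEFAULT_RADIUS) for i in which]
    )


def sasa_series(
    traj: Trajectory, sel=None, probe: float = DEFAULT_PROBE, n_points: int = 960
) -> SeriesSummary:
    """Per-frame total SASA (Å²) over a selection."""
    idx = _as_indices(sel)
    radii = element_radii(traj, sel)
    vals = np.array(
        [sasa(traj.coords[t][idx], radii, probe, n_points)[1]
         for t in range(traj.n_frames)]
    )
    return SeriesSummary(vals, traj.times.copy(), label="sasa")


def superpose_trajectory(
    traj: Trajectory, sel=None, max_iter: int = 10, tol: float = 1e-8,
    superpose: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose every frame onto the iteratively converged mean structure.

    Returns (superposed T x n_sel x 3 coordinates, mean structure).  The
    mean is refined by alternating mean computation and re-fitting until it
    moves by less than ``tol`` (RMS), which removes rigid-body motion that
    would otherwise inflate fluctuation and correlation statistics.

    ``superpose=False`` skips the fit and trusts that frames already share
    a reference frame (e.g. synthetic ensembles generated without
    rigid-body motion); least-squares fitting to pure thermal noise absorbs
    a small part of the fluctuation, so pre-aligned data is best left alone.
    """
    idx = _as_indices(sel)
    coords = traj.coords[:, idx, :].copy()
    if coords.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not superpose:
        return coords, coords.mean(axis=0)
    ref = coords[0].copy()
    for _ in range(max_iter):
        for t in range(coords.shape[0]):
            coords[t] = apply_superposition(
                coords[t], kabsch_superpose(coords[t], ref)
            )
        mean = coords.mean(axis=0)
        shift = np.sqrt(((mean - ref) ** 2).sum(axis=1).mean())
        ref = mean
        if shift < tol:
            break
    return coords, ref


def rmsf(traj: Trajectory, sel=None, superpose: bool = True) -> np.ndarray:
    """Per-atom RMSF (Å) about the converged mean structure."""
    coords, mean = superpose_trajectory(traj, sel, superpose=superpose)
    return np.sqrt(((coords - mean[None]) ** 2).sum(axis=2).mean(axis=0))


def rmsf_to_bfactor(rmsf_values) -> np.ndarray:
    """Isotropic B-factor (Å²): B = (8 pi^2 / 3) RMSF^2."""
    r = np.asarray(rmsf_values, float)
    if np.any(r < 0):
        raise ValueError("RMSF must be non-negative")
    return BFACTOR_FACTOR * r**2
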