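"""Correlated-motion and essential-dynamics analysis.

Dynamic cross-correlation:  C_ij = <dr_i . dr_j> / sqrt(<dr_i^2><dr_j^2>)
with dr the displacement of atom i from its ensemble mean position, after
removal of rigid-body motion by superposition onto the converged mean.
+1 is perfectly correlated (in-phase) motion, -1 perfectly anticorrelated.

Essential dynamics: the 3N x 3N positional covariance of the superposed
C-alpha coordinates is diagonalised; eigenvalues (Å²) sort descending and
their sum (the trace) is the total positional variance.  Subspace overlap
between two ensembles is quantified by the root-mean-square inner product
(RMSIP) over the first n modes, and sampling convergence by the cosine
content of the principal projections (values near 1 indicate random
diffusion, i.e. unconverged sampling; the conventional acceptance level
is < 0.1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .descriptors import superpose_trajectory
from .trajio import Trajectory

__all__ = [
    "DCCM",
    "PCAResult",
    "dccm",
    "dccm_edges",
    "pca",
    "rmsip",
    "cosine_content",
    "porcupine",
    "mode_fluctuation",
    "COSINE_CONVERGENCE_LEVEL",
]

#: Cosine content below this indicates convergent sampling.
COSINE_CONVERGENCE_LEVEL = 0.1


@dataclass
class DCCM:
    """Residue-residue dynamic cross-correlation matrix in [-1, 1].

    Rows/columns of zero-variance atoms are NaN (undefined, not zero).
    """

    residue_ids: list
    c: np.ndarray


@dataclass
class PCAResult:
    mean_structure: np.ndarray   # N x 3, Å
    eigenvectors: np.ndarray     # 3N x M, orthonormal columns
    eigenvalues: np.ndarray      # M, Å², descending
    projections: np.ndarray      # T x M, Å
    trace: float                 # Å², sum over the full spectrum

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]


def dccm(traj: Trajectory, sel=None, superpose: bool = True) -> DCCM:
    """Dynamic cross-correlation matrix over a selection (default: all).

    Frames are superposed onto the converged mean before computing
    displacement covariances; pass ``superpose=False`` for ensembles
    already expressed in a common reference frame.
    """
    coords, mean = superpose_trajectory(traj, sel, superpose=superpose)
    dr = coords - mean[None]                       # T x N x 3
    cov = np.einsum("tik,tjk->ij", dr, dr) / dr.shape[0]
    var = np.diag(cov).copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        c = cov / np.sqrt(np.outer(var, var))
    # fluctuations below 1e-6 A are numerically indistinguishable from rigid
    dead = var <= 1e-12
    c[dead, :] = np.nan
    c[:, dead] = np.nan
    c = np.clip(c, -1.0, 1.0)  # NaN passes through

    atoms = traj.topology.atoms
    if sel is None:
        ids = [(a.chain_id, a.residue_seq) for a in atoms]
    else:
        ids = [(atoms[i].chain_id, atoms[i].residue_seq) for i in sel]
    return DCCM(ids, c)


def dccm_edges(d: DCCM, threshold: float) -> list[tuple[int, int, float]]:
    """Off-diagonal pairs with |c| >= threshold, sorted by |c| descending."""
    edges = []
    r = d.c.shape[0]
    for i in range(r):
        for j in range(i + 1, r):
            cij = d.c[i, j]
            if np.isfinite(cij) and abs(cij) >= threshold:
                edges.append((i, j, float(cij)))
    return sorted(edges, key=lambda e: -abs(e[2]))


def pca(traj: Trajectory, sel=None, superpose: bool = True) -> PCAResult:
    """Essential dynamics of the superposed coordinates.

    Diagonalises the 3N x 3N positional covariance; the eigenvector sign is
    fixed by making the largest-magnitude component positive so porcupine
    orientations are reproducible.  Projections are the centred coordinates
    on each mode (zero mean, variance = eigenvalue).
    """
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least 2 frames")
    coords, mean = superpose_trajectory(traj, sel, superpose=superpose)
    t, n, _ = coords.shape
    if t <= 3 * n:
        warnings.warn(
            f"only {t} frames for {3 * n} coordinates; covariance is rank-deficient",
            stacklevel=2,
        )
    x = coords.reshape(t, 3 * n) - mean.reshape(-1)[None]
    cov = x.T @ x / (t - 1)
    w, v = np.linalg.eigh(cov)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    # reproducible sign convention
    flip = v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])] < 0
    v[:, flip] *= -1.0
    return PCAResult(
        mean_structure=mean,
        eigenvectors=v,
        eigenvalues=w,
        projections=x @ v,
        trace=float(np.trace(cov)),
    )


def rmsip(a: PCAResult, b: PCAResult, n_modes: int = 10) -> float:
    """Root-mean-square inner product of the first ``n_modes`` subspaces.

    1 means identical essential subspaces, 0 orthogonal ones.
    """
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError("PCA results live in different dimensions")
    if n_modes > min(a.n_modes, b.n_modes):
        raise ValueError("n_modes exceeds the available modes")
    va = a.eigenvectors[:, :n_modes]
    vb = b.eigenvectors[:, :n_modes]
    return float(np.sqrt(((va.T @ vb) ** 2).sum() / n_modes))


def cosine_content(projection: np.ndarray, mode_index: int = 1) -> float:
    """Overlap of a principal projection with a half-period cosine.

    ``c_i = (2/T) (sum_t cos(i pi t / T) p(t))^2 / sum_t p(t)^2`` with t the
    frame index — the discrete form of Hess's sampling diagnostic.  Returns
    NaN for a zero-norm projection.
    """
    p = np.asarray(projection, float)
    t_len = len(p)
    if t_len < 4:
        raise ValueError("need at least 4 frames")
    if mode_index < 1:
        raise ValueError("mode_index is 1-based")
    denom = (p**2).sum()
    if denom == 0:
        return np.nan
    t = np.arange(t_len)
    num = (np.cos(mode_index * np.pi * t / t_len) * p).sum()
    return float(2.0 / t_len * num**2 / denom)


def is_convergent(cosine: float, level: float = COSINE_CONVERGENCE_LEVEL) -> bool:
    """Sampling-convergence verdict from the cosine content."""
    return bool(np.isfinite(cosine) and cosine < level)


def porcupine(
    p: PCAResult, mode: int = 0, scale: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom (base, tip) arrows for a mode: tip = base + scale * eigvec."""
    if not 0 <= mode < p.n_modes:
        raise ValueError("mode out of range")
    base = p.mean_structure
    tip = base + scale * p.eigenvectors[:, mode].reshape(-1, 3)
    return base, tip


def mode_fluctuation(p: PCAResult, mode: int = 0) -> np.ndarray:
    """Per-residue amplitude of a mode: |eigvec triple| * sqrt(eigenvalue).

    Squared amplitudes sum to the eigenvalue (eigenvector normalisation).
    """
    if not 0 <= mode < p.n_modes:
        raise ValueError("mode out of range")
    comp = p.eigenvectors[:, mode].reshape(-1, 3)
    lam = max(p.eigenvalues[mode], 0.0)
    return np.linalg.norm(comp, axis=1) * np.sqrt(lam)
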