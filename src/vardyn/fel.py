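"""Free-energy landscapes by Boltzmann inversion of a 2-D histogram.

The conformational ensemble is binned on a descriptor plane — by default
(RMSD, Rg), although any two per-frame series work, e.g. two principal
components — and the free energy of bin i is

    G_i = -k_B T ln(N_i / N_max)

so the most populated bin sits at G = 0 and empty bins are reported as
+inf (masked), never as a finite cap.  Energies are in units of kT by
default or kcal/mol on request (k_B T = 0.5961 kcal/mol at 300 K).

The representative ("lowest-energy") conformer is the frame inside the
global-minimum bin that lies nearest the bin centre in normalised bin
units, with ties broken by earliest time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from scipy.constants import Boltzmann, calorie, Avogadro

__all__ = [
    "FELGrid",
    "fel_surface",
    "lowest_energy_frame",
    "fel_3d_export",
    "KB_KCAL_PER_MOL_K",
]

#: Boltzmann constant in kcal/(mol K).
KB_KCAL_PER_MOL_K = Boltzmann * Avogadro / (1000.0 * calorie)


@dataclass
class FELGrid:
    x_edges: np.ndarray      # RMSD bin edges, Å
    y_edges: np.ndarray      # Rg bin edges, Å
    counts: np.ndarray       # Bx x By integer populations
    g: np.ndarray            # Bx x By free energies; empty bins +inf
    temperature_K: float
    units: str               # "kT" or "kcal/mol"


def _padded_edges(v: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = float(v.min()), float(v.max())
    span = hi - lo
    if span == 0.0:
        # constant descriptor: a nominal half-angstrom window keeps the
        # single occupied bin well defined
        pad = 0.5
    else:
        pad = 0.01 * span
    return np.linspace(lo - pad, hi + pad, bins + 1)


def fel_surface(
    rmsd: np.ndarray,
    rg: np.ndarray,
    bins: int = 100,
    temperature_K: float = 300.0,
    units: str = "kT",
) -> FELGrid:
    """Boltzmann-inverted free-energy surface over a descriptor plane.

    Bin ranges are data-driven with 1% padding.  ``units='kcal/mol'``
    multiplies by k_B T (0.5961 kcal/mol at 300 K).
    """
    x = np.asarray(rmsd, float)
    y = np.asarray(rg, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("rmsd and rg must be equal-length 1-D series")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("descriptor series must be finite")
    if units not in ("kT", "kcal/mol"):
        raise ValueError("units must be 'kT' or 'kcal/mol'")
    if temperature_K <= 0:
        raise ValueError("temperature must be positive")

    x_edges = _padded_edges(x, bins)
    y_edges = _padded_edges(y, bins)
    counts, _, _ = np.histogram2d(x, y, bins=(x_edges, y_edges))
    counts = counts.astype(int)
    n_max = counts.max()
    with np.errstate(divide="ignore"):
        g = -np.log(counts / n_max)
    g[g == 0] = 0.0  # normalise -0.0 from the modal bin
    g[counts == 0] = np.inf
    if units == "kcal/mol":
        g = g * KB_KCAL_PER_MOL_K * temperature_K
    return FELGrid(x_edges, y_edges, counts, g, temperature_K, units)


def lowest_energy_frame(
    grid: FELGrid,
    rmsd: np.ndarray,
    rg: np.ndarray,
    times: np.ndarray | None = None,
) -> tuple[int, float]:
    """Representative conformer from the global-minimum (modal) bin.

    Among the frames falling in the most populated bin, returns the frame
    whose (rmsd, rg) lies nearest the bin centre in normalised bin units;
    ties break toward the earliest time.  Returns (frame_index, time_ns).
    """
    x = np.asarray(rmsd, float)
    y = np.asarray(rg, float)
    t = np.arange(len(x), dtype=float) if times is None else np.asarray(times, float)
    if grid.counts.sum() != len(x):
        raise ValueError("grid was not built from these series")
    if grid.counts.max() == 0:
        raise ValueError("empty grid")
    bi, bj = np.unravel_index(np.argmax(grid.counts), grid.counts.shape)
    ix = np.clip(np.searchsorted(grid.x_edges, x, side="right") - 1, 0,
                 len(grid.x_edges) - 2)
    iy = np.clip(np.searchsorted(grid.y_edges, y, side="right") - 1, 0,
                 len(grid.y_edges) - 2)
    members = np.flatnonzero((ix == bi) & (iy == bj))
    cx = 0.5 * (grid.x_edges[bi] + grid.x_edges[bi + 1])
    cy = 0.5 * (grid.y_edges[bj] + grid.y_edges[bj + 1])
    wx = grid.x_edges[bi + 1] - grid.x_edges[bi]
    wy = grid.y_edges[bj + 1] - grid.y_edges[bj]
    dist = np.hypot((x[members] - cx) / wx, (y[members] - cy) / wy)
    order = np.lexsort((t[members], np.round(dist, 12)))
    best = members[order[0]]
    return int(best), float(t[best])


def fel_3d_export(grid: FELGrid) -> pd.DataFrame:
    """Long-form (x, y, g) table of occupied bins, sorted by g ascending."""
    xc = 0.5 * (grid.x_edges[:-1] + grid.x_edges[1:])
    yc = 0.5 * (grid.y_edges[:-1] + grid.y_edges[1:])
    ii, jj = np.nonzero(grid.counts)
    df = pd.DataFrame({
        "x": xc[ii], "y": yc[jj],
        "g": grid.g[ii, jj], "count": grid.counts[ii, jj],
    })
    return df.sort_values("g", kind="stable").reset_index(drop=True)
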