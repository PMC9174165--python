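"""End-to-end orchestration of the variant-trajectory analysis workflow.

Given, per variant, a set of replica trajectories, the pipeline trims the
pre-equilibration portion of each replica (default: keep the final 60%,
e.g. the last 300 ns of a 500 ns run), concatenates replicas into one
sub-trajectory, and runs every analysis stage: RMSD/Rg/SASA series,
RMSF and B-factors, DCCM, PCA with per-replica cosine contents,
pairwise RMSIP across variants, secondary-structure occupancy,
anchor distances, filtered contact maps and the (RMSD, Rg) free-energy
landscape with a representative conformer.  Outputs are CSV tables plus a
JSON summary, and a manifest (config hash, seeds, package version) that
suffices to re-run the deterministic stages bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import descriptors, dynamics, fel, loopgeom, secstruct, trajio
from .loopgeom import RegionSet

__all__ = ["RunConfig", "RunReport", "run_full_analysis", "compare_variants"]

log = logging.getLogger("vardyn.pipeline")


@dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis run."""

    variants: dict[str, list[str]]          # variant name -> replica PDB paths
    wildtype: str = "WT"
    output_dir: str = "vardyn_out"
    equilibration_keep_fraction: float = 0.6  # keep the final fraction per replica
    dt_ns: float = trajio.DEFAULT_DT_NS
    regions: RegionSet = field(default_factory=RegionSet)
    contact_cutoff: float = loopgeom.DEFAULT_CONTACT_CUTOFF
    min_contact_occupancy: float = loopgeom.DEFAULT_MIN_OCCUPANCY
    fel_bins: int = 100
    temperature_K: float = 300.0
    rmsip_modes: tuple[int, ...] = (10, 3)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError("no variants configured")
        for name, reps in self.variants.items():
            if not reps:
                raise ValueError(f"variant {name} has no replicas")
        if not 0.0 < self.equilibration_keep_fraction <= 1.0:
            raise ValueError("equilibration_keep_fraction must be in (0, 1]")
        if self.wildtype not in self.variants:
            raise ValueError(f"wildtype {self.wildtype!r} not among variants")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "regions" in raw or "anchors" in raw:
            raw["regions"] = RegionSet.from_dict(
                {"regions": raw.pop("regions", None) or loopgeom._DEFAULT_REGIONS,
                 "anchors": raw.pop("anchors", None) or loopgeom._DEFAULT_ANCHORS}
            )
        if "rmsip_modes" in raw:
            raw["rmsip_modes"] = tuple(raw["rmsip_modes"])
        return cls(**raw)

    def digest(self) -> str:
        def default(o):
            if isinstance(o, RegionSet):
                return {"regions": o.regions, "anchors": o.anchors}
            return str(o)
        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Per-variant summaries plus cross-variant comparisons and a manifest."""

    summaries: dict[str, dict]            # variant -> scalar summaries
    rmsip: pd.DataFrame                   # variant x variant (first mode set)
    cosine: pd.DataFrame                  # variant/replica cosine contents
    files: dict[str, list[str]]           # variant -> written artifact paths
    manifest: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, variant: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed for variant {variant!r}: {cause}")
        self.stage = stage
        self.variant = variant


def _trim_and_concat(cfg: RunConfig, paths: list[str]) -> tuple[trajio.Trajectory, list[trajio.Trajectory]]:
    replicas = []
    for p in paths:
        t = trajio.read_multi_model_pdb(p, dt_ns=cfg.dt_ns)
        if t.n_frames > 1:
            span = t.times[-1] - t.times[0]
            t_start = t.times[-1] - cfg.equilibration_keep_fraction * span
            t = trajio.slice_time(t, t_start, t.times[-1])
        replicas.append(t)
    return trajio.concat(replicas), replicas


def _analyze_variant(cfg: RunConfig, name: str, paths: list[str], outdir: Path):
    vdir = outdir / name
    vdir.mkdir(parents=True, exist_ok=True)
    written: list[str] = []

    def save_csv(df: pd.DataFrame, fname: str) -> None:
        p = vdir / fname
        df.to_csv(p, index=False)
        written.append(str(p))

    stage = "trajio.concat"
    try:
        traj, replicas = _trim_and_concat(cfg, paths)
    except Exception as exc:
        raise StageError(stage, name, exc) from exc

    summary: dict = {"n_frames": traj.n_frames}
    try:
        stage = "descriptors"
        try:
            bb = trajio.select(traj, "backbone")
        except trajio.EmptySelectionError:
            bb = None
        try:
            ca = trajio.select(traj, "name CA")
        except trajio.EmptySelectionError:
            ca = None
        rmsd = descriptors.rmsd_series(traj, sel=bb)
        rg = descriptors.rg_series(traj, sel=bb)
        sasa = descriptors.sasa_series(traj, sel=bb, n_points=96)
        save_csv(pd.DataFrame({"time_ns": traj.times, "rmsd_A": rmsd.values,
                               "rg_A": rg.values, "sasa_A2": sasa.values}),
                 "series.csv")
        summary["rmsd_mean_A"] = rmsd.mean
        summary["rg_mean_A"] = rg.mean
        summary["sasa_mean_A2"] = sasa.mean

        stage = "rmsf"
        sel_rmsf = ca if ca is not None else bb
        rmsf_vals = descriptors.rmsf(traj, sel_rmsf)
        bfac = descriptors.rmsf_to_bfactor(rmsf_vals)
        resids = [traj.topology.atoms[i].residue_seq for i in sel_rmsf] \
            if sel_rmsf is not None else list(range(traj.n_atoms))
        save_csv(pd.DataFrame({"resid": resids, "rmsf_A": rmsf_vals,
                               "bfactor_A2": bfac}), "rmsf.csv")
        summary["rmsf_mean_A"] = float(rmsf_vals.mean())

        stage = "dynamics"
        d = dynamics.dccm(traj, ca)
        save_csv(pd.DataFrame(d.c), "dccm.csv")
        p = dynamics.pca(traj, ca)
        summary["pca_trace_A2"] = p.trace
        save_csv(pd.DataFrame({"eigenvalue_A2": p.eigenvalues}), "eigenvalues.csv")
        cosines = []
        for k, rep in enumerate(replicas):
            if rep.n_frames < 4:
                continue
            rp = dynamics.pca(rep, ca)
            for m in range(min(3, rp.n_modes)):
                c = dynamics.cosine_content(rp.projections[:, m], m + 1)
                conv = dynamics.is_convergent(c)
                if not conv:
                    log.warning("variant %s replica %d PC%d cosine content "
                                "%.3f >= 0.1 (sampling may be unconverged)",
                                name, k, m + 1, c)
                cosines.append({"variant": name, "replica": k, "mode": m + 1,
                                "cosine_content": c, "convergent": conv})

        stage = "secstruct"
        has_backbone = bb is not None and ca is not None and len(bb) >= 4 * 4
        per_region = None
        if has_backbone:
            tl = secstruct.assign_timeline(traj)
            per_res, per_region = secstruct.occupancy(tl, cfg.regions.regions)
            save_csv(per_res, "ss_occupancy.csv")
            if per_region is not None:
                save_csv(per_region, "ss_region_occupancy.csv")

        stage = "loopgeom"
        region_names = list(cfg.regions.regions)
        for a_i in range(len(region_names)):
            for b_i in range(a_i + 1, len(region_names)):
                ra, rb = region_names[a_i], region_names[b_i]
                try:
                    ds = loopgeom.anchor_distance_series(
                        traj, cfg.regions.anchors[ra], cfg.regions.anchors[rb])
                except ValueError:
                    continue
                summary[f"dist_{ra}_{rb}_mean_A"] = ds.mean
                cmap = loopgeom.contact_occupancy(
                    traj, cfg.regions.regions[ra], cfg.regions.regions[rb],
                    cutoff=cfg.contact_cutoff, names=(ra, rb))
                kept = loopgeom.filter_contacts(cmap, cfg.min_contact_occupancy)
                save_csv(kept.pairs.assign(region_a=ra, region_b=rb),
                         f"contacts_{ra}_{rb}.csv")

        stage = "fel"
        bins = min(cfg.fel_bins, max(2, int(np.sqrt(traj.n_frames))))
        grid = fel.fel_surface(rmsd.values, rg.values, bins=bins,
                               temperature_K=cfg.temperature_K)
        frame_idx, t_ns = fel.lowest_energy_frame(grid, rmsd.values, rg.values,
                                                  traj.times)
        summary["fel_min_frame"] = frame_idx
        summary["fel_min_time_ns"] = t_ns
        save_csv(fel.fel_3d_export(grid), "fel.csv")
        rep_path = vdir / "representative.pdb"
        trajio.write_multi_model_pdb(
            trajio.Trajectory(traj.topology, traj.coords[[frame_idx]],
                              np.array([traj.times[frame_idx]])),
            rep_path)
        written.append(str(rep_path))
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, name, exc) from exc

    return traj, p, summary, cosines, written


def run_full_analysis(cfg: RunConfig) -> RunReport:
    """Run every stage for every variant and write a machine-readable report."""
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    summaries, pcas, cosines, files = {}, {}, [], {}
    for name, paths in cfg.variants.items():
        log.info("analyzing variant %s (%d replicas)", name, len(paths))
        _, p, summary, cos, written = _analyze_variant(cfg, name, paths, outdir)
        summaries[name] = summary
        pcas[name] = p
        cosines.extend(cos)
        files[name] = written

    names = list(cfg.variants)
    n_modes = min(cfg.rmsip_modes[0], *(pcas[n].n_modes for n in names))
    rmsip_mat = pd.DataFrame(
        [[dynamics.rmsip(pcas[a], pcas[b], n_modes) for b in names] for a in names],
        index=names, columns=names,
    )
    cosine_df = pd.DataFrame(cosines) if cosines else pd.DataFrame(
        columns=["variant", "replica", "mode", "cosine_content", "convergent"])

    manifest = {
        "config_hash": cfg.digest(),
        "vardyn_version": __version__,
        "numpy_version": np.__version__,
        "seed": cfg.seed,
        "rmsip_n_modes": int(n_modes),
    }
    report = RunReport(summaries, rmsip_mat, cosine_df, files, manifest)

    rmsip_mat.to_csv(outdir / "rmsip.csv")
    cosine_df.to_csv(outdir / "cosine_content.csv", index=False)
    with open(outdir / "report.json", "w") as fh:
        json.dump({"summaries": summaries, "manifest": manifest,
                   "deltas": compare_variants(report, cfg.wildtype).to_dict("records")},
                  fh, indent=2, default=float)
    return report


def compare_variants(report: RunReport, wildtype: str = "WT") -> pd.DataFrame:
    """Per-metric (variant - wildtype) deltas for every scalar summary."""
    if wildtype not in report.summaries:
        raise ValueError(f"no wildtype {wildtype!r} in report")
    base = report.summaries[wildtype]
    rows = []
    for name, summ in report.summaries.items():
        if name == wildtype:
            continue
        for metric, value in summ.items():
            if metric in base and isinstance(value, (int, float)):
                rows.append({"variant": name, "metric": metric,
                             "delta": float(value) - float(base[metric])})
    return pd.DataFrame(rows, columns=["variant", "metric", "delta"])
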