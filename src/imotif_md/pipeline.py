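"""Orchestrate the full analysis chain from one configuration.

One :class:`AnalysisConfig` names the input files, the group definitions
and every threshold; :func:`run_full_analysis` runs the configured stages
(pair energies, contact clustering, hydrogen-bond occupancy, RMSD, SASA,
pulling work) and assembles a flat, stable-ordered, machine-readable text
report.  Any stage failure aborts with the stage name; re-running the
same configuration on the same files is bit-identical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import __version__
from .core import Selection, Trajectory, select
from .contacts import (DEFAULT_CONTACT_CUTOFF, DEFAULT_EXCLUDED_CLASSES,
                       cluster_timeseries)
from .energetics import DEFAULT_CUTOFF, pair_energy_series
from .hbonds import (filter_significant, occupancy, per_ligand_count,
                     union_tables)
from .io_formats import read_fftop, read_pulling_trace, read_trajectory
from .pulling import (DEFAULT_FLATNESS, DEFAULT_MIN_LEN, PullingTrace,
                      accumulated_work, binding_energy_estimate,
                      detect_plateaus)
from .structure import rmsd_series, sasa_series

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class AnalysisConfig:
    """Paths, group definitions and thresholds for one full analysis."""

    topology: Optional[str] = None
    trajectory: Optional[str] = None
    trajectory_format: str = "lammps_dump"
    timestep_fs: float = 1.8
    window_ns: Optional[float] = 10.8
    energy_pairs: List[Tuple[str, str]] = field(
        default_factory=lambda: [("class:iM", "class:DOX")])
    energy_cutoff: float = DEFAULT_CUTOFF
    cluster_cutoff: float = DEFAULT_CONTACT_CUTOFF
    cluster_exclude: Tuple[str, ...] = tuple(sorted(DEFAULT_EXCLUDED_CLASSES))
    hbond_donors: str = "class:iM"
    hbond_acceptors: str = "class:DOX"
    hbond_d_max: float = 3.0
    hbond_angle_max: float = 20.0
    hbond_min_occupancy: float = 0.10
    n_ligands: Optional[int] = None
    rmsd_styles: Tuple[str, ...] = ("all", "exclude-DOX")
    sasa_selection: str = "class:DOX"
    sasa_probe: float = 1.4
    sasa_points: int = 960
    pulling_traces: List[dict] = field(default_factory=list)
    plateau_min_len: float = DEFAULT_MIN_LEN
    plateau_flatness: float = DEFAULT_FLATNESS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "energy_pairs" in raw:
            raw["energy_pairs"] = [tuple(p) for p in raw["energy_pairs"]]
        for key in ("cluster_exclude", "rmsd_styles"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        for name in ("energy_cutoff", "cluster_cutoff", "hbond_d_max",
                     "hbond_angle_max", "sasa_probe", "plateau_min_len",
                     "plateau_flatness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _nonempty(traj: Trajectory, predicate: str) -> Optional[Selection]:
    sel = select(traj.topology, predicate)
    return sel if len(sel) else None


def run_full_analysis(config: AnalysisConfig) -> Dict:
    """Run every configured stage; return the report as a nested dict.

    Stages whose selections resolve to no atoms (e.g. ligand analyses on
    a ligand-free system) are omitted from the report rather than failing.
    """
    config.validate()
    report: Dict = {
        "version": __version__,
        "seed": config.seed,
        "window_ns": config.window_ns,
        "thresholds": {
            "energy_cutoff": config.energy_cutoff,
            "cluster_cutoff": config.cluster_cutoff,
            "hbond_d_max": config.hbond_d_max,
            "hbond_angle_max": config.hbond_angle_max,
            "hbond_min_occupancy": config.hbond_min_occupancy,
        },
    }

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return deco

    if config.trajectory is None:
        traj = None
    else:
        if config.topology is None:
            raise PipelineError(
                "stage 'read_topology' failed: no topology configured")

        @stage("read_topology")
        def topo():
            return read_fftop(config.topology)

        @stage("read_trajectory")
        def traj():
            t = read_trajectory(config.trajectory, topo,
                                format=config.trajectory_format,
                                timestep_fs=config.timestep_fs)
            if len(t) == 0:
                raise ValueError(f"{config.trajectory}: no frames")
            return t

    if traj is not None:
        window_frames = (traj.frames if config.window_ns is None
                         else traj.trailing_window(config.window_ns))

        @stage("energies")
        def _():
            rows = []
            for pred_a, pred_b in config.energy_pairs:
                sa = _nonempty(traj, pred_a)
                sb = _nonempty(traj, pred_b)
                if sa is None or sb is None:
                    logger.info("energy pair (%s, %s) skipped: empty group",
                                pred_a, pred_b)
                    continue
                series = pair_energy_series(traj, sa, sb,
                                            cutoff=config.energy_cutoff,
                                            frames=window_frames)
                lj, co, tot = series.means()
                rows.append({"pair": f"{pred_a}|{pred_b}", "lj": lj,
                             "coulomb": co, "total": tot})
            report["energies"] = rows

        @stage("clusters")
        def _():
            _, summary = cluster_timeseries(
                traj, cutoff=config.cluster_cutoff,
                exclude_classes=config.cluster_exclude,
                window_ns=config.window_ns)
            report["clusters"] = {
                "counts": summary.counts.tolist(),
                "min": summary.min_count, "max": summary.max_count,
                "mode": summary.modal_count,
                "terminal": summary.terminal_count,
            }

        @stage("hbonds")
        def _():
            donors = _nonempty(traj, config.hbond_donors)
            acceptors = _nonempty(traj, config.hbond_acceptors)
            if donors is None or acceptors is None:
                logger.info("hbond stage skipped: empty donor/acceptor group")
                return
            fwd = occupancy(traj, donors, acceptors,
                            window_ns=config.window_ns,
                            d_max=config.hbond_d_max,
                            angle_max=config.hbond_angle_max)
            rev = occupancy(traj, acceptors, donors,
                            window_ns=config.window_ns,
                            d_max=config.hbond_d_max,
                            angle_max=config.hbond_angle_max)
            table = union_tables(fwd, rev)
            significant = filter_significant(table,
                                             config.hbond_min_occupancy)
            if config.n_ligands is not None:
                n_lig = config.n_ligands
            else:
                mids = traj.topology.molecule_ids
                classes = traj.topology.molecule_classes
                n_lig = len(np.unique(mids[classes == "DOX"]))
            report["hbonds"] = {
                "occupancy": [
                    {"donor": k.donor_id, "hydrogen": k.hydrogen_id,
                     "acceptor": k.acceptor_id, "occupancy": v}
                    for k, v in table.sorted_items()
                ],
                "total_bonds": table.total_bonds,
                "significant_bonds": significant.total_bonds,
                "n_ligands": n_lig,
                "per_ligand_total": (per_ligand_count(table.total_bonds,
                                                      n_lig)
                                     if n_lig >= 1 else None),
                "per_ligand_significant": (
                    per_ligand_count(significant.total_bonds, n_lig)
                    if n_lig >= 1 else None),
            }

        @stage("rmsd")
        def _():
            out = {}
            for style in config.rmsd_styles:
                series = rmsd_series(traj, style=style,
                                     window_ns=config.window_ns)
                out[style] = {"times": series.times.tolist(),
                              "rmsd": series.rmsd.tolist()}
            report["rmsd"] = out

        @stage("sasa")
        def _():
            sel = _nonempty(traj, config.sasa_selection)
            if sel is None:
                logger.info("SASA stage skipped: empty selection")
                return
            res = sasa_series(traj, sel, probe=config.sasa_probe,
                              n_points=config.sasa_points,
                              window_ns=config.window_ns)
            report["sasa"] = {"mean": res.mean,
                              "per_frame": res.area.tolist(),
                              "probe": res.probe_radius,
                              "n_points": res.n_points}

    if config.pulling_traces:
        @stage("pulling")
        def _():
            rows = []
            curves = []
            for entry in config.pulling_traces:
                raw = read_pulling_trace(entry["trace"])
                trace = PullingTrace(time=raw.time, xi=raw.xi,
                                     center=raw.center,
                                     spring_k=float(entry["spring_k"]),
                                     velocity=raw.velocity)
                curve = accumulated_work(trace)
                est = detect_plateaus(curve,
                                      min_len=config.plateau_min_len,
                                      flatness=config.plateau_flatness)
                curves.append(curve)
                rows.append({
                    "trace": str(entry["trace"]),
                    "velocity": trace.velocity,
                    "final_work": float(curve.work[-1]),
                    "plateaus": est.intervals,
                    "jumps": est.jumps,
                })
            binding = binding_energy_estimate(
                curves, min_len=config.plateau_min_len,
                flatness=config.plateau_flatness)
            report["pulling"] = {
                "traces": rows,
                "binding_levels": binding.levels,
                "binding_range": list(binding.range),
            }

    return report


def report_to_text(report: Dict) -> str:
    """Flat key-value + table rendering, stable-ordered for diffing."""
    lines = ["# imotif-analyze report"]

    def emit(prefix: str, value) -> None:
        if isinstance(value, dict):
            for k in value:
                emit(f"{prefix}.{k}" if prefix else str(k), value[k])
        elif isinstance(value, list) and value \
                and isinstance(value[0], dict):
            cols = list(value[0])
            lines.append(f"## {prefix}")
            lines.append("\t".join(cols))
            for row in value:
                lines.append("\t".join(_fmt(row.get(c)) for c in cols))
        else:
            lines.append(f"{prefix}\t{_fmt(value)}")

    for key in report:
        emit(key, report[key])
    return "\n".join(lines) + "\n"


def _fmt(v) -> str:
    if isinstance(v, float):
        return f"{v:.6g}"
    if isinstance(v, (list, tuple)):
        return ",".join(_fmt(x) for x in v)
    return str(v)
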