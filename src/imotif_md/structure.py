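"""Structural metrics: superposition RMSD and Shrake-Rupley SASA.

RMSD follows the usual superposition convention: subtract the (mass-
weighted) centres of mass, find the optimal proper rotation onto the
reference (Kabsch, reflections corrected), and report the minimal
mass-weighted RMSD.  Three selection styles mirror how mixed
CNT/DNA/ligand systems are usually dissected: all atoms, everything except
the ligand (DOX), and the CNT+ligand subsystem only.

SASA uses Shrake-Rupley sampling: quasi-uniform points on each atom's
probe-expanded sphere; a point is accessible when it lies outside every
other expanded sphere.  Water and ions never occlude (the quantity of
interest is exposure to the solvent).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import Frame, Selection, Topology, Trajectory, select

RMSD_STYLES = ("all", "exclude-DOX", "cnt-dox")
SASA_NON_OCCLUDING = ("WATER", "ION")


@dataclass
class RMSDSeries:
    times: np.ndarray
    rmsd: np.ndarray
    style: str


@dataclass
class SASAResult:
    """Per-frame solvent-accessible surface area (Å²)."""

    times: np.ndarray
    area: np.ndarray
    probe_radius: float
    n_points: int

    @property
    def mean(self) -> float:
        return float(self.area.mean())


def kabsch_align(mobile: np.ndarray, reference: np.ndarray,
                 weights: Optional[np.ndarray] = None,
                 ) -> "tuple[np.ndarray, float]":
    """Optimal superposition of ``mobile`` onto ``reference``.

    Returns the proper rotation matrix (applied to COM-centred mobile
    coordinates) and the minimal weighted RMSD in Å.  Weights are masses
    by convention; ``None`` means unweighted.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("coordinate sets must both have shape (n, 3)")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    wn = w / w.sum()

    Pc = P - (wn[:, None] * P).sum(axis=0)
    Qc = Q - (wn[:, None] * Q).sum(axis=0)
    # collinear reference -> rotation about the line is undefined
    if np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise ValueError("reference atoms are collinear; rotation undefined")

    H = (wn[:, None] * Pc).T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T

    diff = Pc @ R.T - Qc
    rmsd = float(np.sqrt(np.sum(wn[:, None] * diff ** 2)))
    return R, rmsd


def _style_selection(topology: Topology, style: str) -> Selection:
    if style == "all":
        return select(topology, "all")
    if style == "exclude-DOX":
        return select(topology, "~class:DOX")
    if style == "cnt-dox":
        return select(topology, "class:CNT,Gu,DOX")
    raise ValueError(
        f"unknown RMSD style {style!r}; valid: {', '.join(RMSD_STYLES)} "
        "or pass a Selection"
    )


def rmsd_series(traj: Trajectory,
                style: "str | Selection" = "all",
                window_ns: Optional[float] = None,
                mass_weighted: bool = True) -> RMSDSeries:
    """Per-frame minimal RMSD against the first frame of the window.

    ``style`` is one of the named presets (``all``, ``exclude-DOX``,
    ``cnt-dox``) or an explicit Selection.  The reference is the first
    frame of the analysis window, so the series starts at exactly zero.
    """
    sel = style if isinstance(style, Selection) else _style_selection(
        traj.topology, style)
    if len(sel) == 0:
        raise ValueError(f"style {getattr(sel, 'label', style)!r} selects no atoms")
    frames = (traj.frames if window_ns is None
              else traj.trailing_window(window_ns))
    weights = traj.topology.masses()[sel.indices] if mass_weighted else None
    ref = frames[0].positions[sel.indices]
    out = np.empty(len(frames))
    for k, f in enumerate(frames):
        _, out[k] = kabsch_align(f.positions[sel.indices], ref,
                                 weights=weights)
    label = sel.label if isinstance(style, Selection) else style
    return RMSDSeries(times=np.array([f.time for f in frames]),
                      rmsd=out, style=label)


# ---------------------------------------------------------------------------
# SASA
# ---------------------------------------------------------------------------

def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic quasi-uniform unit vectors (golden-spiral lattice)."""
    k = np.arange(n_points)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * k
    z = 1.0 - (2.0 * k + 1.0) / n_points
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def shrake_rupley_sasa(frame: Frame, topology: Topology, sel: Selection,
                       probe: float = 1.4, n_points: int = 960,
                       per_atom: bool = False) -> "float | np.ndarray":
    """Solvent-accessible surface area (Å²) of a selection.

    Occluders are all non-water, non-ion atoms (selected or not) other
    than the atom under test.  Distances use the minimum-image convention.
    """
    if len(sel) == 0:
        raise ValueError("SASA of an empty selection")
    radii = topology.radii
    for i in sel.indices:
        if not np.isfinite(radii[i]) or radii[i] <= 0:
            raise ValueError(
                f"atom {topology.atoms[i].atom_id} has no usable radius"
            )
    classes = topology.molecule_classes
    occluder_mask = ~np.isin(classes, SASA_NON_OCCLUDING)
    occ_idx = np.flatnonzero(occluder_mask)
    occ_pos = frame.positions[occ_idx]
    occ_rad = radii[occ_idx] + probe

    unit = fibonacci_sphere(n_points)
    areas = np.empty(len(sel.indices))
    box = frame.box
    for k, i in enumerate(sel.indices):
        ri = radii[i] + probe
        centre = frame.positions[i]
        # occluders within reach of atom i's expanded sphere
        d = occ_pos - centre
        d -= box * np.floor(d / box + 0.5)
        dist = np.linalg.norm(d, axis=1)
        near = (dist < ri + occ_rad) & (occ_idx != i)
        if not near.any():
            areas[k] = 4.0 * np.pi * ri ** 2
            continue
        pts = centre + ri * unit  # (P, 3)
        dp = pts[:, None, :] - (centre + d[near])[None, :, :]
        # occluder images already minimal relative to centre; points lie
        # within ri of centre so no further wrap is needed for ri << L/2
        r2 = np.einsum("pjk,pjk->pj", dp, dp)
        buried = (r2 < (occ_rad[near] ** 2)[None, :]).any(axis=1)
        frac = 1.0 - buried.mean()
        areas[k] = 4.0 * np.pi * ri ** 2 * frac
    return areas if per_atom else float(areas.sum())


def sasa_series(traj: Trajectory, sel: Selection, probe: float = 1.4,
                n_points: int = 960,
                window_ns: Optional[float] = None) -> SASAResult:
    frames = (traj.frames if window_ns is None
              else traj.trailing_window(window_ns))
    area = np.array([
        shrake_rupley_sasa(f, traj.topology, sel, probe=probe,
                           n_points=n_points)
        for f in frames
    ])
    return SASAResult(times=np.array([f.time for f in frames]), area=area,
                      probe_radius=probe, n_points=n_points)
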