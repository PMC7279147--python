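"""Hydrogen-bond detection, occupancy tracking and reporting filters.

A hydrogen bond is a (donor, hydrogen, acceptor) triple: the donor heavy
atom carries a covalently bonded polar hydrogen, and the geometric
criteria are a donor-acceptor heavy-atom distance below 3 Å together with
a D-H···A angle within 20° of linearity (∠DHA > 160°).  The angle vertex
is not universal in the literature, so the alternative H-D-A convention
(∠HDA <= 20°) is available behind a flag.

Occupancy of a bond is the fraction of analysed frames in which its
geometry is satisfied.  Reporting conventions: bonds with occupancy above
10% are considered significant, and for systems with several identical
ligands the total bond count is normalised per ligand (e.g. divided by
four for a four-ligand system).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, NamedTuple, Optional, Set

import numpy as np

from .core import Frame, Selection, Topology, Trajectory, min_image_displacement

logger = logging.getLogger(__name__)

DEFAULT_DISTANCE_MAX = 3.0
DEFAULT_ANGLE_MAX = 20.0


class HBondKey(NamedTuple):
    """Identity of a hydrogen bond: 1-based donor, hydrogen, acceptor ids.

    The same donor-acceptor pair through a different hydrogen is a
    different bond.
    """

    donor_id: int
    hydrogen_id: int
    acceptor_id: int


@dataclass
class OccupancyTable:
    """Bond -> fraction of frames present, sorted by descending occupancy."""

    occupancy: Dict[HBondKey, float]
    n_frames: int

    @property
    def total_bonds(self) -> int:
        return len(self.occupancy)

    def sorted_items(self) -> "List[tuple[HBondKey, float]]":
        return sorted(self.occupancy.items(),
                      key=lambda kv: (-kv[1], kv[0]))


def detect_hbonds(frame: Frame, topology: Topology, donors: Selection,
                  acceptors: Selection,
                  d_max: float = DEFAULT_DISTANCE_MAX,
                  angle_max: float = DEFAULT_ANGLE_MAX,
                  angle_convention: str = "dha") -> Set[HBondKey]:
    """Hydrogen bonds present in one frame.

    ``donors`` / ``acceptors`` restrict which flagged atoms are considered
    on each side.  ``angle_convention`` is ``"dha"`` (deviation of the
    D-H···A angle from linearity < angle_max) or ``"hda"`` (the H-D-A
    angle itself <= angle_max).  Donors without a bonded polar hydrogen
    are skipped with a warning.
    """
    if angle_convention not in ("dha", "hda"):
        raise ValueError("angle_convention must be 'dha' or 'hda'")
    donor_idx = [i for i in donors.indices if topology.atoms[i].is_donor]
    acc_idx = [i for i in acceptors.indices
               if topology.atoms[i].is_acceptor]
    if not donor_idx or not acc_idx:
        return set()
    box = frame.box
    acc_pos = frame.positions[acc_idx]
    acc_ids = [topology.atoms[i].atom_id for i in acc_idx]

    found: Set[HBondKey] = set()
    for di in donor_idx:
        drec = topology.atoms[di]
        h_ids = topology.bonded_polar_hydrogens(drec.atom_id)
        if not h_ids:
            logger.warning("donor atom %d has no bonded polar hydrogen; "
                           "skipped", drec.atom_id)
            continue
        dpos = frame.positions[di]
        # distance gate: donor heavy atom to acceptor heavy atom
        dvec = acc_pos - dpos
        dvec -= box * np.floor(dvec / box + 0.5)
        dist = np.linalg.norm(dvec, axis=1)
        close = np.flatnonzero(dist < d_max)
        for k in close:
            ai = acc_idx[k]
            if ai == di:
                continue
            for hid in h_ids:
                hpos = frame.positions[topology.index_of(hid)]
                if angle_convention == "dha":
                    v1 = min_image_displacement(hpos, dpos, box)
                    v2 = min_image_displacement(hpos, frame.positions[ai],
                                                box)
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2))
                    theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    ok = (180.0 - theta) < angle_max
                else:
                    v1 = min_image_displacement(dpos, hpos, box)
                    v2 = dvec[k]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2))
                    theta = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    ok = theta <= angle_max
                if ok:
                    found.add(HBondKey(drec.atom_id, hid, acc_ids[k]))
    return found


def occupancy(traj: Trajectory, donors: Selection, acceptors: Selection,
              window_ns: Optional[float] = None,
              d_max: float = DEFAULT_DISTANCE_MAX,
              angle_max: float = DEFAULT_ANGLE_MAX,
              angle_convention: str = "dha") -> OccupancyTable:
    """Per-bond presence fraction over the analysis window."""
    frames = (traj.frames if window_ns is None
              else traj.trailing_window(window_ns))
    if not frames:
        raise ValueError("empty analysis window")
    counts: Dict[HBondKey, int] = {}
    for f in frames:
        for key in detect_hbonds(f, traj.topology, donors, acceptors,
                                 d_max=d_max, angle_max=angle_max,
                                 angle_convention=angle_convention):
            counts[key] = counts.get(key, 0) + 1
    n = len(frames)
    occ = {k: c / n for k, c in counts.items()}
    return OccupancyTable(occupancy=occ, n_frames=n)


def union_tables(a: OccupancyTable, b: OccupancyTable) -> OccupancyTable:
    """Union of two occupancy tables (e.g. both donor->acceptor directions)."""
    if a.n_frames != b.n_frames:
        raise ValueError("cannot union tables over different frame counts")
    occ = dict(a.occupancy)
    for k, v in b.occupancy.items():
        occ[k] = max(occ.get(k, 0.0), v)
    return OccupancyTable(occupancy=occ, n_frames=a.n_frames)


def filter_significant(table: OccupancyTable,
                       threshold: float = 0.10) -> OccupancyTable:
    """Keep bonds with occupancy strictly above the threshold."""
    occ = {k: v for k, v in table.occupancy.items() if v > threshold}
    return OccupancyTable(occupancy=occ, n_frames=table.n_frames)


def per_ligand_count(total_bonds: "int | float", n_ligands: int) -> float:
    """Normalise a total bond count per ligand (exact division).

    For a four-ligand system a total of 34 bonds reports as 8.5 per
    ligand; a single-ligand system reports the count unchanged.
    """
    if n_ligands < 1:
        raise ValueError("n_ligands must be >= 1")
    return total_bonds / n_ligands
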