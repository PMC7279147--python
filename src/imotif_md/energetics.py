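"""Group-group nonbonded pair-energy decomposition.

The interaction model is the standard fixed-charge nonbonded pair
potential: Lennard-Jones 12-6 plus real-space Coulomb,

    U(r) = 4 eps_ij [ (sig_ij/r)^12 - (sig_ij/r)^6 ] + k_e q_i q_j / r,

with Lorentz-Berthelot mixing (eps_ij geometric mean, sig_ij arithmetic
mean), sharp truncation at the cutoff (12 Å default), no shift and no tail
correction, under orthorhombic minimum-image periodicity.  Reciprocal-space
(mesh Ewald) electrostatics are deliberately absent: group-pair energies
are not decomposable from a mesh sum, so only the real-space part is
meaningful per pair of groups.  No intramolecular exclusions are applied;
all reported energies are between distinct molecules or groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from .core import COULOMB_CONSTANT, Frame, Selection, Topology, Trajectory

DEFAULT_CUTOFF = 12.0
CLASH_DISTANCE = 0.1


@dataclass
class PairEnergySeries:
    """Per-frame LJ / Coulomb / total energies (kJ/mol) for one group pair."""

    times: np.ndarray
    lj: np.ndarray
    coulomb: np.ndarray
    label_a: str
    label_b: str

    @property
    def total(self) -> np.ndarray:
        return self.lj + self.coulomb

    def means(self) -> Tuple[float, float, float]:
        return (float(self.lj.mean()), float(self.coulomb.mean()),
                float(self.total.mean()))


def pair_energy(frame: Frame, topology: Topology, group_a: Selection,
                group_b: Selection,
                cutoff: float = DEFAULT_CUTOFF) -> Tuple[float, float]:
    """Nonbonded (LJ, Coulomb) energy in kJ/mol between two disjoint groups.

    Sums over all atom pairs (i in A, j in B) whose minimum-image distance
    is <= cutoff.  Raises on overlapping selections and on interatomic
    distances below 0.1 Å (a clash, most likely a unit error).
    """
    if len(np.intersect1d(group_a.indices, group_b.indices)) > 0:
        raise ValueError(
            f"selections {group_a.label!r} and {group_b.label!r} overlap; "
            "pair energies are defined between disjoint groups"
        )
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("pair_energy requires two non-empty selections")
    # canonical group order makes the summation identical for (A,B) and
    # (B,A), so the symmetry property holds to the last bit
    if group_b.indices.tobytes() < group_a.indices.tobytes():
        group_a, group_b = group_b, group_a

    pa = frame.positions[group_a.indices]
    pb = frame.positions[group_b.indices]
    d = pa[:, None, :] - pb[None, :, :]
    d -= frame.box * np.floor(d / frame.box + 0.5)
    r2 = np.einsum("ijk,ijk->ij", d, d)
    if np.any(r2 < CLASH_DISTANCE ** 2):
        i, j = np.unravel_index(np.argmin(r2), r2.shape)
        raise ValueError(
            f"clash: atoms {topology.atoms[group_a.indices[i]].atom_id} and "
            f"{topology.atoms[group_b.indices[j]].atom_id} are "
            f"{np.sqrt(r2[i, j]):.4f} Å apart (< {CLASH_DISTANCE} Å)"
        )
    mask = r2 <= cutoff ** 2
    if not mask.any():
        return 0.0, 0.0
    r = np.sqrt(r2[mask])

    eps = np.sqrt(np.outer(topology.lj_epsilons[group_a.indices],
                           topology.lj_epsilons[group_b.indices]))[mask]
    sig = (0.5 * (topology.lj_sigmas[group_a.indices][:, None]
                  + topology.lj_sigmas[group_b.indices][None, :]))[mask]
    qq = np.outer(topology.charges[group_a.indices],
                  topology.charges[group_b.indices])[mask]

    sr6 = (sig / r) ** 6
    lj = float(np.sum(4.0 * eps * (sr6 * sr6 - sr6)))
    coulomb = float(np.sum(COULOMB_CONSTANT * qq / r))
    return lj, coulomb


def pair_energy_series(traj: Trajectory, group_a: Selection,
                       group_b: Selection, cutoff: float = DEFAULT_CUTOFF,
                       frames: "List[Frame] | None" = None,
                       ) -> PairEnergySeries:
    """Evaluate pair_energy over frames (default: all) as a series."""
    frames = traj.frames if frames is None else frames
    lj = np.empty(len(frames))
    co = np.empty(len(frames))
    for k, f in enumerate(frames):
        lj[k], co[k] = pair_energy(f, traj.topology, group_a, group_b,
                                   cutoff=cutoff)
    return PairEnergySeries(times=np.array([f.time for f in frames]),
                            lj=lj, coulomb=co,
                            label_a=group_a.label, label_b=group_b.label)


def windowed_mean_energy(traj: Trajectory, group_a: Selection,
                         group_b: Selection, window_ns: float = 10.8,
                         cutoff: float = DEFAULT_CUTOFF,
                         ) -> Tuple[float, float, float]:
    """Mean (LJ, Coulomb, total) over the trailing window of the trajectory.

    The production convention is to average over the final 10.8 ns of a
    run, after the system has settled; the window length is configurable.
    """
    frames = traj.trailing_window(window_ns)
    series = pair_energy_series(traj, group_a, group_b, cutoff=cutoff,
                                frames=frames)
    return series.means()
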