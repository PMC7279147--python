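"""Fixture and scenario generation with machine-readable ground truth.

Three families of builders:

* a geometric zigzag carbon-nanotube builder (atoms on a cylinder of
  radius sqrt(3) n a_cc / (2 pi), diameter ~ 0.78 n Å for the standard
  C-C bond length);
* solvation stoichiometry (NaCl pair counts for a target ionic strength
  plus counter-ions for exact charge neutrality);
* scripted toy trajectories: bead-chain molecules whose per-frame cluster
  membership, hydrogen-bond windows, rigid drift and thermal noise are
  all planted by construction and emitted alongside the trajectory as a
  :class:`ScenarioTruth`, so every analysis stage can be verified against
  known answers without running any MD engine.

Toy molecules are bead models with user-set charges, LJ parameters and
donor/acceptor flags — not chemically faithful DNA or doxorubicin.  All
analyses in this package are geometry- and parameter-driven, so chemical
realism adds nothing to their verification.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import AVOGADRO, AtomRecord, Frame, Topology, Trajectory
from . import io_formats
from .pulling import MorsePMF, PullingTrace, simulate_pull

CC_BOND_LENGTH = 1.421  # Å, aromatic C-C


# ---------------------------------------------------------------------------
# carbon nanotube
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CNTSpec:
    """A zigzag (n,0) tube: chiral index, axial repeats, C-C bond length."""

    n: int
    rings: int = 6
    bond_length: float = CC_BOND_LENGTH

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("chiral index n must be >= 4 (tube would "
                             "self-intersect)")
        if self.rings < 1:
            raise ValueError("rings must be >= 1")


def build_zigzag_cnt(spec: CNTSpec,
                     box: Tuple[float, float, float] = (100.0, 100.0, 100.0),
                     ) -> Tuple[Topology, Frame]:
    """Carbon positions of a zigzag (n,0) tube, axis along z.

    The graphene unit cell maps to four rings of n atoms per axial repeat
    (period 3 a_cc), so the atom count is exactly 4 n rings.  The tube is
    centred in the box.
    """
    n, a = spec.n, spec.bond_length
    radius = math.sqrt(3.0) * n * a / (2.0 * math.pi)
    # ring offsets within one repeat: (z, angular offset in half-steps)
    ring_geometry = [(0.0, 0.0), (a, 0.0), (1.5 * a, 0.5), (2.5 * a, 0.5)]
    dphi = 2.0 * math.pi / n
    coords = []
    for rep in range(spec.rings):
        z0 = rep * 3.0 * a
        for z_off, ang_off in ring_geometry:
            for j in range(n):
                phi = (j + ang_off) * dphi
                coords.append((radius * math.cos(phi),
                               radius * math.sin(phi), z0 + z_off))
    pos = np.array(coords)
    pos += np.asarray(box) / 2.0 - pos.mean(axis=0)

    atoms = [
        AtomRecord(atom_id=i + 1, element="C", type_label="ca", charge=0.0,
                   lj_epsilon=0.36, lj_sigma=3.40, radius=1.70,
                   molecule_id=1, molecule_class="CNT")
        for i in range(len(pos))
    ]
    # bonds from plain distances (tube is not box-spanning)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    ii, jj = np.nonzero((d > 0.1) & (d < 1.3 * a))
    bonds = [(int(i) + 1, int(j) + 1) for i, j in zip(ii, jj) if i < j]
    topo = Topology(atoms, bonds)
    frame = Frame(time=0.0, positions=pos, box=np.asarray(box, dtype=float))
    return topo, frame


def measure_tube_diameter(positions: np.ndarray) -> float:
    """Twice the mean radial distance from the best-fit tube axis.

    The axis is the principal direction of the centred coordinates.
    """
    pos = np.asarray(positions, dtype=float)
    centred = pos - pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    # candidate axes are the principal directions; the true axis is the
    # one about which radial distances are (near-)constant, which stays
    # correct for short, wide tubes where the largest-variance direction
    # is radial rather than axial
    best = None
    for axis in vt:
        radial = centred - np.outer(centred @ axis, axis)
        r = np.linalg.norm(radial, axis=1)
        if best is None or r.std() < best[0]:
            best = (r.std(), r.mean())
    return float(2.0 * best[1])


# ---------------------------------------------------------------------------
# solvation stoichiometry
# ---------------------------------------------------------------------------

def ion_counts(box: Sequence[float], ionic_strength: float = 0.145,
               net_charge: float = 0.0) -> Tuple[int, int]:
    """(n_Na, n_Cl) for a target ionic strength plus exact neutralisation.

    The base NaCl pair count is round(c N_A V) with V the box volume; the
    solute net charge is then cancelled by extra counter-ions so that
    n_Na - n_Cl = -net_charge exactly.
    """
    if ionic_strength < 0:
        raise ValueError("ionic strength must be >= 0")
    volume_l = float(np.prod(np.asarray(box, dtype=float))) * 1e-27
    pairs = int(round(ionic_strength * AVOGADRO * volume_l))
    q = int(round(net_charge))
    n_na, n_cl = pairs, pairs
    if q < 0:
        n_na += -q
    elif q > 0:
        n_cl += q
    return n_na, n_cl


# ---------------------------------------------------------------------------
# scripted scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MoleculeSpec:
    """A toy bead-chain molecule.

    Beads lie along x at ``spacing`` Å.  ``donor_sites`` beads become
    donors (element N) each carrying one polar hydrogen 1 Å above;
    ``acceptor_sites`` beads become acceptors (element O).
    """

    molecule_id: int
    molecule_class: str
    n_atoms: int
    spacing: float = 1.5
    donor_sites: Tuple[int, ...] = ()
    acceptor_sites: Tuple[int, ...] = ()
    charge: float = 0.0
    lj_epsilon: float = 0.30
    lj_sigma: float = 3.0


@dataclass(frozen=True)
class PlantedHBond:
    """A scripted hydrogen bond active in an explicit set of frames.

    While active, the acceptor bead is placed 2.8 Å from the donor with a
    5° deviation of the D-H···A angle from linearity (both inside the
    3 Å / 20° detection gates); while inactive the host ligand is parked
    far away.
    """

    donor_molecule: int
    donor_site: int
    acceptor_molecule: int
    acceptor_site: int
    frames: Tuple[int, ...]
    distance: float = 2.8
    deviation_deg: float = 5.0


@dataclass
class ScenarioConfig:
    molecules: List[MoleculeSpec]
    n_frames: int
    partition_windows: List[Tuple[int, int, List[List[int]]]] = field(
        default_factory=list)
    hbonds: List[PlantedHBond] = field(default_factory=list)
    box: Tuple[float, float, float] = (100.0, 100.0, 100.0)
    dt_frame_ns: float = 0.1
    drift_per_frame: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    noise_sigma: float = 0.05
    seed: int = 0


@dataclass
class ScenarioTruth:
    """Ground truth emitted with every synthetic trajectory."""

    n_frames: int
    seed: int
    noise_sigma: float
    drift_per_frame: Tuple[float, float, float]
    partitions: List[List[List[int]]]          # per frame
    hbond_keys: List[Tuple[int, int, int]]     # (donor, hydrogen, acceptor)
    hbond_frames: List[List[int]]              # active frames per key
    pmf: Optional[dict] = None

    @property
    def cluster_counts(self) -> List[int]:
        return [len(p) for p in self.partitions]

    @property
    def hbond_occupancies(self) -> List[float]:
        return [len(fr) / self.n_frames for fr in self.hbond_frames]

    def to_json(self, path: "str | Path") -> None:
        payload = {
            "n_frames": self.n_frames,
            "seed": self.seed,
            "noise_sigma": self.noise_sigma,
            "drift_per_frame": list(self.drift_per_frame),
            "partitions": self.partitions,
            "hbond_keys": [list(k) for k in self.hbond_keys],
            "hbond_frames": self.hbond_frames,
            "pmf": self.pmf,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: "str | Path") -> "ScenarioTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            n_frames=d["n_frames"], seed=d["seed"],
            noise_sigma=d["noise_sigma"],
            drift_per_frame=tuple(d["drift_per_frame"]),
            partitions=d["partitions"],
            hbond_keys=[tuple(k) for k in d["hbond_keys"]],
            hbond_frames=d["hbond_frames"], pmf=d.get("pmf"),
        )


def _build_scenario_topology(config: ScenarioConfig,
                             ) -> Tuple[Topology, Dict[Tuple[int, int], int],
                                        Dict[Tuple[int, int], int]]:
    """Topology plus (molecule, bead) -> atom-index maps (beads and Hs)."""
    records: List[AtomRecord] = []
    bonds: List[Tuple[int, int]] = []
    bead_index: Dict[Tuple[int, int], int] = {}
    h_index: Dict[Tuple[int, int], int] = {}
    aid = 0
    for spec in config.molecules:
        prev_id = None
        for b in range(spec.n_atoms):
            aid += 1
            is_donor = b in spec.donor_sites
            is_acceptor = b in spec.acceptor_sites
            element = "N" if is_donor else ("O" if is_acceptor else "C")
            charge = -0.3 if (is_donor or is_acceptor) else spec.charge
            records.append(AtomRecord(
                atom_id=aid, element=element, type_label=f"b{b}",
                charge=charge, lj_epsilon=spec.lj_epsilon,
                lj_sigma=spec.lj_sigma, radius=1.70,
                molecule_id=spec.molecule_id,
                molecule_class=spec.molecule_class,
                is_donor=is_donor, is_acceptor=is_acceptor,
            ))
            bead_index[(spec.molecule_id, b)] = len(records) - 1
            if prev_id is not None:
                bonds.append((prev_id, aid))
            prev_id = aid
            if is_donor:
                aid += 1
                records.append(AtomRecord(
                    atom_id=aid, element="H", type_label=f"h{b}",
                    charge=0.3, lj_epsilon=0.05, lj_sigma=1.0, radius=1.20,
                    molecule_id=spec.molecule_id,
                    molecule_class=spec.molecule_class,
                    is_polar_hydrogen=True,
                ))
                h_index[(spec.molecule_id, b)] = len(records) - 1
                bonds.append((aid - 1, aid))
    return Topology(records, bonds), bead_index, h_index


def _partition_for_frame(config: ScenarioConfig,
                         frame: int) -> List[List[int]]:
    for start, end, partition in config.partition_windows:
        if start <= frame < end:
            return partition
    return []


def _validate_config(config: ScenarioConfig) -> List[int]:
    """Return the clustered molecule ids; raise on inconsistent scripts."""
    clustered: set = set()
    for start, end, partition in config.partition_windows:
        seen: set = set()
        for group in partition:
            for m in group:
                if m in seen:
                    raise ValueError(
                        f"molecule {m} appears twice in partition for "
                        f"frames [{start}, {end})"
                    )
                seen.add(m)
        clustered |= seen
    known = {s.molecule_id for s in config.molecules}
    missing = clustered - known
    if missing:
        raise ValueError(f"partition references unknown molecules {missing}")
    for hb in config.hbonds:
        for m in (hb.donor_molecule, hb.acceptor_molecule):
            if m not in known:
                raise ValueError(f"planted bond references unknown molecule {m}")
    return sorted(clustered)


def make_scenario(config: ScenarioConfig,
                  ) -> Tuple[Trajectory, ScenarioTruth]:
    """Realise a scripted scenario as (Trajectory, ScenarioTruth).

    Placement layout: each cluster group sits at a well-separated grid
    anchor; within a group, chains are stacked 3.0 Å apart (inside the
    3.5 Å contact cutoff), while distinct groups stay more than 6 Å
    apart.  Ligand molecules are positioned by their active planted bond,
    or parked in a reserved region when inactive.  Thermal noise is
    applied to every atom except those defining planted bonds, so planted
    geometries are exact and bonds are present in exactly the configured
    frames.  Deterministic under the configured seed.
    """
    clustered = _validate_config(config)
    specs = {s.molecule_id: s for s in config.molecules}
    topo, bead_index, h_index = _build_scenario_topology(config)
    rng = np.random.default_rng(config.seed)

    # atoms whose geometry must stay exact
    rigid = set()
    for hb in config.hbonds:
        rigid.add(bead_index[(hb.donor_molecule, hb.donor_site)])
        rigid.add(h_index[(hb.donor_molecule, hb.donor_site)])
        rigid.add(bead_index[(hb.acceptor_molecule, hb.acceptor_site)])
    noise_mask = np.ones(topo.n_atoms, dtype=bool)
    noise_mask[sorted(rigid)] = False

    ligand_ids = sorted({hb.acceptor_molecule for hb in config.hbonds}
                        | {s.molecule_id for s in config.molecules
                           if s.molecule_id not in clustered})
    bonds_by_ligand: Dict[int, List[PlantedHBond]] = {m: [] for m in ligand_ids}
    for hb in config.hbonds:
        bonds_by_ligand.setdefault(hb.acceptor_molecule, []).append(hb)
    for m, hbs in bonds_by_ligand.items():
        frames_seen: set = set()
        for hb in hbs:
            overlap = frames_seen & set(hb.frames)
            if overlap:
                raise ValueError(
                    f"ligand molecule {m} has two active bonds in frames "
                    f"{sorted(overlap)[:5]}... (cannot be in two places)"
                )
            frames_seen |= set(hb.frames)

    drift = np.asarray(config.drift_per_frame, dtype=float)
    dev = math.radians(5.0)
    frames: List[Frame] = []
    partitions_truth: List[List[List[int]]] = []

    def chain_positions(mol_id: int, origin: np.ndarray) -> None:
        """Place a chain molecule with beads along +x from origin."""
        spec = specs[mol_id]
        for b in range(spec.n_atoms):
            pos[bead_index[(mol_id, b)]] = origin + np.array(
                [b * spec.spacing, 0.0, 0.0])
            if (mol_id, b) in h_index:
                pos[h_index[(mol_id, b)]] = origin + np.array(
                    [b * spec.spacing, 0.0, 1.0])

    for k in range(config.n_frames):
        pos = np.zeros((topo.n_atoms, 3))
        partition = _partition_for_frame(config, k)
        groups = sorted((sorted(g) for g in partition), key=lambda g: g[0])
        for gi, group in enumerate(groups):
            anchor = np.array([12.0 + 28.0 * (gi % 3),
                               15.0 + 28.0 * (gi // 3), 50.0])
            for mi, mol in enumerate(group):
                # stacked along y so nearest inter-chain atoms sit at 3.0 Å
                chain_positions(mol, anchor + np.array([0.0, 3.0 * mi, 0.0]))
        for li, mol in enumerate(ligand_ids):
            active = None
            for hb in bonds_by_ligand.get(mol, []):
                if k in hb.frames:
                    active = hb
                    break
            if active is None:
                chain_positions(mol, np.array([12.0 + 10.0 * li, 75.0, 50.0]))
            else:
                d_pos = pos[bead_index[(active.donor_molecule,
                                        active.donor_site)]]
                u = np.array([0.0, 0.0, 1.0])          # D->H direction
                w = np.array([math.sin(math.radians(active.deviation_deg)),
                              0.0,
                              math.cos(math.radians(active.deviation_deg))])
                cosd = math.cos(math.radians(active.deviation_deg))
                d_ha = -cosd + math.sqrt(cosd * cosd - 1.0
                                         + active.distance ** 2)
                a_target = d_pos + u + d_ha * w
                spec = specs[mol]
                order = sorted(range(spec.n_atoms),
                               key=lambda j: (abs(j - active.acceptor_site), j))
                for rank, j in enumerate(order):
                    pos[bead_index[(mol, j)]] = a_target + np.array(
                        [0.0, 0.0, rank * spec.spacing])

        pos += drift * k
        noise = rng.normal(0.0, config.noise_sigma, size=pos.shape)
        pos[noise_mask] += noise[noise_mask]
        frames.append(Frame(time=k * config.dt_frame_ns, positions=pos,
                            box=np.asarray(config.box, dtype=float)))
        partitions_truth.append([list(g) for g in groups])

    keys = []
    active_frames = []
    for hb in config.hbonds:
        d_id = topo.atoms[bead_index[(hb.donor_molecule, hb.donor_site)]].atom_id
        h_id = topo.atoms[h_index[(hb.donor_molecule, hb.donor_site)]].atom_id
        a_id = topo.atoms[bead_index[(hb.acceptor_molecule,
                                      hb.acceptor_site)]].atom_id
        keys.append((d_id, h_id, a_id))
        active_frames.append(sorted(hb.frames))

    truth = ScenarioTruth(
        n_frames=config.n_frames, seed=config.seed,
        noise_sigma=config.noise_sigma,
        drift_per_frame=tuple(config.drift_per_frame),
        partitions=partitions_truth, hbond_keys=keys,
        hbond_frames=active_frames,
    )
    return Trajectory(topo, frames), truth


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _chains(n: int, n_atoms: int = 8, mol_class: str = "iM",
            **kw) -> List[MoleculeSpec]:
    return [MoleculeSpec(molecule_id=i + 1, molecule_class=mol_class,
                         n_atoms=n_atoms, **kw) for i in range(n)]


def preset_b1(n_frames: int = 40, seed: int = 11) -> ScenarioConfig:
    """Six DNA chains: a five-chain aggregate plus one detached chain.

    Scripted cluster count is 2 in every frame.
    """
    return ScenarioConfig(
        molecules=_chains(6),
        n_frames=n_frames,
        partition_windows=[(0, n_frames, [[1, 2, 3, 4, 5], [6]])],
        drift_per_frame=(0.05, 0.02, 0.0),
        seed=seed,
    )


def preset_b3(n_frames: int = 60, seed: int = 13) -> ScenarioConfig:
    """Six chains oscillating between four and five clusters.

    Alternating 10-frame windows merge and split one pair, so the
    per-frame count oscillates 5 <-> 4 and the window summary reports the
    range (4, 5).
    """
    five = [[1, 2], [3], [4], [5], [6]]
    four = [[1, 2], [3, 4], [5], [6]]
    windows = []
    for start in range(0, n_frames, 10):
        part = five if (start // 10) % 2 == 0 else four
        windows.append((start, min(start + 10, n_frames), part))
    return ScenarioConfig(
        molecules=_chains(6), n_frames=n_frames,
        partition_windows=windows, drift_per_frame=(0.02, 0.0, 0.0),
        seed=seed,
    )


def _ligand(mol_id: int, acceptor_sites=(0,)) -> MoleculeSpec:
    return MoleculeSpec(molecule_id=mol_id, molecule_class="DOX",
                        n_atoms=3, acceptor_sites=acceptor_sites)


def preset_c2(n_frames: int = 100, seed: int = 17) -> ScenarioConfig:
    """One unfolded DNA coil plus four ligands with five planted bonds.

    Planted occupancies 0.90, 0.50, 0.30, 0.12 and 0.05: four bonds
    survive the 10% significance filter, one does not.
    """
    coil = MoleculeSpec(molecule_id=1, molecule_class="iM", n_atoms=15,
                        donor_sites=(0, 3, 6, 9, 12))
    ligands = [_ligand(2, acceptor_sites=(0, 2)), _ligand(3), _ligand(4),
               _ligand(5)]
    hbonds = [
        PlantedHBond(1, 0, 2, 0, tuple(range(0, 90))),    # 0.90
        PlantedHBond(1, 3, 3, 0, tuple(range(0, 50))),    # 0.50
        PlantedHBond(1, 6, 4, 0, tuple(range(0, 30))),    # 0.30
        PlantedHBond(1, 9, 5, 0, tuple(range(0, 12))),    # 0.12
        PlantedHBond(1, 12, 2, 2, tuple(range(90, 95))),  # 0.05
    ]
    return ScenarioConfig(
        molecules=[coil] + ligands, n_frames=n_frames,
        partition_windows=[(0, n_frames, [[1]])], hbonds=hbonds,
        seed=seed,
    )


def preset_c4(n_frames: int = 100, seed: int = 19) -> ScenarioConfig:
    """One folded DNA structure plus four ligands with three planted bonds.

    The folded form offers fewer donor sites (occupancies 0.70, 0.30,
    0.15); one ligand never binds.
    """
    folded = MoleculeSpec(molecule_id=1, molecule_class="iM", n_atoms=15,
                          donor_sites=(0, 3, 6))
    ligands = [_ligand(m) for m in (2, 3, 4, 5)]
    hbonds = [
        PlantedHBond(1, 0, 2, 0, tuple(range(0, 70))),
        PlantedHBond(1, 3, 3, 0, tuple(range(0, 30))),
        PlantedHBond(1, 6, 4, 0, tuple(range(0, 15))),
    ]
    return ScenarioConfig(
        molecules=[folded] + ligands, n_frames=n_frames,
        partition_windows=[(0, n_frames, [[1]])], hbonds=hbonds,
        seed=seed,
    )


PULL_MORSE_DEFAULTS = dict(depth=50.0, width=1.0, r0=10.0, spring_k=100.0,
                           velocity=0.5, temperature=300.0, friction=1.0,
                           dt=2e-4, pull_length=12.0)


def preset_pull_morse(seed: int = 23, **overrides
                      ) -> Tuple[PullingTrace, ScenarioTruth]:
    """A steered-Langevin pull on a Morse well of known 50 kJ/mol depth."""
    params = dict(PULL_MORSE_DEFAULTS, **overrides)
    pmf = MorsePMF(depth=params["depth"], width=params["width"],
                   r0=params["r0"])
    trace = simulate_pull(
        pmf, spring_k=params["spring_k"], velocity=params["velocity"],
        temperature=params["temperature"], friction=params["friction"],
        dt=params["dt"], pull_length=params["pull_length"], seed=seed,
    )
    truth = ScenarioTruth(
        n_frames=len(trace.time), seed=seed, noise_sigma=0.0,
        drift_per_frame=(0.0, 0.0, 0.0), partitions=[], hbond_keys=[],
        hbond_frames=[], pmf=dict(params, kind="morse", seed=seed),
    )
    return trace, truth


PRESETS = {"B1": preset_b1, "B3": preset_b3, "C2": preset_c2,
           "C4": preset_c4}


def generate_fixture_set(preset: str, out_dir: "str | Path",
                         n_frames: Optional[int] = None,
                         seed: Optional[int] = None) -> Path:
    """Emit a preset as files: topology table, dump, truth sidecar.

    For the pulling preset the trajectory is replaced by a trace TSV.
    Returns the output directory.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if preset == "pull-morse":
        kw = {} if seed is None else {"seed": seed}
        trace, truth = preset_pull_morse(**kw)
        io_formats.write_pulling_trace(
            out / "trace.tsv", trace.time, trace.xi, trace.center,
            header_comment=f"spring_k={trace.spring_k} "
                           f"velocity={trace.velocity}")
        truth.to_json(out / "truth.json")
        return out
    if preset not in PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; valid: "
            f"{', '.join(sorted(PRESETS))}, pull-morse"
        )
    kw = {}
    if n_frames is not None:
        kw["n_frames"] = n_frames
    if seed is not None:
        kw["seed"] = seed
    config = PRESETS[preset](**kw)
    traj, truth = make_scenario(config)
    io_formats.write_fftop(out / "topology.tsv", traj.topology)
    io_formats.write_lammps_dump(out / "trajectory.dump", traj.topology,
                                 traj.frames,
                                 timestep_fs=config.dt_frame_ns * 1e6)
    truth.to_json(out / "truth.json")
    return out
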