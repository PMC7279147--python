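"""Readers and writers for the formats the pipeline touches.

Standard formats: PDB (coordinates only, fixed-width v3.3 subset, read via
Biopython), XYZ, and a restricted LAMMPS text-dump dialect
(``ITEM: ATOMS id type x y z`` or scaled ``xs ys zs``, orthorhombic
``ITEM: BOX BOUNDS``).  Self-defined formats: the force-field topology
table (tab-separated, one row per atom, bond section after ``#BONDS``) and
the pulling-trace TSV (columns time/xi/center).

Every reader is total on the matching writer's output: write -> read is
the identity up to the stated printed precision.  Force-field data live
exclusively in the topology table; PDB carries no charges or LJ
parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Optional, Tuple

import numpy as np
import pandas as pd

from .core import (
    BONDI_RADII,
    AtomRecord,
    Frame,
    Selection,
    Topology,
    Trajectory,
)

logger = logging.getLogger(__name__)

DEFAULT_TIMESTEP_FS = 1.8
DEFAULT_BOX = (100.0, 100.0, 100.0)

_FFTOP_COLUMNS = [
    "atom_id", "element", "type_label", "charge", "epsilon", "sigma",
    "radius", "molecule_id", "molecule_class", "donor", "acceptor",
    "polar_h",
]

# residue-name -> molecule class, used when merging PDB metadata
_RESNAME_CLASS = {
    "DOX": "DOX", "CNT": "CNT", "GU": "Gu", "GUA": "Gu",
    "HOH": "WATER", "WAT": "WATER", "SOL": "WATER",
    "NA": "ION", "CL": "ION", "NA+": "ION", "CL-": "ION",
    "DC": "iM", "DA": "iM", "DG": "iM", "DT": "iM", "IM": "iM",
    "IMU": "iM", "IMP": "iM",
}


class FormatError(ValueError):
    """Raised for malformed input files; carries file context in the message."""


# ---------------------------------------------------------------------------
# force-field topology table
# ---------------------------------------------------------------------------

def write_fftop(path: "str | Path", topology: Topology) -> None:
    """Write the tab-separated force-field topology table."""
    lines = ["\t".join(_FFTOP_COLUMNS)]
    for a in topology.atoms:
        lines.append("\t".join([
            str(a.atom_id), a.element, a.type_label,
            f"{a.charge:.6f}", f"{a.lj_epsilon:.6f}", f"{a.lj_sigma:.6f}",
            f"{a.radius:.4f}", str(a.molecule_id), a.molecule_class,
            str(int(a.is_donor)), str(int(a.is_acceptor)),
            str(int(a.is_polar_hydrogen)),
        ]))
    lines.append("#BONDS")
    for i, j in topology.bonds:
        lines.append(f"{i}\t{j}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_fftop(path: "str | Path",
               sigma_convention: str = "sigma") -> Topology:
    """Read the force-field topology table.

    ``sigma_convention`` is ``"sigma"`` for LJ zero-crossing distances or
    ``"rmin2"`` for amber-style Rmin/2 values, converted on ingest via
    sigma = 2 * (Rmin/2) / 2^(1/6).
    """
    if sigma_convention not in ("sigma", "rmin2"):
        raise ValueError("sigma_convention must be 'sigma' or 'rmin2'")
    text = Path(path).read_text().splitlines()
    if not text:
        raise FormatError(f"{path}: empty topology table")
    header = text[0].rstrip("\n").split("\t")
    if header != _FFTOP_COLUMNS:
        raise FormatError(
            f"{path}: bad header, expected columns {_FFTOP_COLUMNS}"
        )
    atoms: List[AtomRecord] = []
    bonds: List[Tuple[int, int]] = []
    in_bonds = False
    for lineno, raw in enumerate(text[1:], start=2):
        line = raw.strip()
        if not line:
            continue
        if line == "#BONDS":
            in_bonds = True
            continue
        fields = line.split("\t")
        try:
            if in_bonds:
                i, j = (int(x) for x in line.split())
                bonds.append((i, j))
            else:
                sigma = float(fields[5])
                if sigma_convention == "rmin2":
                    sigma = 2.0 * sigma / 2 ** (1 / 6)
                atoms.append(AtomRecord(
                    atom_id=int(fields[0]), element=fields[1],
                    type_label=fields[2], charge=float(fields[3]),
                    lj_epsilon=float(fields[4]), lj_sigma=sigma,
                    radius=float(fields[6]), molecule_id=int(fields[7]),
                    molecule_class=fields[8], is_donor=bool(int(fields[9])),
                    is_acceptor=bool(int(fields[10])),
                    is_polar_hydrogen=bool(int(fields[11])),
                ))
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return Topology(atoms, bonds)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _prescan_pdb(path: Path) -> None:
    """Validate fixed-width coordinate fields so errors carry line numbers."""
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            if len(line) < 54:
                raise FormatError(f"{path}:{lineno}: truncated record")
            try:
                float(line[30:38]), float(line[38:46]), float(line[46:54])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: malformed coordinate field"
                ) from None


def read_pdb(path: "str | Path") -> Tuple[Topology, Frame]:
    """Read a PDB file into a coordinates-only topology plus one frame.

    Charges and LJ parameters are left at zero/placeholder values; they are
    merged later from the force-field topology table.  The molecule id is
    the residue sequence number; the molecule class is inferred from the
    residue name.  CRYST1 supplies the box; absent, the 100 Å cube default
    is used with a logged warning.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    _prescan_pdb(path)
    box = None
    for line in path.read_text().splitlines():
        if line.startswith("CRYST1"):
            box = np.array([float(line[6:15]), float(line[15:24]),
                            float(line[24:33])])
            break
    if box is None:
        logger.warning("%s: no CRYST1 record, defaulting box to %s Å",
                       path, DEFAULT_BOX)
        box = np.array(DEFAULT_BOX)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    atoms: List[AtomRecord] = []
    coords: List[np.ndarray] = []
    aid = 0
    for model in structure:
        for chain in model:
            for residue in chain:
                resname = residue.get_resname().strip().upper()
                mol_class = _RESNAME_CLASS.get(resname, "OTHER")
                mol_id = residue.get_id()[1]
                for atom in residue:
                    aid += 1
                    element = (atom.element or atom.get_name()[0]).strip()
                    element = element[0].upper() + element[1:].lower()
                    atoms.append(AtomRecord(
                        atom_id=aid, element=element,
                        type_label=atom.get_name().strip(),
                        charge=0.0, lj_epsilon=0.0, lj_sigma=1.0,
                        radius=BONDI_RADII.get(element, 1.70),
                        molecule_id=int(mol_id), molecule_class=mol_class,
                    ))
                    coords.append(np.asarray(atom.coord, dtype=float))
        break  # first model only
    if not atoms:
        raise FormatError(f"{path}: no ATOM/HETATM records")
    topo = Topology(atoms)
    frame = Frame(time=0.0, positions=np.stack(coords), box=box)
    return topo, frame


def write_pdb(path: "str | Path", topology: Topology, frame: Frame,
              resnames: Optional[dict] = None) -> None:
    """Write coordinates as fixed-width PDB (one model, CRYST1 box).

    ``resnames`` optionally maps molecule_id -> residue name; the default
    derives a residue name from the molecule class.
    """
    class_res = {"iM": "IM", "DOX": "DOX", "CNT": "CNT", "Gu": "GUA",
                 "WATER": "HOH", "ION": "NA", "OTHER": "UNK"}
    lines = [
        f"CRYST1{frame.box[0]:9.3f}{frame.box[1]:9.3f}{frame.box[2]:9.3f}"
        f"  90.00  90.00  90.00 P 1           1"
    ]
    counters: dict = {}
    for i, a in enumerate(topology.atoms):
        res = (resnames or {}).get(a.molecule_id,
                                   class_res.get(a.molecule_class, "UNK"))
        x, y, z = frame.positions[i]
        # atom names must be unique within a residue (PDB readers collapse
        # duplicates), so number them per molecule and element
        counters[(a.molecule_id, a.element)] = \
            counters.get((a.molecule_id, a.element), 0) + 1
        name = f"{a.element}{counters[(a.molecule_id, a.element)]}"[:4]
        lines.append(
            f"HETATM{a.atom_id % 100000:5d} {name:<4s}{res:>4s} A"
            f"{a.molecule_id % 10000:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
            f"{a.element:>2s}"
        )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def merge_fftop_into_pdb_topology(pdb_topo: Topology,
                                  ff_topo: Topology) -> Topology:
    """Adopt force-field fields from the table onto PDB-ordered atoms."""
    if pdb_topo.n_atoms != ff_topo.n_atoms:
        raise ValueError("atom counts differ between PDB and topology table")
    return ff_topo


# ---------------------------------------------------------------------------
# trajectory frames
# ---------------------------------------------------------------------------

def write_xyz(path: "str | Path", topology: Topology,
              frames: "List[Frame]") -> None:
    out = []
    for f in frames:
        out.append(str(topology.n_atoms))
        out.append(f"time={f.time:.9g} box={f.box[0]:.6g},{f.box[1]:.6g},"
                   f"{f.box[2]:.6g}")
        for a, (x, y, z) in zip(topology.atoms, f.positions):
            out.append(f"{a.element} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def _iter_xyz(path: Path, box_default: np.ndarray) -> Iterator[Frame]:
    lines = path.read_text().splitlines()
    pos = 0
    frame_index = 0
    n_expected = None
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        try:
            n = int(lines[pos].strip())
        except ValueError:
            raise FormatError(f"{path}:{pos + 1}: expected atom count")
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise FormatError(
                f"{path}: atom count changed from {n_expected} to {n} "
                f"in frame {frame_index}"
            )
        comment = lines[pos + 1]
        time = float(frame_index)
        box = box_default.copy()
        for token in comment.split():
            if token.startswith("time="):
                time = float(token[5:])
            elif token.startswith("box="):
                box = np.array([float(v) for v in token[4:].split(",")])
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[pos + 2 + k].split()
            coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
        yield Frame(time=time, positions=coords, box=box)
        pos += 2 + n
        frame_index += 1


def write_lammps_dump(path: "str | Path", topology: Topology,
                      frames: "List[Frame]",
                      timestep_fs: float = DEFAULT_TIMESTEP_FS) -> None:
    """Write the restricted ``id type x y z`` text-dump dialect.

    Frame times (ns) are converted to integer timesteps via the supplied
    integration timestep.
    """
    out = []
    for f in frames:
        step = int(round(f.time * 1e6 / timestep_fs))
        out.append("ITEM: TIMESTEP")
        out.append(str(step))
        out.append("ITEM: NUMBER OF ATOMS")
        out.append(str(topology.n_atoms))
        out.append("ITEM: BOX BOUNDS pp pp pp")
        for L in f.box:
            out.append(f"0.0 {L:.6f}")
        out.append("ITEM: ATOMS id type x y z")
        for a, (x, y, z) in zip(topology.atoms, f.positions):
            out.append(f"{a.atom_id} 1 {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


def _iter_lammps_dump(path: Path,
                      timestep_fs: float) -> Iterator[Frame]:
    lines = path.read_text().splitlines()
    pos = 0
    n_expected = None
    frame_index = 0
    while pos < len(lines):
        if not lines[pos].startswith("ITEM: TIMESTEP"):
            raise FormatError(f"{path}:{pos + 1}: expected ITEM: TIMESTEP")
        step = int(lines[pos + 1].strip())
        if not lines[pos + 2].startswith("ITEM: NUMBER OF ATOMS"):
            raise FormatError(f"{path}:{pos + 3}: expected NUMBER OF ATOMS")
        n = int(lines[pos + 3].strip())
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise FormatError(
                f"{path}: atom count changed from {n_expected} to {n} "
                f"in frame {frame_index} (timestep {step})"
            )
        if not lines[pos + 4].startswith("ITEM: BOX BOUNDS"):
            raise FormatError(f"{path}:{pos + 5}: expected BOX BOUNDS")
        bounds = np.array([[float(v) for v in lines[pos + 5 + k].split()[:2]]
                           for k in range(3)])
        box = bounds[:, 1] - bounds[:, 0]
        header = lines[pos + 8]
        if not header.startswith("ITEM: ATOMS"):
            raise FormatError(f"{path}:{pos + 9}: expected ITEM: ATOMS")
        cols = header.split()[2:]
        try:
            i_id = cols.index("id")
            if "x" in cols:
                ix, iy, iz = cols.index("x"), cols.index("y"), cols.index("z")
                scaled = False
            else:
                ix, iy, iz = (cols.index("xs"), cols.index("ys"),
                              cols.index("zs"))
                scaled = True
        except ValueError:
            raise FormatError(
                f"{path}:{pos + 9}: dump must contain id and x y z "
                f"(or xs ys zs) columns"
            ) from None
        ids = np.empty(n, dtype=int)
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[pos + 9 + k].split()
            ids[k] = int(parts[i_id])
            coords[k] = [float(parts[ix]), float(parts[iy]),
                         float(parts[iz])]
        if scaled:
            coords = bounds[:, 0] + coords * box
        order = np.argsort(ids)
        coords = coords[order]
        yield Frame(time=step * timestep_fs * 1e-6, positions=coords,
                    box=box)
        pos += 9 + n
        frame_index += 1


def read_frames(path: "str | Path", format: str = "lammps_dump",
                timestep_fs: float = DEFAULT_TIMESTEP_FS,
                box: Tuple[float, float, float] = DEFAULT_BOX,
                ) -> Iterator[Frame]:
    """Iterate frames from an XYZ file or a LAMMPS text dump.

    Dump timesteps are converted to ns via ``timestep_fs`` (default the
    1.8 fs production timestep).  Dump atom ids are re-ordered to ascending
    id, i.e. topology order.  For XYZ, time and box are taken from
    ``time=``/``box=`` comment tokens when present, else the frame index /
    the ``box`` argument.
    """
    path = Path(path)
    if format == "xyz":
        return _iter_xyz(path, np.asarray(box, dtype=float))
    if format == "lammps_dump":
        return _iter_lammps_dump(path, timestep_fs)
    raise ValueError(f"unknown trajectory format {format!r}")


def read_trajectory(path: "str | Path", topology: Topology,
                    format: str = "lammps_dump",
                    timestep_fs: float = DEFAULT_TIMESTEP_FS) -> Trajectory:
    frames = list(read_frames(path, format=format, timestep_fs=timestep_fs))
    return Trajectory(topology, frames)


# ---------------------------------------------------------------------------
# pulling traces
# ---------------------------------------------------------------------------

@dataclass
class RawPullingTrace:
    """Parsed pulling trace: time (ns), colvar xi (Å), restraint center (Å).

    ``velocity`` is the least-squares slope of center vs time; the spring
    constant is not stored in the file and must be supplied by the caller
    of the work integrator.
    """

    time: np.ndarray
    xi: np.ndarray
    center: np.ndarray
    velocity: float


def write_pulling_trace(path: "str | Path", time: np.ndarray,
                        xi: np.ndarray, center: np.ndarray,
                        header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("time\txi\tcenter\n")
        for t, x, c in zip(time, xi, center):
            fh.write(f"{t:.9g}\t{x:.9g}\t{c:.9g}\n")


def read_pulling_trace(path: "str | Path") -> RawPullingTrace:
    df = pd.read_csv(path, sep="\t", comment="#")
    expected = ["time", "xi", "center"]
    if list(df.columns[:3]) != expected:
        raise FormatError(
            f"{path}: expected columns {expected}, got {list(df.columns)}"
        )
    if len(df) < 2:
        raise FormatError(f"{path}: need at least 2 rows")
    t = df["time"].to_numpy(dtype=float)
    if not np.all(np.diff(t) > 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    center = df["center"].to_numpy(dtype=float)
    velocity = float(np.polyfit(t, center, 1)[0])
    return RawPullingTrace(time=t, xi=df["xi"].to_numpy(dtype=float),
                           center=center, velocity=velocity)
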