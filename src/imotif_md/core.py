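"""Domain types and periodic-geometry primitives shared by all analyses.

The static half of a system is a :class:`Topology` (per-atom identity,
partial charges, Lennard-Jones parameters, donor/acceptor flags, bonds);
the dynamic half is a :class:`Trajectory` of :class:`Frame` objects holding
coordinates in an orthorhombic periodic box.  Distances are in Å, times in
ns, charges in elementary-charge units e, energies in kJ/mol throughout.

Coordinates are stored unwrapped per molecule: a molecule is never split
across the periodic boundary inside a Frame (centre-of-mass and RMSD are
ill-defined on split molecules).  :func:`unwrap_molecules` enforces this on
ingest for molecules whose extent is below half the box edge.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Dict, Iterable, Iterator, List, Sequence, Tuple

import numpy as np

# Coulomb constant e^2 N_A / (4 pi eps0), in kJ Å mol^-1 e^-2
COULOMB_CONSTANT = 1389.35458
# Boltzmann constant in kJ mol^-1 K^-1
KB_KJ_MOL = 0.008314462618
# Avogadro constant, mol^-1
AVOGADRO = 6.02214076e23

VALID_CLASSES = ("iM", "DOX", "CNT", "Gu", "WATER", "ION", "OTHER")

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "Na": 22.990, "Mg": 24.305, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "K": 39.098, "Fe": 55.845,
}

# Bondi-style hard-sphere radii (Å), the fallback when a topology table
# omits per-atom radii.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47,
    "Na": 2.27, "Mg": 1.73, "P": 1.80, "S": 1.80, "Cl": 1.75, "K": 2.75,
}


class SelectionError(ValueError):
    """Raised for malformed or unresolvable selection predicates."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, force-field parameters and H-bond role flags.

    ``charge`` is the fixed partial charge in e; ``lj_epsilon`` /
    ``lj_sigma`` the 12-6 well depth (kJ/mol) and zero-crossing distance
    (Å); ``radius`` the hard-sphere radius used by the SASA calculator.
    """

    atom_id: int
    element: str
    type_label: str
    charge: float
    lj_epsilon: float
    lj_sigma: float
    molecule_id: int
    molecule_class: str
    is_donor: bool = False
    is_acceptor: bool = False
    is_polar_hydrogen: bool = False
    radius: float = 1.70

    def __post_init__(self) -> None:
        if self.atom_id < 1:
            raise ValueError(f"atom_id must be >= 1, got {self.atom_id}")
        if self.molecule_class not in VALID_CLASSES:
            raise ValueError(
                f"unknown molecule class {self.molecule_class!r}; "
                f"valid classes: {', '.join(VALID_CLASSES)}"
            )
        if self.lj_epsilon < 0:
            raise ValueError("lj_epsilon must be >= 0")
        if self.lj_sigma <= 0:
            raise ValueError("lj_sigma must be > 0")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.is_polar_hydrogen and self.is_acceptor:
            raise ValueError(
                f"atom {self.atom_id}: cannot be both polar hydrogen and acceptor"
            )


class Topology:
    """Ordered atom list plus covalent bond list (atom-id pairs, 1-based).

    Internal indexing is 0-based; 1-based atom ids appear only at file
    boundaries.
    """

    def __init__(self, atoms: Sequence[AtomRecord],
                 bonds: Iterable[Tuple[int, int]] = ()) -> None:
        self.atoms: List[AtomRecord] = list(atoms)
        self.bonds: List[Tuple[int, int]] = [tuple(sorted(b)) for b in bonds]
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            raise ValueError("atom_ids are not unique")
        self._id_to_index = {aid: i for i, aid in enumerate(ids)}
        for i, j in self.bonds:
            if i not in self._id_to_index or j not in self._id_to_index:
                raise ValueError(f"bond ({i}, {j}) references unknown atom id")
        self._adjacency: Dict[int, List[int]] = {aid: [] for aid in ids}
        for i, j in self.bonds:
            self._adjacency[i].append(j)
            self._adjacency[j].append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def net_charge(self) -> float:
        return float(sum(a.charge for a in self.atoms))

    def index_of(self, atom_id: int) -> int:
        return self._id_to_index[atom_id]

    def bonded_ids(self, atom_id: int) -> List[int]:
        return list(self._adjacency[atom_id])

    def bonded_polar_hydrogens(self, atom_id: int) -> List[int]:
        """Atom ids of polar hydrogens covalently bonded to ``atom_id``."""
        return [
            j for j in self._adjacency[atom_id]
            if self.atoms[self._id_to_index[j]].is_polar_hydrogen
        ]

    # ---- bulk per-atom arrays -------------------------------------------
    def _array(self, attr: str, dtype=float) -> np.ndarray:
        return np.array([getattr(a, attr) for a in self.atoms], dtype=dtype)

    @property
    def charges(self) -> np.ndarray:
        return self._array("charge")

    @property
    def lj_epsilons(self) -> np.ndarray:
        return self._array("lj_epsilon")

    @property
    def lj_sigmas(self) -> np.ndarray:
        return self._array("lj_sigma")

    @property
    def radii(self) -> np.ndarray:
        return self._array("radius")

    @property
    def molecule_ids(self) -> np.ndarray:
        return self._array("molecule_id", dtype=int)

    @property
    def molecule_classes(self) -> np.ndarray:
        return np.array([a.molecule_class for a in self.atoms], dtype=object)

    def masses(self) -> np.ndarray:
        """Per-atom masses in amu, looked up from the element symbol."""
        out = np.empty(self.n_atoms)
        for i, a in enumerate(self.atoms):
            try:
                out[i] = ATOMIC_MASSES[a.element]
            except KeyError:
                raise ValueError(
                    f"no tabulated mass for element {a.element!r} "
                    f"(atom {a.atom_id}); known: {sorted(ATOMIC_MASSES)}"
                ) from None
        return out

    def molecules(self) -> Dict[int, np.ndarray]:
        """Map molecule_id -> sorted 0-based atom indices."""
        mids = self.molecule_ids
        return {
            int(m): np.flatnonzero(mids == m)
            for m in np.unique(mids)
        }

    def molecule_class_of(self, molecule_id: int) -> str:
        for a in self.atoms:
            if a.molecule_id == molecule_id:
                return a.molecule_class
        raise KeyError(molecule_id)

    def validate_donors(self) -> List[int]:
        """Return atom ids flagged as donors that lack a bonded polar hydrogen."""
        return [
            a.atom_id for a in self.atoms
            if a.is_donor and not self.bonded_polar_hydrogens(a.atom_id)
        ]


@dataclass
class Frame:
    """Time-stamped coordinates (Å) in an orthorhombic box (edge lengths Å)."""

    time: float
    positions: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n_atoms, 3)")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive edge lengths")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]


class Trajectory:
    """A topology plus a time-ordered list of frames."""

    def __init__(self, topology: Topology, frames: Sequence[Frame]) -> None:
        self.topology = topology
        self.frames: List[Frame] = list(frames)
        for f in self.frames:
            if f.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"frame at t={f.time} has {f.n_atoms} atoms, "
                    f"topology has {topology.n_atoms}"
                )
        times = self.times
        if len(times) > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames])

    @property
    def span_ns(self) -> float:
        t = self.times
        return float(t[-1] - t[0]) if len(t) > 1 else 0.0

    def trailing_window(self, window_ns: float) -> List[Frame]:
        """Frames whose time falls in the trailing window of given length.

        The window is ``[t_end - window_ns, t_end]``, inclusive on both
        ends.  Raises if no frame qualifies or the window exceeds the span.
        """
        if not self.frames:
            raise ValueError("empty trajectory")
        if window_ns > self.span_ns and len(self.frames) > 1:
            raise ValueError(
                f"window {window_ns} ns exceeds trajectory span {self.span_ns} ns"
            )
        t_end = self.frames[-1].time
        sel = [f for f in self.frames if f.time >= t_end - window_ns - 1e-12]
        if not sel:
            raise ValueError("empty analysis window")
        return sel


@dataclass(frozen=True)
class Selection:
    """Sorted unique 0-based atom indices with a human-readable label."""

    indices: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        idx = np.unique(np.asarray(self.indices, dtype=int))
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)

    def union(self, other: "Selection") -> "Selection":
        return Selection(
            np.union1d(self.indices, other.indices),
            label=f"{self.label}+{other.label}",
        )

    def complement(self, topology: Topology) -> "Selection":
        full = np.arange(topology.n_atoms)
        return Selection(np.setdiff1d(full, self.indices),
                         label=f"not({self.label})")


# ---------------------------------------------------------------------------
# periodic geometry
# ---------------------------------------------------------------------------

def min_image_displacement(a: np.ndarray, b: np.ndarray,
                           box: np.ndarray) -> np.ndarray:
    """Minimum-image displacement b - a, each component in [-L/2, L/2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    box = np.asarray(box, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))
            and np.all(np.isfinite(box))):
        raise ValueError("non-finite input to min_image_displacement")
    if np.any(box <= 0):
        raise ValueError("box edges must be positive")
    d = b - a
    return d - box * np.floor(d / box + 0.5)


def min_image_distance_matrix(pos_a: np.ndarray, pos_b: np.ndarray,
                              box: np.ndarray) -> np.ndarray:
    """Pairwise minimum-image distances, shape (len(a), len(b))."""
    d = pos_a[:, None, :] - pos_b[None, :, :]
    d -= box * np.floor(d / box + 0.5)
    return np.sqrt(np.einsum("ijk,ijk->ij", d, d))


def center_of_mass(frame: Frame, sel: Selection,
                   masses: np.ndarray) -> np.ndarray:
    """Mass-weighted mean position of a selection (no wrapping applied).

    ``masses`` is the full per-atom mass array in amu.  The caller is
    responsible for having unwrapped molecules first.
    """
    if len(sel) == 0:
        raise ValueError("center_of_mass of an empty selection")
    m = np.asarray(masses, dtype=float)[sel.indices]
    if np.any(m <= 0):
        raise ValueError("masses must be positive")
    r = frame.positions[sel.indices]
    return (m[:, None] * r).sum(axis=0) / m.sum()


def unwrap_molecules(frame: Frame, topology: Topology) -> Frame:
    """Make every molecule whole relative to its first atom.

    Valid for molecules whose extent is below half the smallest box edge,
    which holds for every system this package targets.
    """
    pos = frame.positions.copy()
    for idx in topology.molecules().values():
        anchor = pos[idx[0]]
        pos[idx] = anchor + np.stack(
            [min_image_displacement(anchor, pos[i], frame.box) for i in idx]
        )
    return Frame(time=frame.time, positions=pos, box=frame.box)


# ---------------------------------------------------------------------------
# selections
# ---------------------------------------------------------------------------

_TERM_RE = re.compile(r"^(~?)(all|class|element|molecule):?(.*)$")


def _resolve_term(topology: Topology, term: str) -> np.ndarray:
    term = term.strip()
    m = _TERM_RE.match(term)
    if not m:
        raise SelectionError(f"cannot parse selection term {term!r}")
    negate, kind, args = m.groups()
    if kind == "all":
        idx = np.arange(topology.n_atoms)
    elif kind == "class":
        names = [s.strip() for s in args.split(",") if s.strip()]
        for name in names:
            if name not in VALID_CLASSES:
                raise SelectionError(
                    f"unknown molecule class {name!r}; "
                    f"valid classes: {', '.join(VALID_CLASSES)}"
                )
        classes = topology.molecule_classes
        idx = np.flatnonzero(np.isin(classes, names))
    elif kind == "element":
        names = [s.strip() for s in args.split(",") if s.strip()]
        elements = np.array([a.element for a in topology.atoms], dtype=object)
        idx = np.flatnonzero(np.isin(elements, names))
    elif kind == "molecule":
        try:
            ids = [int(s) for s in args.split(",") if s.strip()]
        except ValueError:
            raise SelectionError(f"bad molecule ids in {term!r}") from None
        idx = np.flatnonzero(np.isin(topology.molecule_ids, ids))
    else:  # pragma: no cover - regex restricts kinds
        raise SelectionError(term)
    if negate:
        idx = np.setdiff1d(np.arange(topology.n_atoms), idx)
    return idx


def select(topology: Topology,
           predicate: "str | Callable[[AtomRecord], bool]") -> Selection:
    """Resolve a predicate to a deterministic, sorted Selection.

    String grammar: terms joined by ``+`` (union); a term is ``all``,
    ``class:NAME[,NAME...]``, ``element:SYM[,...]`` or
    ``molecule:ID[,...]``, optionally prefixed by ``~`` (complement).
    A callable predicate receives each :class:`AtomRecord`.
    """
    if callable(predicate):
        idx = np.array(
            [i for i, a in enumerate(topology.atoms) if predicate(a)],
            dtype=int,
        )
        return Selection(idx, label="<callable>")
    parts = [p for p in str(predicate).split("+") if p.strip()]
    if not parts:
        raise SelectionError("empty selection predicate")
    idx = np.unique(np.concatenate(
        [_resolve_term(topology, p) for p in parts]
    )) if parts else np.array([], dtype=int)
    return Selection(idx, label=str(predicate))
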