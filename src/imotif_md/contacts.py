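"""Single-linkage molecular clustering by interatomic contact.

Two molecules are in contact when any pair of their atoms is closer than
the cutoff (3.5 Å by default, strict inequality) under the minimum-image
convention; clusters are the connected components of the resulting
molecule graph (single linkage, transitive).  By default the nanotube,
its guanine functional groups, the ligand, water and ions are excluded, so
the partition describes the arrangement of the DNA molecules only.  All
atoms of included molecules, hydrogens included, participate in the
contact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .core import Frame, Topology, Trajectory

DEFAULT_CONTACT_CUTOFF = 3.5
DEFAULT_EXCLUDED_CLASSES = frozenset({"CNT", "Gu", "DOX", "WATER", "ION"})


@dataclass
class ClusterResult:
    """Molecule -> cluster label for one frame.

    Labels are deterministic: each cluster is labelled by the smallest
    molecule_id it contains.
    """

    time: float
    labels: Dict[int, int]
    cutoff: float
    excluded_classes: FrozenSet[str]

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels.values()))

    @property
    def partition(self) -> "List[FrozenSet[int]]":
        groups: Dict[int, set] = {}
        for mol, lab in self.labels.items():
            groups.setdefault(lab, set()).add(mol)
        return sorted((frozenset(g) for g in groups.values()),
                      key=lambda s: min(s))


@dataclass
class ClusterSummary:
    times: np.ndarray
    counts: np.ndarray
    cutoff: float

    @property
    def min_count(self) -> int:
        return int(self.counts.min())

    @property
    def max_count(self) -> int:
        return int(self.counts.max())

    @property
    def modal_count(self) -> int:
        vals, freq = np.unique(self.counts, return_counts=True)
        return int(vals[np.argmax(freq)])

    @property
    def terminal_count(self) -> int:
        return int(self.counts[-1])


def contact_clusters(frame: Frame, topology: Topology,
                     cutoff: float = DEFAULT_CONTACT_CUTOFF,
                     exclude_classes: Sequence[str] = DEFAULT_EXCLUDED_CLASSES,
                     ) -> ClusterResult:
    """Single-frame single-linkage clustering of included molecules."""
    excluded = frozenset(exclude_classes)
    mols = {
        m: idx for m, idx in topology.molecules().items()
        if topology.atoms[idx[0]].molecule_class not in excluded
    }
    if not mols:
        raise ValueError(
            f"all molecules excluded (excluded classes: {sorted(excluded)})"
        )
    mol_ids = sorted(mols)
    n = len(mol_ids)
    rows, cols = [], []
    box = frame.box
    for a in range(n):
        pa = frame.positions[mols[mol_ids[a]]]
        for b in range(a + 1, n):
            pb = frame.positions[mols[mol_ids[b]]]
            d = pa[:, None, :] - pb[None, :, :]
            d -= box * np.floor(d / box + 0.5)
            r2min = np.einsum("ijk,ijk->ij", d, d).min()
            if r2min < cutoff ** 2:
                rows += [a, b]
                cols += [b, a]
    adj = csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    n_comp, comp = connected_components(adj, directed=False)
    # label each component by its smallest molecule_id
    comp_label: Dict[int, int] = {}
    for k, m in zip(comp, mol_ids):
        comp_label[k] = min(comp_label.get(k, m), m)
    labels = {m: comp_label[k] for k, m in zip(comp, mol_ids)}
    return ClusterResult(time=frame.time, labels=labels, cutoff=cutoff,
                         excluded_classes=excluded)


def cluster_timeseries(traj: Trajectory,
                       cutoff: float = DEFAULT_CONTACT_CUTOFF,
                       exclude_classes: Sequence[str] = DEFAULT_EXCLUDED_CLASSES,
                       window_ns: Optional[float] = None,
                       ) -> Tuple[List[ClusterResult], ClusterSummary]:
    """Per-frame clustering plus a min/max/mode summary over the window.

    The summary supports range-style reporting ("4-5 clusters") alongside
    the modal and terminal-frame counts, since a fluctuating aggregate has
    no single well-defined count.
    """
    frames = (traj.frames if window_ns is None
              else traj.trailing_window(window_ns))
    results = [
        contact_clusters(f, traj.topology, cutoff=cutoff,
                         exclude_classes=exclude_classes)
        for f in frames
    ]
    summary = ClusterSummary(
        times=np.array([r.time for r in results]),
        counts=np.array([r.n_clusters for r in results]),
        cutoff=cutoff,
    )
    return results, summary
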