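import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from imotif_md.core import AtomRecord, Frame, Topology

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_bead_topology(n_molecules, atoms_per_molecule, molecule_class="iM",
                       charge=0.0, epsilon=0.3, sigma=3.0, element="C"):
    """Uniform bead molecules, handy for geometry-driven tests."""
    atoms = []
    aid = 0
    for m in range(1, n_molecules + 1):
        for _ in range(atoms_per_molecule):
            aid += 1
            atoms.append(AtomRecord(
                atom_id=aid, element=element, type_label="b",
                charge=charge, lj_epsilon=epsilon, lj_sigma=sigma,
                radius=1.7, molecule_id=m, molecule_class=molecule_class,
            ))
    return Topology(atoms)


def make_water(atom_id0=1, molecule_id=1):
    """One water: O donor/acceptor with two polar hydrogens bonded."""
    o = AtomRecord(atom_id=atom_id0, element="O", type_label="OW",
                   charge=-0.834, lj_epsilon=0.636, lj_sigma=3.15,
                   radius=1.52, molecule_id=molecule_id,
                   molecule_class="WATER", is_donor=True, is_acceptor=True)
    h1 = AtomRecord(atom_id=atom_id0 + 1, element="H", type_label="HW",
                    charge=0.417, lj_epsilon=0.0001, lj_sigma=1.0,
                    radius=1.2, molecule_id=molecule_id,
                    molecule_class="WATER", is_polar_hydrogen=True)
    h2 = AtomRecord(atom_id=atom_id0 + 2, element="H", type_label="HW",
                    charge=0.417, lj_epsilon=0.0001, lj_sigma=1.0,
                    radius=1.2, molecule_id=molecule_id,
                    molecule_class="WATER", is_polar_hydrogen=True)
    bonds = [(atom_id0, atom_id0 + 1), (atom_id0, atom_id0 + 2)]
    return [o, h1, h2], bonds


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def big_box():
    return np.array([100.0, 100.0, 100.0])


def frame_of(positions, box=(100.0, 100.0, 100.0), time=0.0):
    return Frame(time=time, positions=np.asarray(positions, dtype=float),
                 box=np.asarray(box, dtype=float))
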