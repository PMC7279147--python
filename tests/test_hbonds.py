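import math

import numpy as np
import pytest

from imotif_md.builders import make_scenario, preset_c2
from imotif_md.core import Selection, Topology, Trajectory, select
from imotif_md.hbonds import (
    HBondKey,
    OccupancyTable,
    detect_hbonds,
    filter_significant,
    occupancy,
    per_ligand_count,
    union_tables,
)

from conftest import frame_of, make_water


def donor_acceptor_system(d_oo=2.8, deviation_deg=0.0):
    """Water donor + lone acceptor O with a chosen D-A distance and
    deviation of the D-H···A angle from linearity."""
    atoms, bonds = make_water()
    from imotif_md.core import AtomRecord
    acceptor = AtomRecord(atom_id=4, element="O", type_label="OA",
                          charge=-0.5, lj_epsilon=0.6, lj_sigma=3.1,
                          radius=1.52, molecule_id=2,
                          molecule_class="OTHER", is_acceptor=True)
    topo = Topology(atoms + [acceptor], bonds)
    d_pos = np.array([50.0, 50.0, 50.0])
    h_pos = d_pos + np.array([1.0, 0.0, 0.0])
    # place A so that angle(D,H,A) = 180 - deviation and |D-A| = d_oo
    dev = math.radians(deviation_deg)
    w = np.array([math.cos(dev), math.sin(dev), 0.0])
    cosd = math.cos(dev)
    d_ha = -cosd + math.sqrt(cosd * cosd - 1.0 + d_oo ** 2)
    a_pos = h_pos + d_ha * w
    pos = np.array([d_pos, h_pos, d_pos + [0, -1.0, 0], a_pos])
    donors = Selection([0])
    acceptors = Selection([3])
    return topo, frame_of(pos), donors, acceptors


def brute_force_hbonds(frame, topo, d_max, angle_max):
    """Exhaustive oracle over all donor/hydrogen/acceptor triples."""
    found = set()
    for d in topo.atoms:
        if not d.is_donor:
            continue
        for a in topo.atoms:
            if not a.is_acceptor or a.atom_id == d.atom_id:
                continue
            dp = frame.positions[topo.index_of(d.atom_id)]
            ap = frame.positions[topo.index_of(a.atom_id)]
            if np.linalg.norm(ap - dp) >= d_max:  # big box, no wrap
                continue
            for hid in topo.bonded_ids(d.atom_id):
                h = topo.atoms[topo.index_of(hid)]
                if not h.is_polar_hydrogen:
                    continue
                hp = frame.positions[topo.index_of(hid)]
                v1, v2 = dp - hp, ap - hp
                cosang = np.dot(v1, v2) / (np.linalg.norm(v1)
                                           * np.linalg.norm(v2))
                theta = math.degrees(math.acos(np.clip(cosang, -1, 1)))
                if 180.0 - theta < angle_max:
                    found.add(HBondKey(d.atom_id, hid, a.atom_id))
    return found


class TestDetection:
    def test_collinear_within_gates_detected(self):
        topo, fr, d, a = donor_acceptor_system(d_oo=2.8, deviation_deg=0)
        assert detect_hbonds(fr, topo, d, a) \
            == {HBondKey(1, 2, 4)}

    def test_distance_gate(self):
        topo, fr, d, a = donor_acceptor_system(d_oo=3.2, deviation_deg=0)
        assert detect_hbonds(fr, topo, d, a) == set()

    def test_angle_gate(self):
        topo, fr, d, a = donor_acceptor_system(d_oo=2.8, deviation_deg=25)
        assert detect_hbonds(fr, topo, d, a) == set()

    def test_hda_convention_flag(self):
        topo, fr, d, a = donor_acceptor_system(d_oo=2.8, deviation_deg=0)
        got = detect_hbonds(fr, topo, d, a, angle_convention="hda")
        assert got == {HBondKey(1, 2, 4)}

    def test_donor_without_hydrogen_skipped_with_warning(self, caplog):
        from imotif_md.core import AtomRecord
        donor = AtomRecord(atom_id=1, element="N", type_label="N",
                           charge=-0.3, lj_epsilon=0.3, lj_sigma=3.0,
                           molecule_id=1, molecule_class="OTHER",
                           is_donor=True)
        acceptor = AtomRecord(atom_id=2, element="O", type_label="O",
                              charge=-0.3, lj_epsilon=0.3, lj_sigma=3.0,
                              molecule_id=2, molecule_class="OTHER",
                              is_acceptor=True)
        topo = Topology([donor, acceptor])
        fr = frame_of([[0, 0, 0], [2.5, 0, 0]])
        with caplog.at_level("WARNING"):
            got = detect_hbonds(fr, topo, Selection([0]), Selection([1]))
        assert got == set()
        assert "no bonded polar hydrogen" in caplog.text

    def test_matches_exhaustive_triple_oracle(self, rng):
        # 30 random polar triatomics scattered in a small region
        from imotif_md.core import AtomRecord
        atoms, bonds, coords = [], [], []
        aid = 0
        for m in range(1, 31):
            aid += 1
            base = rng.uniform(40, 60, 3)
            atoms.append(AtomRecord(
                atom_id=aid, element="O", type_label="O", charge=-0.5,
                lj_epsilon=0.5, lj_sigma=3.0, molecule_id=m,
                molecule_class="OTHER", is_donor=True, is_acceptor=True))
            coords.append(base)
            aid += 1
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            atoms.append(AtomRecord(
                atom_id=aid, element="H", type_label="H", charge=0.3,
                lj_epsilon=0.01, lj_sigma=1.0, molecule_id=m,
                molecule_class="OTHER", is_polar_hydrogen=True))
            coords.append(base + u)
            bonds.append((aid - 1, aid))
            aid += 1
            atoms.append(AtomRecord(
                atom_id=aid, element="C", type_label="C", charge=0.2,
                lj_epsilon=0.3, lj_sigma=3.2, molecule_id=m,
                molecule_class="OTHER"))
            coords.append(base + rng.normal(size=3))
        topo = Topology(atoms, bonds)
        fr = frame_of(np.array(coords))
        sel = select(topo, "all")
        got = detect_hbonds(fr, topo, sel, sel)
        assert got == brute_force_hbonds(fr, topo, 3.0, 20.0)

    @pytest.mark.parametrize("tighten", ["d_max", "angle_max"])
    def test_tightening_gates_never_adds_bonds(self, rng, tighten):
        topo, fr, d, a = donor_acceptor_system(d_oo=2.8, deviation_deg=10)
        loose = detect_hbonds(fr, topo, d, a, d_max=3.5, angle_max=30)
        kwargs = {"d_max": 3.5, "angle_max": 30}
        for value in (25, 15, 8, 2) if tighten == "angle_max" \
                else (3.2, 3.0, 2.5, 2.0):
            kwargs[tighten] = value
            tight = detect_hbonds(fr, topo, d, a, **kwargs)
            assert tight <= loose
            loose = tight


class TestOccupancy:
    def _planted_trajectory(self, present_frames, n_frames=100):
        topo, fr, d, a = donor_acceptor_system()
        far = fr.positions.copy()
        far[3] += np.array([5.0, 0, 0])
        frames = []
        for k in range(n_frames):
            pos = fr.positions if k in present_frames else far
            frames.append(frame_of(pos, time=0.1 * k))
        return Trajectory(topo, frames), d, a

    def test_bond_in_every_frame(self):
        traj, d, a = self._planted_trajectory(set(range(100)))
        table = occupancy(traj, d, a)
        assert table.occupancy[HBondKey(1, 2, 4)] == 1.0

    def test_bond_in_ten_of_hundred_frames(self):
        traj, d, a = self._planted_trajectory(set(range(10)))
        table = occupancy(traj, d, a)
        assert table.occupancy[HBondKey(1, 2, 4)] == pytest.approx(0.10)

    def test_scenario_truth_recovered_within_frame_resolution(self):
        traj, truth = make_scenario(preset_c2())
        donors = select(traj.topology, "class:iM")
        acceptors = select(traj.topology, "class:DOX")
        table = occupancy(traj, donors, acceptors)
        assert set(table.occupancy) == {HBondKey(*k)
                                        for k in truth.hbond_keys}
        for key, target in zip(truth.hbond_keys,
                               truth.hbond_occupancies):
            got = table.occupancy[HBondKey(*key)]
            assert abs(got - target) <= 1.0 / truth.n_frames


class TestFiltersAndNormalisation:
    def _table(self, values):
        occ = {HBondKey(3 * i + 1, 3 * i + 2, 3 * i + 3): v
               for i, v in enumerate(values)}
        return OccupancyTable(occupancy=occ, n_frames=100)

    def test_ten_percent_filter(self):
        table = self._table([0.9, 0.5, 0.3, 0.12, 0.05])
        assert filter_significant(table).total_bonds == 4

    def test_empty_table(self):
        assert filter_significant(self._table([])).total_bonds == 0

    def test_zero_threshold_keeps_all(self):
        table = self._table([0.9, 0.5, 0.05])
        assert filter_significant(table, 0.0).total_bonds == 3

    def test_union_takes_max(self):
        a = self._table([0.4])
        b = OccupancyTable({next(iter(a.occupancy)): 0.7}, n_frames=100)
        assert union_tables(a, b).occupancy[next(iter(a.occupancy))] == 0.7

    @pytest.mark.parametrize("total,n,expected", [
        (34, 4, 8.5),
        (19, 4, 4.75),
        (15, 1, 15.0),
    ])
    def test_per_ligand_normalisation(self, total, n, expected):
        assert per_ligand_count(total, n) == expected

    def test_zero_ligands_rejected(self):
        with pytest.raises(ValueError):
            per_ligand_count(10, 0)
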