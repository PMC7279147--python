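import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imotif_md.core import AtomRecord, Selection, Topology, Trajectory
from imotif_md.energetics import (
    pair_energy,
    pair_energy_series,
    windowed_mean_energy,
)

from conftest import frame_of


def two_atom_topology(eps=1.0, sigma=3.0, q=0.0):
    atoms = [
        AtomRecord(atom_id=i + 1, element="C", type_label="c", charge=q,
                   lj_epsilon=eps, lj_sigma=sigma, molecule_id=i + 1,
                   molecule_class="OTHER")
        for i in range(2)
    ]
    return Topology(atoms)


def random_topology(rng, n, eps_range=(0.05, 1.0), sigma_range=(2.5, 3.5)):
    atoms = [
        AtomRecord(atom_id=i + 1, element="C", type_label="c",
                   charge=float(rng.uniform(-1, 1)),
                   lj_epsilon=float(rng.uniform(*eps_range)),
                   lj_sigma=float(rng.uniform(*sigma_range)),
                   molecule_id=i + 1, molecule_class="OTHER")
        for i in range(n)
    ]
    return Topology(atoms)


def brute_force_pair_energy(frame, topo, idx_a, idx_b, cutoff):
    """O(N^2) double loop with explicit 27-image minimum distance."""
    k_e = 1389.35458
    box = frame.box
    shifts = [np.array([i, j, k]) * box
              for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
    lj = coulomb = 0.0
    for i in idx_a:
        for j in idx_b:
            r = min(np.linalg.norm(frame.positions[j] + s
                                   - frame.positions[i]) for s in shifts)
            if r > cutoff:
                continue
            ai, aj = topo.atoms[i], topo.atoms[j]
            eps = math.sqrt(ai.lj_epsilon * aj.lj_epsilon)
            sig = 0.5 * (ai.lj_sigma + aj.lj_sigma)
            sr6 = (sig / r) ** 6
            lj += 4 * eps * (sr6 * sr6 - sr6)
            coulomb += k_e * ai.charge * aj.charge / r
    return lj, coulomb


class TestPairEnergyPointValues:
    def test_lj_zero_crossing_at_sigma(self):
        topo = two_atom_topology(eps=1.0, sigma=3.0)
        fr = frame_of([[0, 0, 0], [3.0, 0, 0]])
        lj, _ = pair_energy(fr, topo, Selection([0]), Selection([1]))
        assert lj == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_is_minus_epsilon(self):
        topo = two_atom_topology(eps=1.0, sigma=3.0)
        r = 2 ** (1 / 6) * 3.0
        fr = frame_of([[0, 0, 0], [r, 0, 0]])
        lj, _ = pair_energy(fr, topo, Selection([0]), Selection([1]))
        assert lj == pytest.approx(-1.0, rel=1e-12)

    def test_coulomb_constant_from_codata(self):
        # independent evaluation of k_e = e^2 N_A / (4 pi eps0) in kJ Å/mol
        e = 1.602176634e-19
        n_a = 6.02214076e23
        eps0 = 8.8541878128e-12
        k_e = e ** 2 * n_a / (4 * math.pi * eps0) * 1e10 * 1e-3
        topo = two_atom_topology(eps=0.0, sigma=3.0, q=1.0)
        fr = frame_of([[0, 0, 0], [10.0, 0, 0]])
        _, coulomb = pair_energy(fr, topo, Selection([0]), Selection([1]))
        # the package constant is rounded to 6 significant decimals
        assert coulomb == pytest.approx(k_e / 10.0, rel=1e-8)
        assert coulomb == pytest.approx(138.935, abs=1e-3)

    def test_beyond_cutoff_is_zero(self):
        topo = two_atom_topology(eps=1.0, sigma=3.0, q=1.0)
        fr = frame_of([[0, 0, 0], [12.5, 0, 0]], box=(200, 200, 200))
        assert pair_energy(fr, topo, Selection([0]), Selection([1])) \
            == (0.0, 0.0)


class TestPairEnergyErrors:
    def test_overlapping_selections_rejected(self):
        topo = two_atom_topology()
        fr = frame_of([[0, 0, 0], [5, 0, 0]])
        with pytest.raises(ValueError, match="overlap"):
            pair_energy(fr, topo, Selection([0, 1]), Selection([1]))

    def test_clash_rejected(self):
        topo = two_atom_topology()
        fr = frame_of([[0, 0, 0], [0.05, 0, 0]])
        with pytest.raises(ValueError, match="clash"):
            pair_energy(fr, topo, Selection([0]), Selection([1]))


class TestBruteForceEquivalence:
    def test_random_systems_match_27_image_double_loop(self, rng):
        box = (30.0, 30.0, 30.0)
        for _ in range(10):
            topo = random_topology(rng, 30)
            pos = rng.uniform(0, 30, (30, 3))
            # enforce no clashes by construction check
            fr = frame_of(pos, box=box)
            idx_a, idx_b = np.arange(15), np.arange(15, 30)
            try:
                got = pair_energy(fr, topo, Selection(idx_a),
                                  Selection(idx_b), cutoff=12.0)
            except ValueError:
                continue  # rare clash draw
            want = brute_force_pair_energy(fr, topo, idx_a, idx_b, 12.0)
            assert got[0] == pytest.approx(want[0], rel=1e-9, abs=1e-9)
            assert got[1] == pytest.approx(want[1], rel=1e-9, abs=1e-9)


class TestAlgebraicProperties:
    def test_symmetry(self, rng):
        topo = random_topology(rng, 20)
        fr = frame_of(rng.uniform(5, 25, (20, 3)), box=(30, 30, 30))
        a, b = Selection(np.arange(10)), Selection(np.arange(10, 20))
        assert pair_energy(fr, topo, a, b) == pair_energy(fr, topo, b, a)

    def test_additivity_over_disjoint_groups(self, rng):
        topo = random_topology(rng, 30)
        fr = frame_of(rng.uniform(5, 25, (30, 3)), box=(30, 30, 30))
        a = Selection(np.arange(10))
        b1 = Selection(np.arange(10, 20))
        b2 = Selection(np.arange(20, 30))
        lj_u, co_u = pair_energy(fr, topo, a, b1.union(b2))
        lj1, co1 = pair_energy(fr, topo, a, b1)
        lj2, co2 = pair_energy(fr, topo, a, b2)
        assert lj_u == pytest.approx(lj1 + lj2, rel=1e-12)
        assert co_u == pytest.approx(co1 + co2, rel=1e-12)

    def test_coulomb_monotone_in_cutoff_for_like_charges(self, rng):
        atoms = [
            AtomRecord(atom_id=i + 1, element="C", type_label="c",
                       charge=0.5, lj_epsilon=0.0, lj_sigma=3.0,
                       molecule_id=i + 1, molecule_class="OTHER")
            for i in range(20)
        ]
        topo = Topology(atoms)
        fr = frame_of(rng.uniform(0, 40, (20, 3)), box=(40, 40, 40))
        a, b = Selection(np.arange(10)), Selection(np.arange(10, 20))
        prev = 0.0
        for cutoff in (4.0, 8.0, 12.0, 16.0):
            _, co = pair_energy(fr, topo, a, b, cutoff=cutoff)
            assert co >= prev - 1e-12
            prev = co


class TestWindowedMean:
    def _static_trajectory(self, n_frames=5, sep=4.0):
        topo = two_atom_topology(eps=1.0, sigma=3.0, q=0.2)
        frames = [frame_of([[0, 0, 0], [sep, 0, 0]], time=0.1 * k)
                  for k in range(n_frames)]
        return Trajectory(topo, frames)

    def test_constant_geometry_mean_equals_single_frame(self):
        traj = self._static_trajectory()
        fr = traj.frames[0]
        lj0, co0 = pair_energy(fr, traj.topology, Selection([0]),
                               Selection([1]))
        lj, co, tot = windowed_mean_energy(traj, Selection([0]),
                                           Selection([1]), window_ns=0.4)
        assert (lj, co) == pytest.approx((lj0, co0))
        assert tot == pytest.approx(lj0 + co0)

    def test_window_covers_exactly_last_three_frames(self):
        topo = two_atom_topology(eps=1.0, sigma=3.0)
        seps = [3.5, 3.6, 3.7, 3.8, 3.9, 4.0, 4.1, 4.2, 4.3, 4.4]
        frames = [frame_of([[0, 0, 0], [s, 0, 0]], time=0.1 * k)
                  for k, s in enumerate(seps)]
        traj = Trajectory(topo, frames)
        lj, co, _ = windowed_mean_energy(traj, Selection([0]),
                                         Selection([1]), window_ns=0.2)
        expected = np.mean([
            pair_energy(f, topo, Selection([0]), Selection([1]))[0]
            for f in frames[-3:]
        ])
        assert lj == pytest.approx(expected, rel=1e-12)

    def test_scripted_separations_match_hand_sum(self):
        topo = two_atom_topology(eps=0.8, sigma=3.2, q=-0.3)
        seps = [3.4, 4.1, 5.0, 6.3]
        frames = [frame_of([[0, 0, 0], [s, 0, 0]], time=0.1 * k)
                  for k, s in enumerate(seps)]
        traj = Trajectory(topo, frames)
        series = pair_energy_series(traj, Selection([0]), Selection([1]))
        by_hand = [pair_energy(f, topo, Selection([0]), Selection([1]))
                   for f in frames]
        assert np.allclose(series.lj, [x[0] for x in by_hand])
        assert np.allclose(series.coulomb, [x[1] for x in by_hand])
        assert np.allclose(series.total, series.lj + series.coulomb)

    def test_window_longer_than_span_rejected(self):
        traj = self._static_trajectory()
        with pytest.raises(ValueError, match="window"):
            windowed_mean_energy(traj, Selection([0]), Selection([1]),
                                 window_ns=10.8)
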