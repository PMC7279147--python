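import math

import numpy as np
import pytest

from imotif_md.core import AtomRecord, Selection, Topology, Trajectory
from imotif_md.structure import (
    fibonacci_sphere,
    kabsch_align,
    rmsd_series,
    sasa_series,
    shrake_rupley_sasa,
)

from conftest import frame_of, make_bead_topology


def quaternion_rmsd(P, Q, weights=None):
    """Independent minimal-RMSD oracle via the quaternion key matrix."""
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    w = np.ones(len(P)) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    Pc = P - (w[:, None] * P).sum(0)
    Qc = Q - (w[:, None] * Q).sum(0)
    S = (w[:, None] * Pc).T @ Qc
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    lam = np.linalg.eigvalsh(K)[-1]
    ga = float((w[:, None] * Pc ** 2).sum())
    gb = float((w[:, None] * Qc ** 2).sum())
    return math.sqrt(max(0.0, ga + gb - 2.0 * lam))


def rotation_z(deg):
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t), 0],
                     [math.sin(t), math.cos(t), 0],
                     [0, 0, 1.0]])


class TestKabsch:
    def test_identical_sets_zero(self, rng):
        P = rng.uniform(0, 10, (8, 3))
        _, r = kabsch_align(P, P)
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_translation_invisible(self, rng):
        P = rng.uniform(0, 10, (8, 3))
        _, r = kabsch_align(P, P + np.array([5.0, 5.0, 5.0]))
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_rotation_invisible(self, rng):
        P = rng.uniform(0, 10, (8, 3))
        _, r = kabsch_align(P, P @ rotation_z(90).T)
        assert r == pytest.approx(0.0, abs=1e-10)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(20):
            P = rng.uniform(0, 10, (20, 3))
            Q = P @ rotation_z(rng.uniform(0, 360)).T \
                + rng.normal(0, 0.5, (20, 3))
            w = rng.uniform(1, 16, 20)
            _, got = kabsch_align(P, Q, weights=w)
            assert got == pytest.approx(quaternion_rmsd(P, Q, w),
                                        abs=1e-8)

    def test_matches_mdanalysis(self, rng):
        mda_rms = pytest.importorskip("MDAnalysis.analysis.rms")
        P = rng.uniform(0, 10, (15, 3))
        Q = P @ rotation_z(33).T + rng.normal(0, 0.3, (15, 3))
        _, got = kabsch_align(P, Q)
        want = mda_rms.rmsd(P, Q, center=True, superposition=True)
        assert got == pytest.approx(want, abs=1e-6)

    def test_reflection_not_allowed(self, rng):
        P = rng.uniform(0, 10, (10, 3))
        Q = P.copy()
        Q[:, 0] *= -1  # mirrored structure
        R, r = kabsch_align(P, Q)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        assert r > 0.1  # a proper rotation cannot undo a reflection

    def test_small_or_collinear_rejected(self):
        with pytest.raises(ValueError, match="3 atoms"):
            kabsch_align(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="collinear"):
            kabsch_align(line + 0.0, line)

    def test_invariant_under_common_rigid_transform(self, rng):
        P = rng.uniform(0, 10, (12, 3))
        Q = P + rng.normal(0, 0.4, (12, 3))
        _, r0 = kabsch_align(P, Q)
        R = rotation_z(57.0)
        shift = np.array([3.0, -2.0, 8.0])
        _, r1 = kabsch_align(P @ R.T + shift, Q @ R.T + shift)
        assert r1 == pytest.approx(r0, abs=1e-9)


def mixed_trajectory(rng, n_frames=6, move="DOX"):
    """2 iM chains + 1 DOX ligand; only atoms of `move` class displaced."""
    atoms = []
    aid = 0
    for m, cls, n in ((1, "iM", 6), (2, "iM", 6), (3, "DOX", 5)):
        for _ in range(n):
            aid += 1
            atoms.append(AtomRecord(
                atom_id=aid, element="C", type_label="b", charge=0,
                lj_epsilon=0.3, lj_sigma=3.0, molecule_id=m,
                molecule_class=cls))
    topo = Topology(atoms)
    base = rng.uniform(20, 60, (17, 3))
    mask = np.array([a.molecule_class == move for a in atoms])
    frames = []
    for k in range(n_frames):
        pos = base.copy()
        pos[mask] += k * np.array([0.8, 0.3, -0.2])
        frames.append(frame_of(pos, time=0.1 * k))
    return Trajectory(topo, frames)


class TestRMSDSeries:
    def test_static_trajectory_all_zero(self, rng):
        topo = make_bead_topology(1, 10)
        pos = rng.uniform(0, 20, (10, 3))
        traj = Trajectory(topo, [frame_of(pos, time=0.1 * k)
                                 for k in range(5)])
        series = rmsd_series(traj, style="all")
        assert np.allclose(series.rmsd, 0, atol=1e-10)

    def test_excluding_the_moving_ligand_flattens_the_series(self, rng):
        traj = mixed_trajectory(rng, move="DOX")
        full = rmsd_series(traj, style="all")
        no_dox = rmsd_series(traj, style="exclude-DOX")
        assert full.rmsd[0] == pytest.approx(0.0, abs=1e-12)
        assert full.rmsd[-1] > 0.5
        assert np.allclose(no_dox.rmsd, 0, atol=1e-10)

    def test_gaussian_noise_matches_closed_form(self, rng):
        # two noisy copies of the same structure: E[RMSD] ~ sigma * sqrt(6)
        topo = make_bead_topology(1, 300)
        sigma = 0.2
        base = rng.uniform(0, 40, (300, 3))
        frames = [frame_of(base + rng.normal(0, sigma, (300, 3)),
                           time=0.1 * k) for k in range(8)]
        traj = Trajectory(topo, frames)
        series = rmsd_series(traj, style="all")
        expected = sigma * math.sqrt(6.0)
        assert np.mean(series.rmsd[1:]) == pytest.approx(expected,
                                                         rel=0.05)

    def test_empty_style_selection_rejected(self, rng):
        topo = make_bead_topology(1, 5, molecule_class="iM")
        traj = Trajectory(topo, [frame_of(rng.uniform(0, 10, (5, 3)))])
        with pytest.raises(ValueError, match="no atoms"):
            rmsd_series(traj, style="cnt-dox")


def sphere_topology(n, radius=1.6, molecule_class="DOX"):
    atoms = [
        AtomRecord(atom_id=i + 1, element="C", type_label="s", charge=0,
                   lj_epsilon=0.3, lj_sigma=3.0, radius=radius,
                   molecule_id=i + 1, molecule_class=molecule_class)
        for i in range(n)
    ]
    return Topology(atoms)


class TestSASA:
    def test_single_atom_analytic_sphere(self):
        topo = sphere_topology(1)
        fr = frame_of([[50, 50, 50]])
        area = shrake_rupley_sasa(fr, topo, Selection([0]), probe=1.4)
        assert area == pytest.approx(4 * math.pi * 3.0 ** 2, rel=1e-12)

    def test_distant_atoms_additive(self):
        topo = sphere_topology(2)
        fr = frame_of([[20, 50, 50], [80, 50, 50]], box=(200, 200, 200))
        area = shrake_rupley_sasa(fr, topo, Selection([0, 1]), probe=1.4)
        assert area == pytest.approx(2 * 4 * math.pi * 3.0 ** 2, rel=1e-12)

    def test_two_sphere_lens_closed_form(self):
        # equal expanded radii R, centres d apart: exposed = 2*2piR(R+d/2)
        topo = sphere_topology(2)
        d = 3.0
        fr = frame_of([[50, 50, 50], [50 + d, 50, 50]])
        area = shrake_rupley_sasa(fr, topo, Selection([0, 1]), probe=1.4,
                                  n_points=960)
        R = 1.6 + 1.4
        exact = 2 * 2 * math.pi * R * (R + d / 2)
        assert area == pytest.approx(exact, rel=0.01)

    def test_monotone_decrease_on_approach(self):
        topo = sphere_topology(2)
        areas = []
        for d in (6.5, 5.0, 4.0, 3.0, 2.0):
            fr = frame_of([[50, 50, 50], [50 + d, 50, 50]])
            areas.append(shrake_rupley_sasa(fr, topo, Selection([0, 1])))
        assert all(a >= b - 1e-9 for a, b in zip(areas, areas[1:]))

    def test_point_count_convergence(self):
        # non-round separation so no point count is accidentally exact
        topo = sphere_topology(2)
        d = 2.618
        fr = frame_of([[50, 50, 50], [50 + d, 50, 50]])
        R = 3.0
        exact = 2 * 2 * math.pi * R * (R + d / 2)
        errs = [abs(shrake_rupley_sasa(fr, topo, Selection([0, 1]),
                                       n_points=n) - exact)
                for n in (240, 960, 3840)]
        assert errs[2] <= errs[0] + 1e-9
        assert errs[1] / exact < 0.01

    def test_water_and_ions_never_occlude(self):
        atoms = [
            AtomRecord(atom_id=1, element="C", type_label="s", charge=0,
                       lj_epsilon=0.3, lj_sigma=3.0, radius=1.6,
                       molecule_id=1, molecule_class="DOX"),
            AtomRecord(atom_id=2, element="O", type_label="w", charge=0,
                       lj_epsilon=0.3, lj_sigma=3.0, radius=1.52,
                       molecule_id=2, molecule_class="WATER"),
            AtomRecord(atom_id=3, element="Na", type_label="i", charge=1,
                       lj_epsilon=0.3, lj_sigma=2.3, radius=2.27,
                       molecule_id=3, molecule_class="ION"),
        ]
        topo = Topology(atoms)
        fr = frame_of([[50, 50, 50], [52, 50, 50], [48, 50, 50]])
        area = shrake_rupley_sasa(fr, topo, Selection([0]))
        assert area == pytest.approx(4 * math.pi * 3.0 ** 2, rel=1e-12)

    def test_fibonacci_points_on_unit_sphere(self):
        pts = fibonacci_sphere(960)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
        assert np.linalg.norm(pts.mean(axis=0)) < 0.01

    def test_series_mean(self, rng):
        topo = sphere_topology(3)
        frames = [frame_of(rng.uniform(40, 60, (3, 3)), time=0.1 * k)
                  for k in range(4)]
        traj = Trajectory(topo, frames)
        res = sasa_series(traj, Selection([0, 1, 2]))
        assert res.mean == pytest.approx(res.area.mean())
        assert np.all(res.area >= 0)
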