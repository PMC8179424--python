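import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

import fretdyn as fd
from fretdyn.traj import Trajectory, superpose


def _random_rigid(rng):
    rot = Rotation.random(random_state=rng).as_matrix()
    trans = rng.uniform(-20, 20, 3)
    return rot, trans


class TestSuperpose:
    def test_self_superposition_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(12, 3))
        _, _, rmsd = superpose(x, x)
        assert rmsd < 1e-12

    def test_rigid_copy_zero_rmsd(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 3)) * 5
        rot, trans = _random_rigid(rng)
        _, _, rmsd = superpose(x @ rot.T + trans, x)
        assert rmsd < 1e-8

    def test_matches_brute_force_minimum(self):
        """Kabsch result equals direct numerical minimisation over rotation
        vectors for small four-point sets."""
        rng = np.random.default_rng(2)
        for _ in range(3):
            mob = rng.normal(size=(4, 3)) * 3
            ref = rng.normal(size=(4, 3)) * 3
            _, _, rmsd = superpose(mob, ref)

            mc, rc = mob - mob.mean(0), ref - ref.mean(0)

            def cost(v):
                r = Rotation.from_rotvec(v).as_matrix()
                return np.sqrt(((mc @ r.T - rc) ** 2).sum(1).mean())

            best = min(minimize(cost, x0, method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12}).fun
                       for x0 in [np.zeros(3), [3, 0, 0], [0, 3, 0],
                                  [0, 0, 3], [1.5, 1.5, 1.5]])
            assert rmsd == pytest.approx(best, abs=1e-5)

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            superpose(line, line + 1.0)


class TestDomainRmsd:
    def test_reduces_to_plain_rmsd_when_selections_match(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(size=(10, 3)) * 4
        frames = ref[None] + rng.normal(0, 0.5, size=(4, 10, 3))
        traj = Trajectory(frames)
        idx = np.arange(10)
        series = fd.domain_rmsd(traj, idx, idx, ref)
        for f, s in zip(frames, series):
            _, _, rmsd = superpose(f, ref)
            assert s == pytest.approx(rmsd, abs=1e-10)

    def test_first_frame_vs_itself_zero(self):
        rng = np.random.default_rng(4)
        ref = rng.normal(size=(8, 3)) * 5
        traj = Trajectory(ref[None])
        assert fd.domain_rmsd(traj, np.arange(4), np.arange(4, 8), ref)[0] < 1e-12

    def test_rotating_domain_matches_chord_length(self):
        """M beads on a circle of radius r rotating about the fixed N frame:
        RMSD(theta) = 2 r sin(theta/2)."""
        rng = np.random.default_rng(5)
        n_fix = rng.normal(size=(6, 3)) * 3          # static reference domain
        r = 4.0
        phi = np.linspace(0, 2 * np.pi, 8, endpoint=False)
        ring = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(8)])
        thetas = np.linspace(0, np.pi / 2, 6)
        frames = []
        for th in thetas:
            rot = Rotation.from_euler("z", th).as_matrix()
            frames.append(np.vstack([n_fix, ring @ rot.T]))
        traj = Trajectory(np.array(frames))
        ref = frames[0]
        series = fd.domain_rmsd(traj, np.arange(6), np.arange(6, 14), ref)
        expected = 2 * r * np.sin(thetas / 2)
        assert np.allclose(series, expected, atol=1e-8)


class TestRgAndDistances:
    def test_square_corner_geometry(self):
        coords = np.array([[[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]]],
                          dtype=float)
        traj = Trajectory(coords)
        assert fd.radius_of_gyration(traj)[0] == pytest.approx(np.sqrt(2.0))

    def test_rg_scales_homogeneously(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(1, 20, 3))
        r1 = fd.radius_of_gyration(Trajectory(x))[0]
        r3 = fd.radius_of_gyration(Trajectory(3.0 * x))[0]
        assert r3 == pytest.approx(3.0 * r1)

    def test_contracted_state_smaller_rg(self, toy_dimers):
        a, b = toy_dimers
        traj = Trajectory.from_structure(a, np.stack([a.coords, b.coords]))
        rg = fd.radius_of_gyration(traj)
        assert rg[1] < rg[0]

    def test_zero_mass_rejected(self):
        traj = Trajectory(np.zeros((1, 4, 3)), mass=np.zeros(4))
        with pytest.raises(ValueError):
            fd.radius_of_gyration(traj)

    def test_distance_values_and_modes(self):
        coords = np.array([[[0, 0, 0], [3, 4, 0], [1, 0, 0]]], dtype=float)
        traj = Trajectory(coords)
        assert fd.distance_series(traj, [0], [1], mode="atom")[0] == pytest.approx(5.0)
        assert fd.distance_series(traj, [0], [0])[0] == 0.0
        # mass-center of {1,2} differs from atom 1 alone
        d_mc = fd.distance_series(traj, [0], [1, 2])[0]
        assert d_mc != pytest.approx(5.0)
        assert fd.distance_series(traj, [0], [1])[0] == pytest.approx(5.0)


class TestContactPCA:
    def test_switching_contact_dominates_pc1(self):
        """Two metastable contact patterns: the switching pair carries the
        top PC1 loading and the projection is bimodal."""
        rng = np.random.default_rng(7)
        n_frames = 200
        base = np.array([[0, 0, 0], [4, 0, 0], [0, 4, 0], [4, 4, 0.0]])
        frames = np.tile(base, (2 * n_frames, 1, 1))
        # atom 3 hops between two positions -> contact (0,3) switches
        frames[n_frames:, 3, 2] += 5.0
        frames += rng.normal(0, 0.05, frames.shape)
        trajs = {"sys": Trajectory(frames)}
        res = fd.contact_pca(trajs, np.arange(4), cutoff=10.0)
        top_pair = res.loadings.iloc[0]["pair"]
        assert 3 in top_pair
        proj = res.projections["sys"][:, 0]
        assert (proj[:n_frames].mean() - proj[n_frames:].mean()) ** 2 > \
            4 * (proj[:n_frames].var() + proj[n_frames:].var())

    def test_repeated_frame_zero_variance_error_path(self):
        frame = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0.0]])
        trajs = {"sys": Trajectory(np.tile(frame, (5, 1, 1)))}
        with pytest.raises(ValueError):
            fd.contact_pca(trajs, np.arange(3))

    def test_independent_contacts_have_flat_spectrum(self):
        """Disjoint, far-separated contact pairs with independent jitter:
        the correlation spectrum is flat near 1 (no dominant component)."""
        rng = np.random.default_rng(8)
        # five dumbbells, 100 A apart; only intra-dumbbell pairs pass the
        # cutoff, so the retained distance coordinates share no atom
        anchors = []
        for k in range(5):
            anchors += [[100.0 * k, 0, 0], [100.0 * k + 5.0, 0, 0]]
        frames = np.asarray(anchors)[None] + rng.normal(0, 0.3, (3000, 10, 3))
        res = fd.contact_pca({"sys": Trajectory(frames)}, np.arange(10),
                             cutoff=10.0)
        assert len(res.pairs) == 5
        assert res.eigenvalues.max() < 1.25
        assert res.eigenvalues.min() > 0.8

    def test_trace_conservation(self):
        rng = np.random.default_rng(9)
        frames = rng.normal(size=(50, 5, 3)) * 3
        res = fd.contact_pca({"a": Trajectory(frames)}, np.arange(5), cutoff=1e6)
        assert res.eigenvalues.sum() == pytest.approx(len(res.pairs), rel=1e-9)


class TestTimescaleReport:
    @staticmethod
    def _sigmoid_series(midpoints, t_max=1000.0):
        t = np.linspace(0, t_max, 2000)
        return {f"s{m}": (t, 1.0 / (1.0 + np.exp(-(t - m) / (m / 10))))
                for m in midpoints}

    def test_planted_midpoints_ordered(self):
        series = self._sigmoid_series([1.0, 10.0, 100.0])
        thr = {k: 0.5 for k in series}
        rep = fd.timescale_report(series, thr)
        assert list(rep["series"]) == ["s1.0", "s10.0", "s100.0"]
        assert rep["crossed"].all()

    def test_flat_series_absent(self):
        t = np.linspace(0, 10, 100)
        rep = fd.timescale_report({"flat": (t, np.zeros_like(t))}, {"flat": 0.5})
        assert not rep["crossed"].iloc[0]
        assert np.isinf(rep["event_time"].iloc[0])

    def test_order_invariant_under_time_rescaling(self):
        series = self._sigmoid_series([2.0, 40.0, 300.0])
        thr = {k: 0.5 for k in series}
        order1 = list(fd.timescale_report(series, thr)["series"])
        scaled = {k: (10.0 * t, y) for k, (t, y) in series.items()}
        order2 = list(fd.timescale_report(scaled, thr)["series"])
        assert order1 == order2


class TestRigidMotionInvariance:
    def test_observables_invariant_under_global_rigid_motion(self, toy_dimers):
        a, b = toy_dimers
        coords = np.stack([a.coords, b.coords])
        traj = Trajectory.from_structure(a, coords)
        rng = np.random.default_rng(10)
        rot, trans = _random_rigid(rng)
        moved = Trajectory.from_structure(a, coords @ rot.T + trans)

        assert np.allclose(fd.radius_of_gyration(traj),
                           fd.radius_of_gyration(moved), atol=1e-9)
        assert np.allclose(fd.distance_series(traj, [0], [20]),
                           fd.distance_series(moved, [0], [20]), atol=1e-9)
        # domain RMSD invariant when the reference is co-transformed
        m_idx = traj.select(res_range=a.domain_map["M"])
        n_idx = traj.select(res_range=a.domain_map["N"])
        s1 = fd.domain_rmsd(traj, n_idx, m_idx, coords[1])
        s2 = fd.domain_rmsd(moved, n_idx, m_idx, coords[1] @ rot.T + trans)
        assert np.allclose(s1, s2, atol=1e-8)
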