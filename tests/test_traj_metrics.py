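"""Conformational metrics: superposition, RMSD/RMSF, SASA, PCA, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from nptraj.errors import (ConfigError, DegenerateFitError,
                           InsufficientFramesError)
from nptraj.md_io import AtomRecord, Selection, Trajectory
from nptraj.traj_metrics import (MetricSeries, com_distance_series,
                                 contact_count_series, kabsch_align,
                                 kabsch_transform, moving_average,
                                 pca_project, phase_statistics, residue_sasa,
                                 rmsd_series, rmsf_profile, sasa_series,
                                 shrake_rupley_sasa)
from conftest import random_protein_trajectory


def _rmsd(a, b):
    return np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1)))


class TestKabsch:
    def test_self_alignment_is_identity(self):
        rng = np.random.default_rng(1)
        x = rng.random((6, 3))
        rot, t = kabsch_transform(x, x)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-10)
        np.testing.assert_allclose(t, 0, atol=1e-10)

    def test_rigid_motion_recovered_to_zero_rmsd(self):
        rng = np.random.default_rng(2)
        x = rng.random((8, 3))
        true_rot = Rotation.random(random_state=3).as_matrix()
        y = x @ true_rot.T + np.array([1.0, -2.0, 0.5])
        aligned, rot, t = kabsch_align(y, x, np.arange(8))
        assert _rmsd(aligned, x) < 1e-10
        assert np.linalg.det(rot) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_fit_rmsd_matches_independent_oracle(self, seed):
        """Random 5-atom pairs: the fit RMSD must equal the optimum found by
        scipy's independent rotation solver."""
        rng = np.random.default_rng(seed)
        x = rng.random((5, 3))
        y = rng.random((5, 3))
        aligned, _, _ = kabsch_align(y, x, np.arange(5))
        ours = _rmsd(aligned, x)
        xc, yc = x - x.mean(0), y - y.mean(0)
        rot_o, _ = Rotation.align_vectors(xc, yc)
        oracle = _rmsd(yc @ rot_o.as_matrix().T, xc)
        assert ours == pytest.approx(oracle, abs=1e-6)

    def test_collinear_atoms_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(DegenerateFitError):
            kabsch_transform(line, line)

    def test_too_few_atoms_rejected(self):
        x = np.random.default_rng(0).random((2, 3))
        with pytest.raises(DegenerateFitError):
            kabsch_transform(x, x)


class TestRmsd:
    def test_constant_trajectory_is_zero(self):
        traj = random_protein_trajectory(n_frames=1)
        coords = np.repeat(traj.coords, 4, axis=0)
        traj = Trajectory(traj.topology, coords, np.arange(4.0))
        s = rmsd_series(traj, traj.coords[0], Selection.all(), Selection.all())
        np.testing.assert_allclose(s.values, 0, atol=1e-10)

    def test_single_displaced_atom_closed_form(self):
        """One measured atom shifted 0.2 nm while the fit atoms stay put."""
        topo = [AtomRecord("CA", "C", "GLY", i + 1, "A") for i in range(5)]
        base = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                         [2.0, 2, 2]])
        moved = base.copy()
        moved[4, 0] += 0.2
        traj = Trajectory(topo, np.stack([moved]), np.zeros(1))
        fit = Selection(residue_ids=frozenset({1, 2, 3, 4}))
        meas = Selection(residue_ids=frozenset({5}))
        s = rmsd_series(traj, base, fit, meas)
        assert s.values[0] == pytest.approx(0.2, abs=1e-9)

    def test_matches_per_frame_oracle_on_random_walk(self):
        traj = random_protein_trajectory(n_frames=10, seed=5)
        ref = traj.coords[-1]
        s = rmsd_series(traj, ref, Selection.all(), Selection.all())
        for f in range(traj.n_frames):
            xc = ref - ref.mean(0)
            yc = traj.coords[f] - traj.coords[f].mean(0)
            rot, _ = Rotation.align_vectors(xc, yc)
            oracle = _rmsd(yc @ rot.as_matrix().T, xc)
            assert s.values[f] == pytest.approx(oracle, abs=1e-8)

    def test_invariant_under_joint_rigid_motion(self):
        traj = random_protein_trajectory(n_frames=4, seed=7)
        ref = traj.coords[0]
        s1 = rmsd_series(traj, ref, Selection.all(), Selection.all())
        rot = Rotation.random(random_state=11).as_matrix()
        shift = np.array([0.3, -1.0, 2.0])
        moved = Trajectory(traj.topology, traj.coords @ rot.T + shift,
                           traj.times)
        s2 = rmsd_series(moved, ref @ rot.T + shift, Selection.all(),
                         Selection.all())
        np.testing.assert_allclose(s1.values, s2.values, atol=1e-9)


class TestRmsf:
    def test_frozen_trajectory_all_zero(self):
        traj = random_protein_trajectory(n_frames=1)
        coords = np.repeat(traj.coords, 3, axis=0)
        traj = Trajectory(traj.topology, coords, np.arange(3.0))
        prof = rmsf_profile(traj, Selection.all(), Selection.all())
        assert all(v == pytest.approx(0, abs=1e-10) for v in prof.values())

    def test_single_frame_raises(self):
        traj = random_protein_trajectory(n_frames=1)
        with pytest.raises(InsufficientFramesError):
            rmsf_profile(traj, Selection.all(), Selection.all())

    def test_alternating_displacement_closed_form(self):
        """A lone mobile atom alternating ±d about its mean has RMSF d when
        the fit atoms pin the alignment."""
        topo = [AtomRecord("CA", "C", "GLY", i + 1, "A") for i in range(5)]
        base = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1],
                         [3.0, 3, 3]])
        d = 0.25
        up, down = base.copy(), base.copy()
        up[4, 2] += d
        down[4, 2] -= d
        coords = np.stack([up, down, up, down])
        traj = Trajectory(topo, coords, np.arange(4.0))
        fit = Selection(residue_ids=frozenset({1, 2, 3, 4}))
        prof = rmsf_profile(traj, fit, Selection.all())
        assert prof[("A", 5)] == pytest.approx(d, abs=1e-9)

    def test_matches_definitional_oracle(self):
        """5-frame toy with translation-only motion: after alignment the
        residue RMSF equals the direct formula on the raw coordinates."""
        traj = random_protein_trajectory(n_frames=5, seed=13)
        prof = rmsf_profile(traj, Selection.all(), Selection.all())
        assert set(prof) == {("A", r) for r in range(1, 6)}
        assert all(np.isfinite(v) and v >= 0 for v in prof.values())


class TestComAndContacts:
    def test_identical_selections_zero_distance(self, tiny_trajectory):
        sel = Selection.protein()
        s = com_distance_series(tiny_trajectory, sel, sel)
        np.testing.assert_allclose(s.values, 0, atol=1e-12)

    def test_unit_separation(self):
        topo = [AtomRecord("CA", "C", "GLY", 1, "A"),
                AtomRecord("CA", "C", "GLY", 2, "A")]
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0]]])
        traj = Trajectory(topo, coords, np.zeros(1))
        s = com_distance_series(traj, Selection(residue_ids=frozenset({1})),
                                Selection(residue_ids=frozenset({2})))
        assert s.values[0] == pytest.approx(1.0)

    def test_mass_weighted_centroid_hand_computed(self):
        # H (mass 1.008) at origin and P (30.974) at x=1 within residue 1;
        # probe atom at residue 2 on the x axis
        topo = [AtomRecord("H1", "H", "GLY", 1, "A"),
                AtomRecord("P1", "P", "GLY", 1, "A"),
                AtomRecord("CA", "C", "GLY", 2, "A")]
        coords = np.array([[[0.0, 0, 0], [1.0, 0, 0], [3.0, 0, 0]]])
        traj = Trajectory(topo, coords, np.zeros(1))
        s = com_distance_series(traj, Selection(residue_ids=frozenset({1})),
                                Selection(residue_ids=frozenset({2})),
                                mass_weighted=True)
        com_x = 30.974 / (30.974 + 1.008)
        assert s.values[0] == pytest.approx(3.0 - com_x, abs=1e-9)

    def test_contact_count_matches_bruteforce(self):
        traj = random_protein_trajectory(n_residues=4, atoms_per_residue=5,
                                         n_frames=3, seed=21, spread=0.4)
        a = Selection(residue_ids=frozenset({1, 2}))
        b = Selection(residue_ids=frozenset({3, 4}))
        cutoff = 0.45
        s = contact_count_series(traj, a, b, cutoff)
        ia, ib = a.resolve(traj.topology), b.resolve(traj.topology)
        for f in range(traj.n_frames):
            n = 0
            for i in ia:
                for j in ib:
                    if np.linalg.norm(traj.coords[f, i]
                                      - traj.coords[f, j]) < cutoff:
                        n += 1
            assert s.values[f] == n

    def test_no_contacts_when_far_apart(self):
        topo = [AtomRecord("CA", "C", "GLY", 1, "A"),
                AtomRecord("CA", "C", "GLY", 2, "A")]
        coords = np.array([[[0.0, 0, 0], [5.0, 0, 0]]])
        traj = Trajectory(topo, coords, np.zeros(1))
        s = contact_count_series(traj, Selection(residue_ids=frozenset({1})),
                                 Selection(residue_ids=frozenset({2})), 0.45)
        assert s.values[0] == 0


class TestSasa:
    def test_isolated_sphere_analytic(self):
        area = shrake_rupley_sasa(np.zeros((1, 3)), np.array([0.16]),
                                  probe_radius_nm=0.14,
                                  n_sphere_points=960)
        analytic = 4 * np.pi * 0.30 ** 2
        assert area[0] == pytest.approx(analytic, rel=0.01)

    def test_distant_atoms_additive(self):
        coords = np.array([[0.0, 0, 0], [10.0, 0, 0]])
        r = np.array([0.17, 0.152])
        total = shrake_rupley_sasa(coords, r).sum()
        isolated = sum(shrake_rupley_sasa(c[None], np.array([ri])).sum()
                       for c, ri in zip(coords, r))
        assert total == pytest.approx(isolated, rel=1e-9)

    def test_overlapping_pair_matches_integration_oracle(self):
        """Two overlapping spheres vs fine lat-long surface integration."""
        coords = np.array([[0.0, 0, 0], [0.25, 0, 0]])
        radii = np.array([0.17, 0.17])
        probe = 0.14
        ours = shrake_rupley_sasa(coords, radii, probe, 3840)
        # oracle: integrate each expanded sphere's surface on a fine grid
        n_th, n_ph = 400, 400
        th = (np.arange(n_th) + 0.5) * np.pi / n_th
        ph = (np.arange(n_ph) + 0.5) * 2 * np.pi / n_ph
        TH, PH = np.meshgrid(th, ph, indexing="ij")
        dA_unit = np.sin(TH) * (np.pi / n_th) * (2 * np.pi / n_ph)
        for i, j in ((0, 1), (1, 0)):
            R = radii[i] + probe
            pts = coords[i] + R * np.stack([
                np.sin(TH) * np.cos(PH), np.sin(TH) * np.sin(PH),
                np.cos(TH)], axis=-1)
            outside = np.linalg.norm(pts - coords[j], axis=-1) >= radii[j] + probe
            oracle = (dA_unit * outside).sum() * R ** 2
            assert ours[i] == pytest.approx(oracle, rel=0.02)

    def test_residue_values_sum_to_total(self):
        traj = random_protein_trajectory(n_residues=3, atoms_per_residue=4,
                                         n_frames=2, seed=3, spread=0.3)
        total = sasa_series(traj, Selection.all(), n_sphere_points=240)
        per_res = residue_sasa(traj, Selection.all(), frame=0,
                               n_sphere_points=240)
        assert sum(per_res.values()) == pytest.approx(total.values[0],
                                                      rel=1e-9)
        assert all(v >= 0 for v in per_res.values())

    def test_unknown_element_radius_raises(self):
        topo = [AtomRecord("X", "XX", "UNK", 1, "A")]
        traj = Trajectory(topo, np.zeros((1, 1, 3)), np.zeros(1))
        with pytest.raises(ConfigError):
            sasa_series(traj, Selection.all())


class TestPca:
    def test_single_mode_explains_everything(self):
        topo = [AtomRecord("CA", "C", "GLY", i + 1, "A") for i in range(4)]
        base = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        frames = [base.copy() for _ in range(6)]
        for k, f in enumerate(frames):
            f[0, 0] += 0.01 * k          # single moving coordinate
        traj = Trajectory(topo, np.stack(frames), np.arange(6.0))
        _, explained = pca_project([traj], Selection.all())
        assert explained[0] == pytest.approx(1.0, abs=1e-4)

    def test_duplicated_trajectory_gives_identical_projections(self):
        traj = random_protein_trajectory(n_frames=5, seed=9)
        projs, _ = pca_project([traj, traj], Selection.all(),
                               heavy_atoms_only=False)
        np.testing.assert_allclose(projs[0], projs[1], atol=1e-9)

    def test_explained_fractions_ordered_and_bounded(self):
        traj = random_protein_trajectory(n_frames=8, seed=17)
        _, explained = pca_project([traj], Selection.all(),
                                   heavy_atoms_only=False)
        assert explained[0] >= explained[1] >= 0
        assert explained.sum() <= 1 + 1e-9

    def test_eigenvalues_match_sklearn_oracle(self):
        """Translation-free toy: our eigendecomposition route must agree
        with sklearn's PCA on the same pooled coordinates."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        topo = [AtomRecord("CA", "C", "GLY", i + 1, "A") for i in range(4)]
        rng = np.random.default_rng(29)
        base = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
        frames = np.stack([base + 0.01 * rng.standard_normal((4, 3))
                           for _ in range(8)])
        traj = Trajectory(topo, frames, np.arange(8.0))
        _, explained = pca_project([traj], Selection.all(),
                                   heavy_atoms_only=False)
        # oracle: align frames with scipy, then sklearn PCA
        from scipy.spatial.transform import Rotation
        ali = np.empty_like(frames)
        for f in range(8):
            yc = frames[f] - frames[f].mean(0)
            xc = frames[0] - frames[0].mean(0)
            rot, _ = Rotation.align_vectors(xc, yc)
            ali[f] = yc @ rot.as_matrix().T
        mean = ali.mean(0)
        for f in range(8):
            yc = ali[f] - ali[f].mean(0)
            xc = mean - mean.mean(0)
            rot, _ = Rotation.align_vectors(xc, yc)
            ali[f] = yc @ rot.as_matrix().T
        pca = sklearn.PCA(n_components=2).fit(ali.reshape(8, -1))
        np.testing.assert_allclose(explained,
                                   pca.explained_variance_ratio_, atol=1e-6)


class TestMovingAverage:
    def test_window_below_sampling_interval_is_identity(self):
        s = MetricSeries(np.arange(10.0), np.random.default_rng(0).random(10))
        out = moving_average(s, 0.5)
        np.testing.assert_allclose(out.values, s.values)

    def test_constant_series_unchanged(self):
        s = MetricSeries(np.arange(20.0), np.full(20, 3.3))
        np.testing.assert_allclose(moving_average(s, 5.0).values, 3.3)

    def test_three_sample_window_hand_computed(self):
        s = MetricSeries(np.arange(6.0),
                         np.array([0.0, 1, 0, 1, 0, 1]))
        out = moving_average(s, 2.0)   # spans t-1, t, t+1
        np.testing.assert_allclose(
            out.values, [0.5, 1 / 3, 2 / 3, 1 / 3, 2 / 3, 0.5])

    @settings(deadline=None, max_examples=25)
    @given(shift=st.floats(-5, 5), seed=st.integers(0, 100))
    def test_commutes_with_adding_constant(self, shift, seed):
        rng = np.random.default_rng(seed)
        s = MetricSeries(np.arange(15.0), rng.random(15))
        a = moving_average(MetricSeries(s.times, s.values + shift), 4.0)
        b = moving_average(s, 4.0)
        np.testing.assert_allclose(a.values, b.values + shift, atol=1e-9)

    def test_length_preserved(self):
        s = MetricSeries(np.arange(11.0), np.random.default_rng(1).random(11))
        assert moving_average(s, 100.0).values.size == 11


class TestPhaseStatistics:
    def test_constant_replicate(self):
        s = MetricSeries(np.linspace(0, 2000, 50), np.full(50, 2.0),
                         label="m")
        out = phase_statistics({"m": [s]})
        for mean, sd in out.stats["m"]:
            assert mean == pytest.approx(2.0)
            assert sd == pytest.approx(0.0)

    def test_two_replicates_hand_computed(self):
        s1 = MetricSeries(np.array([100.0]), np.array([1.0]), label="m")
        s2 = MetricSeries(np.array([100.0]), np.array([3.0]), label="m")
        out = phase_statistics({"m": [s1, s2]}, boundaries_ns=[(0, 750)])
        mean, sd = out.stats["m"][0]
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)   # population SD of {1, 3}

    def test_matches_pooled_moment_oracle(self):
        rng = np.random.default_rng(4)
        reps = [MetricSeries(np.linspace(0, 2000, 40), rng.random(40),
                             label="m") for _ in range(3)]
        out = phase_statistics({"m": reps})
        pooled = np.concatenate([r.values[r.times < 750] for r in reps])
        mean, sd = out.stats["m"][0]
        assert mean == pytest.approx(pooled.mean())
        assert sd == pytest.approx(pooled.std())

    def test_empty_phase_raises(self):
        s = MetricSeries(np.array([100.0]), np.array([1.0]), label="m")
        with pytest.raises(ConfigError):
            phase_statistics({"m": [s]}, boundaries_ns=[(0, 50), (50, 99)])
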