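"""RMSD, clustering, end-to-end regimes and quenching classification."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation

from petquench.datatypes import (BRIGHT, CLOSE, DARK, INTERMEDIATE, OPEN,
                                 StateSequence)
from petquench.synthetic_data import (TelegraphParams, default_atom_table,
                                      simulate_telegraph,
                                      simulate_two_well_distance)
from petquench.traj_analysis import (QuenchCriterion, RegimeThresholds,
                                     TrajectoryEnsemble, classify_distances,
                                     count_transitions, end_to_end_series,
                                     kabsch_rmsd, min_rmsd_to_reference,
                                     pairwise_rmsd, quench_autocorrelation,
                                     quench_series, rmsd, select_atoms,
                                     single_linkage_cluster)

# three-atom toy structures with printed coordinates (nm)
TOY_A = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
TOY_B = np.array([[0.1, 0.0, 0.0], [1.0, 0.3, 0.0], [0.2, 1.8, 0.4]])


class TestRmsd:
    def test_identical_frames_zero(self):
        # SVD trace formula cancels to ~sqrt(eps * |A|^2): 1e-7 nm scale
        assert rmsd(TOY_A, TOY_A) == pytest.approx(0.0, abs=1e-7)

    def test_rigid_transform_removed(self, rng):
        rot = Rotation.random(rng=rng)
        moved = rot.apply(TOY_A) + np.array([3.0, -1.0, 5.0])
        assert rmsd(TOY_A, moved) == pytest.approx(0.0, abs=1e-7)

    def test_toy_structures_match_independent_kabsch(self):
        # MDAnalysis implements Kabsch superposition independently
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd
        expected = mda_rmsd(TOY_A, TOY_B, center=True, superposition=True)
        assert rmsd(TOY_A, TOY_B) == pytest.approx(expected, rel=1e-8)

    def test_pseudometric_properties(self, rng):
        frames = rng.normal(0, 1, (12, 10, 3))
        d = pairwise_rmsd(frames)
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_mismatched_selection_raises(self):
        with pytest.raises(ValueError):
            rmsd(TOY_A, TOY_B[:2])


class TestSingleLinkage:
    def test_planted_populations(self, planted_ensemble):
        spec, ens, assignment = planted_ensemble
        res = single_linkage_cluster(ens, cutoff_nm=0.25)
        assert res.n_clusters == 3
        n = ens.n_frames
        for rank, weight in enumerate((0.6, 0.3, 0.1)):
            se = 100.0 * np.sqrt(weight * (1 - weight) / n)
            assert abs(res.populations_pct[rank] - 100 * weight) < 4 * se

    def test_matches_brute_force_components(self, planted_ensemble):
        import scipy.sparse as sp
        from scipy.sparse.csgraph import connected_components
        _, ens, _ = planted_ensemble
        res = single_linkage_cluster(ens, cutoff_nm=0.25)
        centered = ens.frames - ens.frames.mean(axis=1, keepdims=True)
        d = pairwise_rmsd(centered)
        n_cc, comp = connected_components(sp.coo_matrix(d < 0.25))
        assert res.n_clusters == n_cc
        # identical partitions (labels may differ, membership may not)
        for c in range(n_cc):
            members = np.flatnonzero(comp == c)
            assert len(set(res.labels[members])) == 1

    def test_chaining_links_distant_ends(self):
        # frames 0.2 nm apart stepwise, > 0.4 nm end to end: one cluster
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, (20, 3))
        b = a.copy()
        b[:, 0] += np.linspace(-1, 1, 20) * 1.2   # rmsd(a, b) ~ 0.7 nm
        steps = [a + (b - a) * f for f in np.linspace(0, 1, 5)]
        frames = np.stack(steps)
        assert float(kabsch_rmsd(frames[0], frames[-1])) > 0.4
        assert float(kabsch_rmsd(frames[0], frames[1])) < 0.25
        res = single_linkage_cluster(frames, cutoff_nm=0.25)
        assert res.n_clusters == 1

    def test_cutoff_above_diameter_gives_one_cluster(self, planted_ensemble):
        _, ens, _ = planted_ensemble
        res = single_linkage_cluster(ens, cutoff_nm=50.0)
        assert res.n_clusters == 1
        assert res.populations_pct[0] == pytest.approx(100.0)

    def test_frame_order_invariance(self, planted_ensemble):
        _, ens, _ = planted_ensemble
        res = single_linkage_cluster(ens, cutoff_nm=0.25)
        rng = np.random.default_rng(8)
        perm = rng.permutation(ens.n_frames)
        res_p = single_linkage_cluster(ens.frames[perm], cutoff_nm=0.25)
        np.testing.assert_allclose(np.sort(res.populations_pct),
                                   np.sort(res_p.populations_pct))
        np.testing.assert_array_equal(res.labels[perm], res_p.labels)

    def test_medoid_minimizes_summed_rmsd(self, planted_ensemble):
        _, ens, _ = planted_ensemble
        res = single_linkage_cluster(ens, cutoff_nm=0.25)
        members = res.members(1)
        centered = ens.frames[members] - ens.frames[members].mean(1, keepdims=True)
        d = pairwise_rmsd(centered)
        best = members[np.argmin(d.sum(axis=1))]
        assert res.medoid_frames[0] == best

    def test_empty_selection_raises(self, planted_ensemble):
        _, ens, _ = planted_ensemble
        with pytest.raises(ValueError, match="empty"):
            single_linkage_cluster(ens, selection=np.array([], int))


class TestMinRmsd:
    def test_member_target_gives_zero(self, planted_ensemble):
        _, ens, _ = planted_ensemble
        mn, arg = min_rmsd_to_reference(ens, ens.frames[17])
        assert mn == pytest.approx(0.0, abs=1e-6)
        assert arg == 17

    def test_noise_floor_against_own_center(self, planted_ensemble):
        spec, ens, assignment = planted_ensemble
        mn, _ = min_rmsd_to_reference(ens, spec.center_structures[0])
        # typical rmsd ~ sd*sqrt(3); the minimum sits below it but above 0
        assert 0.0 < mn < spec.within_cluster_sd_nm * np.sqrt(3.0)

    def test_separated_ensembles(self, rng):
        base = rng.normal(0, 1, (15, 3))
        shifted = base.copy()
        shifted[:, 0] += np.linspace(-1, 1, 15) * 0.5 * np.sqrt(12 / 7.0)
        sep = float(kabsch_rmsd(base, shifted))
        frames = np.stack([base + rng.normal(0, 0.005, (15, 3)) for _ in range(20)])
        mn, _ = min_rmsd_to_reference(frames, shifted)
        assert mn == pytest.approx(sep, abs=0.03)

    def test_empty_ensemble_raises(self):
        with pytest.raises(ValueError):
            min_rmsd_to_reference(np.empty((0, 5, 3)), TOY_A)


def _two_well_ensemble(n_steps=20_000, noise=0.0, seed=1):
    """14-residue pseudo-peptide whose CB1-CB14 distance follows the
    two-well process; all other atoms are static."""
    res = simulate_two_well_distance(noise_sd_nm=noise, n_steps=n_steps,
                                     seed=seed)
    atoms = default_atom_table(14)
    base = np.zeros((14, 3))
    base[:, 1] = np.arange(14) * 0.1
    frames = np.tile(base, (n_steps, 1, 1))
    frames[:, 13, 0] = res.distances_nm
    frames[:, 13, 1] = 0.0
    return res, TrajectoryEnsemble(atoms, base, frames, dt_frame_ns=res.dt_ns)


class TestEndToEnd:
    def test_labels_match_hidden_states(self):
        res, ens = _two_well_ensemble()
        d, states = end_to_end_series(ens)
        np.testing.assert_allclose(d, np.abs(res.distances_nm), rtol=1e-12)
        np.testing.assert_array_equal(states.values, res.hidden.values)

    def test_boundary_is_intermediate(self):
        thr = RegimeThresholds()
        labels = classify_distances(np.array([1.3, 2.5, 1.2999, 2.5001]), thr)
        np.testing.assert_array_equal(
            labels, [INTERMEDIATE, INTERMEDIATE, CLOSE, OPEN])

    def test_missing_cbeta_names_residue(self):
        atoms = default_atom_table(14)
        atoms.loc[0, "name"] = "CA"   # residue 1 has no C-beta
        ens = TrajectoryEnsemble(atoms, np.zeros((14, 3)),
                                 np.zeros((2, 14, 3)), 1.0)
        with pytest.raises(ValueError, match="residue 1"):
            end_to_end_series(ens)


class TestCountTransitions:
    def test_alternating_labels(self):
        s = StateSequence(np.array([OPEN, CLOSE, OPEN, CLOSE], np.int8),
                          250.0, "ternary")
        stats = count_transitions(s, total_time_us=1.0)
        assert stats.n_transitions == 3
        assert stats.rate_per_us == pytest.approx(3.0)

    def test_intermediate_excursion_not_counted(self):
        s = StateSequence(np.array([OPEN, INTERMEDIATE, OPEN], np.int8),
                          10.0, "ternary")
        assert count_transitions(s).n_transitions == 0

    def test_intermediate_keeps_previous_regime(self):
        s = StateSequence(np.array([OPEN, INTERMEDIATE, CLOSE, INTERMEDIATE,
                                    CLOSE, OPEN], np.int8), 10.0, "ternary")
        assert count_transitions(s).n_transitions == 2

    def test_published_transition_rate_arithmetic(self):
        # 1503 switches in 30 us of trajectory -> 50.1 per us
        n_frames = 100_000
        labels = np.full(n_frames, INTERMEDIATE, np.int8)
        switch_at = np.linspace(10, n_frames - 10, 1504).astype(int)
        for i, s in enumerate(switch_at):
            labels[s] = OPEN if i % 2 == 0 else CLOSE
        seq = StateSequence(labels, 30_000_000.0 / n_frames, "ternary")
        stats = count_transitions(seq, total_time_us=30.0)
        assert stats.n_transitions == 1503
        assert stats.rate_per_us == pytest.approx(50.1)

    def test_time_reversal_invariance(self, rng):
        labels = rng.integers(0, 3, 500).astype(np.int8)
        fwd = StateSequence(labels, 1.0, "ternary")
        rev = StateSequence(labels[::-1].copy(), 1.0, "ternary")
        assert count_transitions(fwd).n_transitions == \
            count_transitions(rev).n_transitions

    def test_never_assigned_warns(self):
        s = StateSequence(np.full(10, INTERMEDIATE, np.int8), 1.0, "ternary")
        with pytest.warns(UserWarning):
            stats = count_transitions(s)
        assert stats.n_transitions == 0


def _ring_ensemble(distances_nm):
    """Two rigid 3-atom 'ring' groups whose geometric centers sit at the
    requested distances."""
    names = ["C1", "C2", "C3", "CG", "CD1", "CD2"]
    atoms = pd.DataFrame({"resid": [1, 1, 1, 2, 2, 2],
                          "resname": ["DYE"] * 3 + ["TRP"] * 3,
                          "name": names, "element": ["C"] * 6})
    frames = np.zeros((len(distances_nm), 6, 3))
    ring = np.array([[0.1, 0.0, 0.0], [-0.05, 0.1, 0.0], [-0.05, -0.1, 0.0]])
    for f, d in enumerate(distances_nm):
        frames[f, :3] = ring
        frames[f, 3:] = ring + np.array([d, 0.0, 0.0])
    return TrajectoryEnsemble(atoms, frames[0], frames, 30.0)


class TestQuenchSeries:
    def test_distance_criterion(self):
        ens = _ring_ensemble([0.50, 0.56, 0.548])
        crit = QuenchCriterion(group_a=("C1", "C2", "C3"),
                               group_b=("CG", "CD1", "CD2"))
        states = quench_series(ens, crit)
        np.testing.assert_array_equal(states.values, [DARK, BRIGHT, DARK])

    def test_exact_boundary_is_bright(self):
        # strict inequality: a center distance exactly at r* stays bright;
        # single-atom groups and r* = 0.5 keep the distance exactly
        # representable
        atoms = pd.DataFrame({"resid": [1, 2], "resname": ["DYE", "TRP"],
                              "name": ["C1", "CG"], "element": ["C", "C"]})
        frames = np.zeros((1, 2, 3))
        frames[0, 1, 0] = 0.5
        ens = TrajectoryEnsemble(atoms, frames[0], frames, 1.0)
        crit = QuenchCriterion(group_a=("C1",), group_b=("CG",), r_star_nm=0.5)
        assert quench_series(ens, crit).values[0] == BRIGHT

    def test_missing_ring_atoms_listed(self):
        ens = _ring_ensemble([0.5])
        crit = QuenchCriterion(group_a=("C1", "C9"), group_b=("CG",))
        with pytest.raises(ValueError, match="C9"):
            quench_series(ens, crit)

    def test_overlapping_groups_rejected(self):
        ens = _ring_ensemble([0.5])
        crit = QuenchCriterion(group_a=("C1", "CG"), group_b=("CG",))
        with pytest.raises(ValueError, match="disjoint"):
            quench_series(ens, crit)


class TestQuenchAutocorrelation:
    def test_recovers_telegraph_kinetics(self):
        seq = simulate_telegraph(TelegraphParams(8.4, 5.5, dt_ns=30.0,
                                                 n_steps=600_000, seed=23))
        curve, fit = quench_autocorrelation(seq, convention="telegraph_oracle")
        assert curve.convention == "excess"
        assert fit.tau_r_ns == pytest.approx(71.9, rel=0.12)
        # amplitude = dark/bright fraction ratio
        assert fit.a_r == pytest.approx(8.4 / 5.5, rel=0.15)

    def test_constant_signal_rejected(self):
        seq = StateSequence(np.ones(1000, np.int8), 30.0, "binary")
        with pytest.raises(ValueError, match="switches"):
            quench_autocorrelation(seq)

    def test_window_offset_shortens_apparent_relaxation(self):
        # slow regime for the first 40%, fast afterwards: discarding the
        # initial window must shorten the fitted relaxation time
        slow = simulate_telegraph(TelegraphParams(1.5, 1.1, dt_ns=30.0,
                                                  n_steps=400_000, seed=5))
        fast = simulate_telegraph(TelegraphParams(8.4, 5.5, dt_ns=30.0,
                                                  n_steps=600_000, seed=6))
        joined = StateSequence(np.concatenate([slow.values, fast.values]),
                               30.0, "binary")
        _, fit_full = quench_autocorrelation(joined)
        _, fit_late = quench_autocorrelation(
            joined, start_time_us=slow.duration_us)
        assert fit_late.tau_r_ns < fit_full.tau_r_ns
        assert fit_late.tau_r_ns == pytest.approx(72.0, rel=0.2)


class TestEnsembleIO:
    def test_pdb_and_frames_roundtrip(self, tmp_path):
        res, ens = _two_well_ensemble(n_steps=5, seed=2)
        pdb = tmp_path / "ref.pdb"
        table = tmp_path / "frames.csv"
        ens.write_pdb(pdb)
        ens.write_frames_table(table)
        back = TrajectoryEnsemble.from_pdb(pdb, table, dt_frame_ns=ens.dt_frame_ns)
        assert len(back.atoms) == 14
        np.testing.assert_allclose(back.reference, ens.reference, atol=1e-4)
        np.testing.assert_allclose(back.frames, ens.frames, atol=1e-6)
        np.testing.assert_array_equal(back.atoms["resid"], ens.atoms["resid"])

    def test_selection_helpers(self):
        atoms = default_atom_table(14)
        sel = select_atoms(atoms, resids=[1, 14], names="CB")
        assert list(sel) == [0, 13]
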