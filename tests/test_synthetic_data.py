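"""Ground-truth properties of the synthetic-data generators."""

import numpy as np
import pytest
from scipy import stats

from petquench.datatypes import BRIGHT, CLOSE, OPEN, StateSequence
from petquench.fitting import fit_fcs, fit_two_state, guess_fcs_init
from petquench.correlate import segment_errors
from petquench.models import FCSModelParams, diffusion_coefficient
from petquench.synthetic_data import (EnsembleSpec, PhotonSimParams,
                                      TelegraphParams, simulate_ensemble,
                                      simulate_photons, simulate_telegraph,
                                      simulate_two_well_distance,
                                      standard_photon_spec, telegraph_events)
from petquench.traj_analysis import (classify_distances, kabsch_rmsd,
                                     RegimeThresholds, single_linkage_cluster)


def _stationary_se(f, relax_time_ns, duration_ns):
    """Standard error of the time-averaged bright fraction of a telegraph
    process: var = f(1-f), integrated correlation time ~ 2 tau_r."""
    n_eff = duration_ns / (2 * relax_time_ns)
    return np.sqrt(f * (1 - f) / n_eff)


class TestTelegraph:
    def test_symmetric_bright_fraction(self):
        p = TelegraphParams(5.0, 5.0, dt_ns=10.0, n_steps=500_000, seed=1)
        seq = simulate_telegraph(p)
        se = _stationary_se(0.5, p.relax_time_ns, seq.duration_ns)
        assert abs(seq.values.mean() - 0.5) < 3 * se

    def test_asymmetric_bright_fraction(self):
        # stationary fraction k_diss/(k_form+k_diss) = 5.0/12.4
        p = TelegraphParams(7.4, 5.0, dt_ns=10.0, n_steps=500_000, seed=2)
        seq = simulate_telegraph(p)
        f = 5.0 / 12.4
        se = _stationary_se(f, p.relax_time_ns, seq.duration_ns)
        assert abs(seq.values.mean() - f) < 3 * se

    def test_autocorrelation_amplitude_and_time(self):
        p = TelegraphParams(5.0, 5.0, dt_ns=1.0, n_steps=2_000_000, seed=3)
        seq = simulate_telegraph(p)
        curve = segment_errors(seq, max_lag_s=1e-6).to_excess()
        fit = fit_two_state(curve, convention="telegraph_oracle")
        assert fit.a_r == pytest.approx(1.0, rel=0.1)
        assert fit.tau_r_ns == pytest.approx(100.0, rel=0.1)

    def test_dwell_times_are_exponential(self):
        gen = np.random.default_rng(5)
        times, init = telegraph_events(4.0, 2.5, 20_000.0, gen)
        dwells = np.diff(times)
        states = (init + 1 + np.arange(dwells.size)) % 2
        for state, rate in ((BRIGHT, 4.0), (1 - BRIGHT, 2.5)):
            sample = dwells[states == state]
            assert sample.size > 1000
            _, pval = stats.kstest(sample, "expon", args=(0, 1.0 / rate))
            assert pval > 0.01

    def test_bit_for_bit_reproducibility(self):
        p = TelegraphParams(8.4, 5.5, dt_ns=30.0, n_steps=50_000, seed=42)
        a = simulate_telegraph(p)
        b = simulate_telegraph(p)
        np.testing.assert_array_equal(a.values, b.values)

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            TelegraphParams(k_form_per_us=-1.0, k_diss_per_us=5.0)


class TestTwoWell:
    def test_noiseless_labels_match_hidden(self):
        res = simulate_two_well_distance(noise_sd_nm=0.0, n_steps=20_000, seed=1)
        labels = classify_distances(res.distances_nm, RegimeThresholds())
        np.testing.assert_array_equal(labels, res.hidden.values)

    def test_zero_hop_rate_means_zero_transitions(self):
        res = simulate_two_well_distance(hop_rates_per_us=0.0, n_steps=5_000, seed=2)
        assert res.n_hidden_transitions == 0

    def test_symmetric_rate_transition_count(self):
        # expected switches = r * T_total for symmetric per-direction rate r
        r, n, dt = 2.0, 200_000, 30.0
        res = simulate_two_well_distance(hop_rates_per_us=r, dt_ns=dt,
                                         n_steps=n, seed=3)
        expected = r * n * dt * 1e-3
        assert abs(res.n_hidden_transitions - expected) < 4 * np.sqrt(expected)

    def test_wells_in_band_warn(self):
        with pytest.warns(UserWarning, match="intermediate band"):
            simulate_two_well_distance(d_close_nm=1.25, noise_sd_nm=0.1,
                                       n_steps=100, seed=0)


class TestEnsemble:
    def test_single_cluster_fully_recovered(self):
        gen = np.random.default_rng(0)
        spec = EnsembleSpec(center_structures=[gen.normal(0, 1, (15, 3))],
                            within_cluster_sd_nm=0.02, n_frames=80, seed=1)
        ens, _ = simulate_ensemble(spec)
        res = single_linkage_cluster(ens, cutoff_nm=0.3)
        assert res.n_clusters == 1
        assert res.populations_pct[0] == pytest.approx(100.0)

    def test_noise_free_frames_preserve_center_rmsd(self):
        gen = np.random.default_rng(1)
        centers = [gen.normal(0, 1, (12, 3)), gen.normal(0, 1, (12, 3))]
        spec = EnsembleSpec(center_structures=centers, weights=(0.5, 0.5),
                            within_cluster_sd_nm=0.0, n_frames=40, seed=2)
        ens, assignment = simulate_ensemble(spec)
        i0 = np.flatnonzero(assignment == 0)[0]
        i1 = np.flatnonzero(assignment == 1)[0]
        expected = float(kabsch_rmsd(centers[0], centers[1]))
        got = float(kabsch_rmsd(ens.frames[i0], ens.frames[i1]))
        assert got == pytest.approx(expected, rel=1e-6)

    def test_weights_must_sum_to_one(self):
        gen = np.random.default_rng(2)
        with pytest.raises(ValueError):
            EnsembleSpec(center_structures=[gen.normal(0, 1, (5, 3))] * 2,
                         weights=(0.7, 0.7))

    def test_reproducible(self):
        gen = np.random.default_rng(3)
        spec = EnsembleSpec(center_structures=[gen.normal(0, 1, (8, 3))],
                            n_frames=10, seed=9)
        a, _ = simulate_ensemble(spec)
        b, _ = simulate_ensemble(spec)
        np.testing.assert_array_equal(a.frames, b.frames)


class TestPhotonSimulator:
    def test_immobile_poisson_count_and_dispersion(self):
        p = PhotonSimParams(n_particles=1, diff_coeff_um2_s=0.0,
                            brightness_per_ms=100.0, duration_s=0.5,
                            split_channels=False, seed=1)
        s = simulate_photons(p)
        expected = 100e3 * 0.5
        assert abs(s.n_photons - expected) < 4 * np.sqrt(expected)
        # index-of-dispersion test on 1 ms bins
        bins = np.bincount((s.channels[0] * 16e-12 / 1e-3).astype(int),
                           minlength=500)[:500]
        disp = bins.var(ddof=1) / bins.mean() * (bins.size - 1)
        lo, hi = stats.chi2.ppf([0.005, 0.995], bins.size - 1)
        assert lo < disp < hi

    def test_diffusion_time_recovery(self):
        # input-recovery oracle: tau_D = w^2/(4D) = 10 us
        d = diffusion_coefficient(195.0, 10.0)
        p = PhotonSimParams(n_particles=0.3, focus_lateral_nm=195.0,
                            diff_coeff_um2_s=d, brightness_per_ms=1500.0,
                            duration_s=0.12, seed=6)
        s = simulate_photons(p)
        curve = segment_errors(s, channels=(0, 1), base_bin_s=2e-7)
        init = guess_fcs_init(curve, n_dyn=0, with_triplet=False)
        fit = fit_fcs(curve, init, vary=("n", "tau_d", "offset"), n_starts=4)
        assert fit["tau_d"].value == pytest.approx(10e-6, rel=0.15)

    def test_quench_telegraph_recovery_on_immobile_emitter(self):
        p = PhotonSimParams(n_particles=1, diff_coeff_um2_s=0.0,
                            brightness_per_ms=500.0,
                            quench=TelegraphParams(5.0, 5.0),
                            duration_s=0.5, seed=2)
        s = simulate_photons(p)
        curve = segment_errors(s, channels=(0, 1), base_bin_s=1e-8,
                               max_lag_s=1e-5)
        fit = fit_two_state(curve, convention="telegraph_oracle")
        assert fit.a_r == pytest.approx(1.0, rel=0.15)
        assert fit.tau_r_ns == pytest.approx(100.0, rel=0.15)

    def test_antibunching_dip(self):
        p = PhotonSimParams(n_particles=1, diff_coeff_um2_s=0.0,
                            brightness_per_ms=2000.0,
                            excited_lifetime_ns=200.0,
                            duration_s=0.2, seed=4)
        s = simulate_photons(p)
        curve = segment_errors(s, channels=(0, 1), base_bin_s=5e-8,
                               max_lag_s=1e-5)
        # anti-correlation below the excited-state dwell, flat beyond
        assert curve.values[0] < 0.75
        assert np.mean(curve.values[curve.lags_s > 2e-6]) == pytest.approx(1.0, abs=0.05)

    def test_resolution_guard(self):
        p = standard_photon_spec(seed=0)
        p.dt_sim_s = p.tau_d_s  # far coarser than tau_D/10
        with pytest.raises(ValueError, match="refus"):
            simulate_photons(p)

    def test_timestamps_strictly_increasing_and_reproducible(self):
        p = PhotonSimParams(n_particles=0.3, brightness_per_ms=500.0,
                            diff_coeff_um2_s=190.0, duration_s=0.05, seed=11)
        a = simulate_photons(p)
        b = simulate_photons(p)
        for ch_a, ch_b in zip(a.channels, b.channels):
            np.testing.assert_array_equal(ch_a, ch_b)
            assert np.all(np.diff(ch_a) > 0)
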