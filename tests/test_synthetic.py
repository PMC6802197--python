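"""Generator contracts: determinism, ground-truth agreement, distributions."""

import numpy as np
import pytest

from plectokin import dwellstats, kinetics, stepfind, synthetic


class TestDeterminism:
    def test_tcc_trace_bitwise_reproducible(self):
        cfg = synthetic.SimulationConfig(seed=21, duration_s=30.0)
        t1, l1 = synthetic.simulate_tcc_trace(cfg)
        t2, l2 = synthetic.simulate_tcc_trace(cfg)
        np.testing.assert_array_equal(t1.extension_nm, t2.extension_nm)
        np.testing.assert_array_equal(l1.times_s, l2.times_s)
        np.testing.assert_array_equal(l1.values, l2.values)

    def test_different_seeds_differ(self):
        a, _ = synthetic.simulate_tcc_trace(synthetic.SimulationConfig(seed=1, duration_s=30.0))
        b, _ = synthetic.simulate_tcc_trace(synthetic.SimulationConfig(seed=2, duration_s=30.0))
        assert not np.array_equal(a.extension_nm, b.extension_nm)

    def test_force_jump_reproducible(self):
        cfg = synthetic.SimulationConfig(seed=5)
        t1 = synthetic.simulate_force_jump(cfg, n_per_force=10)
        t2 = synthetic.simulate_force_jump(cfg, n_per_force=10)
        assert t1.equals(t2)


class TestTccTrace:
    def test_noiseless_trace_reproduces_eventlog(self):
        cfg = synthetic.SimulationConfig(seed=3, duration_s=60.0, noise_sd_nm=0.0)
        tr, log = synthetic.simulate_tcc_trace(cfg, tau_tcc_s=5.0)
        fit = stepfind.find_steps(tr)
        assert fit.n_steps == len(log)
        np.testing.assert_allclose(np.sort(fit.step_times_s), np.sort(log.times_s), atol=1e-9)
        np.testing.assert_allclose(np.sort(fit.step_sizes_nm), np.sort(log.values), atol=1e-9)

    def test_dwell_sample_mean_near_tau(self):
        cfg = synthetic.SimulationConfig(seed=8, duration_s=3600.0, noise_sd_nm=0.0)
        _, log = synthetic.simulate_tcc_trace(cfg, tau_tcc_s=3.0)
        dwells = log.dwells_s[1:]
        se = dwells.std(ddof=1) / np.sqrt(dwells.size)
        assert abs(dwells.mean() - 3.0) < 3 * se

    def test_event_count_poisson(self):
        cfg = synthetic.SimulationConfig(seed=12, duration_s=3600.0, noise_sd_nm=0.0)
        _, log = synthetic.simulate_tcc_trace(cfg, tau_tcc_s=3.0, capture_time_s=0.0)
        expected = 3600.0 / 3.0
        assert abs(len(log) - expected) < 4 * np.sqrt(expected)

    def test_step_size_mle_recovers_decay(self):
        cfg = synthetic.SimulationConfig(seed=4, duration_s=3600.0, noise_sd_nm=0.0)
        _, log = synthetic.simulate_tcc_trace(cfg, tau_tcc_s=3.0, step_decay_nm=45.0)
        est = dwellstats.fit_exponential_mle(np.abs(log.values))
        assert est.covers(45.0)

    def test_invalid_lifetime_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_tcc_trace(synthetic.SimulationConfig(), tau_tcc_s=0.0)


class TestRelaxationTrace:
    def test_rebind_probability_one_releases_single_turns(self):
        cfg = synthetic.SimulationConfig(seed=2, duration_s=600.0, noise_sd_nm=0.0)
        _, log = synthetic.simulate_relaxation_trace(
            cfg, tau_apic_s=2.0, rebind_prob_per_turn=1.0, total_turns=50
        )
        assert np.all(log.values == 1.0)

    def test_geometric_mean_turns(self):
        cfg = synthetic.SimulationConfig(seed=13, duration_s=6000.0, noise_sd_nm=0.0)
        _, log = synthetic.simulate_relaxation_trace(
            cfg, tau_apic_s=4.0, rebind_prob_per_turn=0.3, total_turns=2000
        )
        vals = log.values[:-1]  # last event may be truncated at the turn budget
        assert vals.size >= 500
        se = vals.std(ddof=1) / np.sqrt(vals.size)
        assert abs(vals.mean() - 1 / 0.3) < 3 * se

    def test_total_turns_budget_respected(self):
        cfg = synthetic.SimulationConfig(seed=1, duration_s=3000.0, noise_sd_nm=0.0)
        tr, log = synthetic.simulate_relaxation_trace(
            cfg, tau_apic_s=2.0, rebind_prob_per_turn=0.4, total_turns=25
        )
        assert log.values.sum() == 25
        # staircase rises by exactly total_turns x slope
        rise = tr.extension_nm[-1] - tr.extension_nm[0]
        assert rise == pytest.approx(25 * 45.0, abs=1e-6)

    def test_integer_quantized_dlk_histogram(self):
        """Recovered step sizes cluster at integer turn values."""
        cfg = synthetic.SimulationConfig(seed=17, duration_s=4000.0, noise_sd_nm=6.0)
        tr, _ = synthetic.simulate_relaxation_trace(
            cfg, tau_apic_s=5.0, rebind_prob_per_turn=0.4, total_turns=600
        )
        fit = stepfind.find_steps(tr)
        dlk = np.abs(fit.step_sizes_nm) / 45.0
        grid, dens = dwellstats.kde_linking_density(dlk, bandwidth_turns=0.2)
        for k in (1, 2, 3):
            window = (grid > k - 0.5) & (grid < k + 0.5)
            assert grid[window][np.argmax(dens[window])] == pytest.approx(k, abs=0.15)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_relaxation_trace(
                synthetic.SimulationConfig(), rebind_prob_per_turn=1.5
            )


class TestForceJump:
    def test_zero_dx_is_force_insensitive(self):
        cfg = synthetic.SimulationConfig(seed=31)
        tab = synthetic.simulate_force_jump(cfg, tau0_days=0.01, delta_x_nm=0.0,
                                            n_per_force=400, loop_fraction=0.0)
        means = tab.groupby("force_pN")["rupture_time_s"].mean()
        pooled = tab["rupture_time_s"].mean()
        se = tab["rupture_time_s"].std() / np.sqrt(400)
        assert np.all(np.abs(means - pooled) < 3 * se)

    def test_empty_request_gives_empty_table(self):
        cfg = synthetic.SimulationConfig(seed=1)
        tab = synthetic.simulate_force_jump(cfg, n_per_force=0)
        assert len(tab) == 0

    def test_empty_force_list_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_force_jump(synthetic.SimulationConfig(), forces_pN=[])

    def test_loop_precedes_rupture(self):
        cfg = synthetic.SimulationConfig(seed=9)
        tab = synthetic.simulate_force_jump(cfg, n_per_force=100)
        with_loop = tab.dropna(subset=["loop_time_s"])
        assert (with_loop["loop_time_s"] < with_loop["rupture_time_s"]).all()


class TestEnsembleKinetics:
    PARAMS = kinetics.KineticParameters(
        f_active=0.4, k_on={1800: 0.02, 4361: 0.03}, k_hs=0.05, k_fs=0.02
    )

    def test_zero_noise_equals_ode(self):
        t = [0.0, 60.0, 240.0]
        tab = synthetic.simulate_ensemble_kinetics(self.PARAMS, [4361], t,
                                                   noise_sd=0.0, replicates=3)
        expected = kinetics.full_site_fraction(self.PARAMS, 4361, t)
        np.testing.assert_allclose(tab["fs_fraction_mean"], expected, atol=1e-12)
        np.testing.assert_allclose(tab["fs_fraction_sd"], 0.0)

    def test_time_zero_is_zero(self):
        tab = synthetic.simulate_ensemble_kinetics(self.PARAMS, [1800, 4361], [0.0],
                                                   noise_sd=0.0, replicates=1)
        np.testing.assert_allclose(tab["fs_fraction_mean"], 0.0, atol=1e-12)

    def test_asymptote_is_active_fraction(self):
        tab = synthetic.simulate_ensemble_kinetics(self.PARAMS, [4361], [1e5],
                                                   noise_sd=0.0, replicates=1)
        assert tab["fs_fraction_mean"].iloc[0] == pytest.approx(0.4, abs=1e-6)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_ensemble_kinetics(self.PARAMS, [4361], [0.0], noise_sd=-1)


class TestAfmParticles:
    def test_only_supercoiled_rows(self):
        tab = synthetic.simulate_afm_particles(0, 50, seed=1)
        assert (tab["class_label"] == "covalently_closed").all()

    def test_sample_means_match_stated_world(self):
        # n=2000/class: 3 SE exceeds the ~0.06 clip bias of the OC class
        tab = synthetic.simulate_afm_particles(2000, 2000, seed=7)
        oc = tab[tab["class_label"] == "open_circular"]["n_crossings"]
        sc = tab[tab["class_label"] == "covalently_closed"]["n_crossings"]
        assert abs(oc.mean() - 2.4) < 3 * 1.7 / np.sqrt(2000) + 0.07
        assert abs(sc.mean() - 12.2) < 3 * 1.7 / np.sqrt(2000)

    def test_counts_are_nonnegative_integers(self):
        tab = synthetic.simulate_afm_particles(500, 500, seed=2)
        assert (tab["n_crossings"] >= 0).all()
        assert np.issubdtype(tab["n_crossings"].dtype, np.integer)

    def test_negative_request_rejected(self):
        with pytest.raises(ValueError):
            synthetic.simulate_afm_particles(-1, 10)


def test_lifetime_recovery_calibration():
    """MLE 95% CI covers the generating dwell mean in >=90/100 seeded traces."""
    hits = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        est = dwellstats.fit_exponential_mle(rng.exponential(3.0, 200))
        hits += est.covers(3.0)
    assert hits >= 90
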