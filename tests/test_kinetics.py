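"""Chain ODE correctness (vs closed form) and global-fit behaviour."""

import numpy as np
import pytest

from plectokin import kinetics, synthetic

TRUE = kinetics.KineticParameters(
    f_active=0.4,
    k_on={1800: 0.02, 2686: 0.025, 4361: 0.03, 7249: 0.035},
    k_hs=0.05,
    k_fs=0.02,
)
LENGTHS = [1800, 2686, 4361, 7249]
TIMES = [0.0, 30.0, 60.0, 120.0, 240.0, 480.0]


def bateman_full_site(t, k1, k2, k3):
    """Closed-form end-state occupancy of an irreversible 3-step chain."""
    ks = np.array([k1, k2, k3])
    acc = np.zeros_like(np.asarray(t, dtype=float))
    for i in range(3):
        others = np.delete(ks, i)
        coeff = np.prod(others / (others - ks[i]))
        acc = acc + coeff * np.exp(-ks[i] * np.asarray(t, dtype=float))
    return 1.0 - acc


class TestIntegrateModel:
    def test_initial_state(self):
        traj = kinetics.integrate_model(TRUE, 4361, [0.0])
        np.testing.assert_allclose(traj[0], [1.0, 0.0, 0.0, 0.0], atol=1e-12)

    def test_absorbing_chain_saturates(self):
        p = kinetics.KineticParameters(f_active=1.0, k_on={100: 0.5}, k_hs=0.5,
                                       k_fs=0.2, k_off=0.0)
        t_long = 20.0 / 0.2
        traj = kinetics.integrate_model(p, 100, [t_long])
        assert traj[0, 3] == pytest.approx(1.0, abs=1e-6)

    def test_matches_closed_form_chain(self):
        p = kinetics.KineticParameters(f_active=1.0, k_on={100: 0.1}, k_hs=0.5,
                                       k_fs=0.2, k_off=0.0)
        t = np.linspace(0.0, 50.0, 40)
        traj = kinetics.integrate_model(p, 100, t)
        expected = bateman_full_site(t, 0.1, 0.5, 0.2)
        np.testing.assert_allclose(traj[:, 3], expected, rtol=1e-8, atol=1e-10)

    def test_near_degenerate_rates_still_accurate(self):
        # k_hs == k_fs defeats the eigen route; the expm fallback must engage
        p = kinetics.KineticParameters(f_active=1.0, k_on={100: 0.1}, k_hs=0.2,
                                       k_fs=0.2, k_off=0.0)
        t = np.array([0.0, 5.0, 25.0])
        traj = kinetics.integrate_model(p, 100, t)
        np.testing.assert_allclose(traj.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(traj[:, 3]) > 0)

    def test_mass_conservation_and_monotonicity(self):
        t = np.linspace(0.0, 600.0, 50)
        for length in LENGTHS:
            traj = kinetics.integrate_model(TRUE, length, t)
            np.testing.assert_allclose(traj.sum(axis=1), 1.0, atol=1e-9)
            assert np.all(traj >= 0)
            assert np.all(np.diff(traj[:, 3]) >= -1e-12)

    def test_observable_plateaus_at_active_fraction(self):
        fs = kinetics.full_site_fraction(TRUE, 4361, [1e5])
        assert fs[0] == pytest.approx(TRUE.f_active, abs=1e-6)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            kinetics.KineticParameters(f_active=0.5, k_on={100: -0.1}, k_hs=0.1, k_fs=0.1)
        with pytest.raises(ValueError):
            kinetics.integrate_model(TRUE, 4361, [3.0, 1.0])
        with pytest.raises(KeyError):
            kinetics.integrate_model(TRUE, 9999, [0.0, 1.0])


class TestGlobalFit:
    def test_noiseless_self_consistency(self):
        tab = synthetic.simulate_ensemble_kinetics(TRUE, LENGTHS, TIMES,
                                                   noise_sd=0.0, replicates=1)
        datasets = {L: g for L, g in tab.groupby("length_bp")}
        res = kinetics.global_fit(datasets, multistart=3)
        assert res.success
        assert res.params.f_active == pytest.approx(TRUE.f_active, rel=0.01)
        assert res.params.k_hs == pytest.approx(TRUE.k_hs, rel=0.01)
        assert res.params.k_fs == pytest.approx(TRUE.k_fs, rel=0.01)
        for L in LENGTHS:
            assert res.params.k_on[L] == pytest.approx(TRUE.k_on[L], rel=0.01)

    def test_noisy_recovery_within_ci(self):
        """Shared parameters recovered within 95% CI on the 4-length design."""
        hits = 0
        for seed in range(10):
            tab = synthetic.simulate_ensemble_kinetics(TRUE, LENGTHS, TIMES,
                                                       noise_sd=0.05, replicates=3,
                                                       seed=seed)
            datasets = {L: g for L, g in tab.groupby("length_bp")}
            res = kinetics.global_fit(datasets, multistart=1, seed=seed)
            ok = abs(res.params.f_active - TRUE.f_active) <= 1.96 * res.se["f_active"]
            hits += ok
        assert hits >= 8

    def test_single_length_still_fits(self):
        tab = synthetic.simulate_ensemble_kinetics(TRUE, [4361], TIMES,
                                                   noise_sd=0.02, replicates=3, seed=1)
        datasets = {L: g for L, g in tab.groupby("length_bp")}
        res = kinetics.global_fit(datasets, multistart=1)
        assert res.success  # degenerate design runs; uncertainty is just wide

    def test_zero_sd_replaced_not_fatal(self):
        tab = synthetic.simulate_ensemble_kinetics(TRUE, [4361, 7249], TIMES,
                                                   noise_sd=0.0, replicates=1)
        datasets = {L: g for L, g in tab.groupby("length_bp")}
        res = kinetics.global_fit(datasets, multistart=1)
        assert np.isfinite(res.ssr)


class TestProfileIdentifiability:
    def test_k_off_profile_is_flat_below_1e4(self):
        tab = synthetic.simulate_ensemble_kinetics(TRUE, [1800, 4361], TIMES,
                                                   noise_sd=0.02, replicates=3, seed=3)
        datasets = {L: g for L, g in tab.groupby("length_bp")}
        grid, ssr = kinetics.profile_identifiability(
            datasets, "k_off", [1e-10, 1e-7, 1e-5, 1e-4]
        )
        assert ssr.max() - ssr.min() < 2.0

    def test_k_hs_profile_is_convex_at_truth(self):
        tab = synthetic.simulate_ensemble_kinetics(TRUE, [1800, 4361], TIMES,
                                                   noise_sd=0.02, replicates=3, seed=4)
        datasets = {L: g for L, g in tab.groupby("length_bp")}
        grid = np.array([0.01, 0.03, 0.05, 0.1, 0.2])
        _, ssr = kinetics.profile_identifiability(datasets, "k_hs", grid)
        assert np.argmin(ssr) in (1, 2, 3)  # minimum near the generating 0.05
        assert ssr[0] > ssr.min() and ssr[-1] > ssr.min()

    def test_single_point_grid(self):
        tab = synthetic.simulate_ensemble_kinetics(TRUE, [4361], TIMES,
                                                   noise_sd=0.02, replicates=3, seed=5)
        datasets = {L: g for L, g in tab.groupby("length_bp")}
        grid, ssr = kinetics.profile_identifiability(datasets, "k_fs", [0.02])
        assert grid.size == ssr.size == 1

    def test_unknown_parameter_rejected(self):
        tab = synthetic.simulate_ensemble_kinetics(TRUE, [4361], TIMES,
                                                   noise_sd=0.02, replicates=3, seed=6)
        datasets = {L: g for L, g in tab.groupby("length_bp")}
        with pytest.raises(ValueError):
            kinetics.profile_identifiability(datasets, "k_nope", [0.1])
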