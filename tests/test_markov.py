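"""Interval-censored Markov estimation: closed forms, recovery, bootstrap."""
import numpy as np
import pytest

from morbiditrail.markov import (
    PanelDataError,
    build_intensity_matrix,
    compare_absorption_times,
    expected_absorption_time,
    fit_discrete,
    fit_intensities,
    interval_counts,
    simulate_observations,
    transition_probabilities,
)
from morbiditrail.states import build_state_space
from morbiditrail.synthetic import SyntheticConfig, trajectory_oracle

SPACE = build_state_space()


def q_single_edge(rate, i=6, j=9):
    return build_intensity_matrix({(i, j): rate}, SPACE)


class TestTransitionProbabilities:
    def test_zero_horizon_is_identity(self):
        Q = SyntheticConfig().true_Q
        np.testing.assert_allclose(transition_probabilities(Q, 0.0), np.eye(9), atol=1e-12)

    def test_negative_horizon_rejected(self):
        with pytest.raises(ValueError):
            transition_probabilities(np.zeros((9, 9)), -1.0)

    def test_chapman_kolmogorov(self):
        Q = SyntheticConfig().true_Q
        P5 = transition_probabilities(Q, 5.0)
        P10 = transition_probabilities(Q, 10.0)
        np.testing.assert_allclose(P5 @ P5, P10, atol=1e-10)

    def test_two_state_stay_probability_closed_form(self):
        P = transition_probabilities(q_single_edge(0.1), 5.0)
        assert P[5, 5] == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert P[5, 8] == pytest.approx(1 - np.exp(-0.5), abs=1e-12)

    def test_rows_stochastic_and_absorbing_row_unit(self):
        Q = SyntheticConfig().true_Q
        for t in (1.0, 5.0, 20.0):
            P = transition_probabilities(Q, t)
            np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-8)
            np.testing.assert_allclose(P[8], np.eye(9)[8], atol=1e-12)

    def test_trio_mass_nondecreasing_in_time(self):
        Q = SyntheticConfig().true_Q
        horizons = np.linspace(0, 40, 21)
        mass = np.array([transition_probabilities(Q, t)[:, 8] for t in horizons])
        assert (np.diff(mass, axis=0) >= -1e-12).all()


class TestAbsorptionTime:
    def test_from_absorbing_state_is_zero(self):
        assert expected_absorption_time(SyntheticConfig().true_Q, 9) == 0.0

    def test_linear_chain_sum_of_exponential_means(self):
        Q = build_intensity_matrix({(3, 6): 0.5, (6, 9): 0.25}, SPACE)
        assert expected_absorption_time(Q, 3) == pytest.approx(6.0, abs=1e-8)

    def test_doubling_rates_halves_times(self):
        Q = SyntheticConfig().true_Q
        tau = expected_absorption_time(Q)
        tau2 = expected_absorption_time(2 * Q)
        np.testing.assert_allclose(tau2[:8], tau[:8] / 2, rtol=1e-10)

    def test_unreachable_state_gets_infinite_time(self):
        Q = q_single_edge(0.3)  # only 6→9 active
        tau = expected_absorption_time(Q)
        assert np.isinf(tau[0]) and np.isinf(tau[4])
        assert tau[5] == pytest.approx(1 / 0.3)

    def test_dual_state_no_slower_than_constituent_single(self):
        tau = expected_absorption_time(SyntheticConfig().true_Q)
        assert tau[5] <= tau[2] and tau[5] <= tau[3]  # 6 vs 3 and 4
        assert tau[7] <= tau[3] and tau[7] <= tau[4]  # 8 vs 4 and 5

    def test_monte_carlo_first_passage_agrees(self, rng):
        from morbiditrail.synthetic import _gillespie_trajectory

        Q = SyntheticConfig().true_Q
        n = 10_000
        times = np.empty(n)
        for k in range(n):
            jt, js = _gillespie_trajectory(Q, 4, 10_000.0, rng)
            assert js[-1] == 9
            times[k] = jt[-1]
        mc, se = times.mean(), times.std(ddof=1) / np.sqrt(n)
        assert abs(mc - expected_absorption_time(Q, 4)) < 3 * se


class TestFitting:
    def test_no_transitions_gives_boundary_solution(self):
        seqs = [(f"p{k}", np.array([0.0, 2.0, 4.0]), np.array([3, 3, 3])) for k in range(20)]
        fit = fit_intensities(seqs, SPACE, compute_se=False, n_starts=1)
        assert fit.Q[2, 5] < 1e-4 and fit.Q[2, 6] < 1e-4
        assert "boundary" in fit.message

    def test_interval_censored_mle_matches_closed_form(self):
        # 500 unit intervals from state 6, 50 ending in state 9:
        # single-edge chain has stay-probability exp(-q), so the MLE is
        # q = -log(1 - 50/500), close to the crude rate 0.1/yr.
        seqs = [(f"s{k}", np.array([0.0, 1.0]), np.array([6, 6])) for k in range(450)]
        seqs += [(f"e{k}", np.array([0.0, 1.0]), np.array([6, 9])) for k in range(50)]
        fit = fit_intensities(seqs, SPACE, compute_se=True, n_starts=1)
        q = fit.Q[5, 8]
        assert q == pytest.approx(-np.log(0.9), rel=1e-4)
        assert q == pytest.approx(0.1, rel=0.06)
        # SE from observed information ≈ binomial delta method
        p = 0.1
        se_expected = np.sqrt(p * (1 - p) / 500) / (1 - p)
        assert fit.se_Q[5, 8] == pytest.approx(se_expected, rel=0.05)

    def test_impossible_observed_pair_names_participant(self):
        seqs = [("bad", np.array([0.0, 2.0]), np.array([9, 3]))]
        with pytest.raises(PanelDataError, match="bad"):
            interval_counts(seqs, SPACE)

    def test_loglik_at_optimum_beats_perturbation(self, rng):
        cfg = SyntheticConfig(n_participants=800, seed=5)
        from morbiditrail.synthetic import generate_panel
        from morbiditrail.markov import panel_to_sequences_fast, _nll_factory

        panel, _ = generate_panel(cfg, mode="discrete")
        seqs = panel_to_sequences_fast(panel)
        counts = interval_counts(seqs, SPACE)
        edges_idx = np.array([(i - 1, j - 1) for i, j in SPACE.edges])
        nll = _nll_factory(counts, edges_idx)
        theta_true = np.log(cfg.true_Q[edges_idx[:, 0], edges_idx[:, 1]])
        for _ in range(5):
            perturbed = theta_true + rng.normal(0, 0.5, size=len(theta_true))
            assert nll(theta_true) < nll(perturbed)

    def test_fit_discrete_rows_stochastic(self):
        cfg = SyntheticConfig(n_participants=300, seed=6)
        from morbiditrail.synthetic import generate_panel
        from morbiditrail.markov import panel_to_sequences_fast

        panel, _ = generate_panel(cfg, mode="discrete")
        P = fit_discrete(panel_to_sequences_fast(panel), SPACE).to_numpy()
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-12)
        assert P[8, 8] == 1.0


class TestSimulatedObservations:
    def test_frozen_chain_stays_put(self, rng):
        design = (np.tile(np.arange(0, 10, 2.0), (50, 1)), np.full(50, 5),
                  np.full(50, 4, dtype=np.int64))
        seqs = simulate_observations(np.zeros((9, 9)), design, rng)
        for _, _, states in seqs:
            assert (states == 4).all()

    def test_absorbing_state_never_left(self, rng):
        Q = SyntheticConfig().true_Q * 5  # fast chain to hit state 9 often
        design = (np.tile(np.arange(0, 22, 2.0), (300, 1)), np.full(300, 11),
                  np.full(300, 1, dtype=np.int64))
        for _, _, states in simulate_observations(Q, design, rng):
            hit = np.flatnonzero(states == 9)
            if len(hit):
                assert (states[hit[0]:] == 9).all()

    def test_occupancy_matches_matrix_exponential(self, rng):
        Q = SyntheticConfig().true_Q
        n = 5_000
        design = (np.tile(np.array([0.0, 6.0]), (n, 1)), np.full(n, 2),
                  np.full(n, 1, dtype=np.int64))
        seqs = simulate_observations(Q, design, rng)
        final = np.array([s[-1] for _, _, s in seqs])
        p0 = np.eye(9)[0]
        expected = trajectory_oracle(Q, p0, 6.0)
        for s in range(1, 10):
            phat = (final == s).mean()
            se = np.sqrt(max(expected[s - 1] * (1 - expected[s - 1]), 1e-12) / n)
            assert abs(phat - expected[s - 1]) <= 3 * se + 1e-9


class TestBootstrapComparison:
    def test_zero_bootstrap_rejected(self):
        cfg = SyntheticConfig(n_participants=120, seed=7)
        from morbiditrail.synthetic import generate_panel
        from morbiditrail.markov import panel_to_sequences_fast

        panel, _ = generate_panel(cfg, mode="discrete")
        fit = fit_intensities(panel_to_sequences_fast(panel), SPACE,
                              compute_se=False, n_starts=1)
        with pytest.raises(ValueError):
            compare_absorption_times(fit, n_boot=0)

    def test_detects_faster_metabolic_pathway(self):
        # default world: MTD route genuinely faster; MTD contrasts should
        # be significant and the point ordering correct
        cfg = SyntheticConfig(n_participants=2_000, seed=8)
        from morbiditrail.synthetic import generate_panel
        from morbiditrail.markov import panel_to_sequences_fast

        panel, _ = generate_panel(cfg, mode="discrete")
        fit = fit_intensities(panel_to_sequences_fast(panel), SPACE,
                              compute_se=False, n_starts=1)
        table = compare_absorption_times(fit, n_boot=100, seed=9)
        times = dict(zip(table.times["state"], table.times["expected_years"]))
        assert times[4] < times[3] and times[4] < times[5]
        mtd_rows = table.pairwise[
            (table.pairwise["state_a"] == 4) | (table.pairwise["state_b"] == 4)
        ]
        assert (mtd_rows["p_bonferroni"] < 0.05).all()
        assert table.global_p < 0.05
        assert table.n_failed == 0
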