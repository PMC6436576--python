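"""Belief arithmetic, value tables, softmax choice, and ideal-agent policies."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import costedbeads as cb


class TestPosterior:
    @pytest.mark.parametrize(
        "n_d,n_g,expected,places",
        [
            (20, 12, 0.835, 3),  # full exact-ratio sequence
            (0, 0, 0.5, 12),     # equiprobable prior
            (2, 1, 0.5, 12),     # balanced evidence
            (1, 1, 0.6, 12),     # one majority fish
        ],
    )
    def test_reference_values(self, n_d, n_g, expected, places):
        assert cb.posterior_gold(n_d, n_g, 0.6) == pytest.approx(expected, abs=10**-places / 2)

    @given(n_d=st.integers(0, 40), frac=st.floats(0, 1))
    def test_complement_symmetry(self, n_d, frac):
        n_g = int(round(frac * n_d))
        p = cb.posterior_gold(n_d, n_g) + cb.posterior_gold(n_d, n_d - n_g)
        assert p == pytest.approx(1.0)

    @given(n_d=st.integers(1, 40))
    def test_strictly_increasing_in_gold_count(self, n_d):
        vals = cb.posterior_gold(np.full(n_d + 1, n_d), np.arange(n_d + 1))
        assert np.all(np.diff(vals) > 0)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValueError):
            cb.posterior_gold(2, 3)


class TestDeclareValues:
    def test_hand_evaluated_states(self, blocks, config):
        b2 = blocks[1]
        assert cb.declare_values(2, 1, b2, config) == pytest.approx((0.0, 0.0))
        assert cb.declare_values(1, 1, b2, config) == pytest.approx((20.0, -20.0))
        q_dg, q_db = cb.declare_values(20, 12, b2, config)
        assert (round(q_dg, 1), round(q_db, 1)) == (67.0, -67.0)


class TestSoftmax:
    def test_symmetry_and_limits(self):
        assert cb.action_probabilities((0.0, 0.0, 0.0), 3.0) == pytest.approx([1 / 3] * 3)
        cold = cb.action_probabilities((10.0, 0.0, 5.0), 1e-9)
        assert cold == pytest.approx([1.0, 0.0, 0.0], abs=1e-12)
        hot = cb.action_probabilities((10.0, 0.0, 5.0), 1e9)
        assert hot == pytest.approx([1 / 3] * 3, abs=1e-6)

    def test_absent_action_gets_zero_probability(self):
        p = cb.action_probabilities((5.0, -5.0, np.nan), 2.0)
        assert p[2] == 0.0 and p.sum() == pytest.approx(1.0)

    def test_parameter_domain(self):
        with pytest.raises(ValueError):
            cb.action_probabilities((1.0, 2.0, 3.0), 0.0)
        with pytest.raises(ValueError):
            cb.action_probabilities((np.inf, 0.0, 0.0), 1.0)


class TestValueTables:
    def test_zero_cost_policy_samples_everywhere(self, blocks, config):
        table = cb.solve_value_table(blocks[1], config)
        for n_d in range(1, config.draw_cap):
            for n_g in range(n_d + 1):
                assert table.greedy_action(n_d, n_g) == "S"

    def test_prohibitive_cost_declares_immediately(self, blocks, config):
        table = cb.solve_value_table(blocks[1], config, subjective_cost=200.0)
        assert table.greedy_action(1, 0) == "DB" and table.greedy_action(1, 1) == "DG"

    def test_flat_cost_threshold_is_two(self, blocks, config):
        table = cb.solve_value_table(blocks[2], config)
        assert cb.declare_threshold(table) == 2

    def test_sampling_value_dominates_at_zero_cost(self, blocks, config):
        # E[V(next)] >= value of declaring now: the max of linear functions
        # of the belief is convex, and the posterior is a martingale.
        table = cb.solve_value_table(blocks[1], config)
        for n_d in range(1, config.draw_cap):
            q = table.Q[n_d, : n_d + 1]
            assert np.all(q[:, 2] >= np.max(q[:, :2], axis=1) - 1e-9)

    def test_softmax_state_values_bounded_by_max(self, blocks, config):
        vmax = cb.solve_value_table(blocks[2], config).V
        for T in (0.5, 3.0, 20.0):
            vsoft = cb.solve_value_table(blocks[2], config, mode="softmax", temperature=T).V
            assert np.all(vsoft[~np.isnan(vsoft)] <= vmax[~np.isnan(vmax)] + 1e-9)

    def test_sampling_unavailable_at_cap(self, blocks, config):
        table = cb.solve_value_table(blocks[1], config)
        assert np.isnan(table.Q[config.draw_cap, 0, 2])

    def test_softmax_mode_requires_temperature(self, blocks, config):
        with pytest.raises(ValueError):
            cb.solve_value_table(blocks[1], config, mode="softmax", temperature=0.0)


class TestIdealAgent:
    def test_policy_stats_per_block(self, blocks, config):
        seqs = cb.generate_sequences(config, 10, exact_ratio=True, seed=7)
        s1, s2, s3, s4 = cb.ideal_policy_stats(blocks, seqs, config)
        assert s1.mean_dtd == s2.mean_dtd == 20.0
        assert s1.mean_accuracy == pytest.approx(0.835, abs=5e-4)
        assert s4.mean_dtd == 1.0
        assert s4.mean_accuracy == pytest.approx(0.6)
        assert 1.0 <= s3.mean_dtd <= 20.0
        # full-sequence declarations follow the exact 12/8 majority, so the
        # no-cost blocks are always correct and earn the full 1000 points
        assert s1.frac_correct == 1.0 and s1.total_points == 1000.0

    def test_flat_cost_accuracy_matches_gamblers_ruin(self, blocks, config):
        table = cb.solve_value_table(blocks[2], config)
        exact = cb.policy_outcome_exact(table, config)
        assert abs(exact["p_correct"] - 9 / 13) < 0.002
        assert round(exact["p_correct"], 3) == 0.692

    def test_escalating_cost_guesses_after_first_fish(self, blocks, config):
        table = cb.solve_value_table(blocks[3], config)
        exact = cb.policy_outcome_exact(table, config)
        assert exact["mean_dtd"] == 1.0
        assert exact["p_correct"] == pytest.approx(0.6)


class TestSimulateAgent:
    def test_deterministic_under_seed(self, blocks, config):
        seqs = {b.block_id: cb.generate_sequences(config, 5, seed=2) for b in blocks}
        params = cb.SubjectParams(cs=1.0, temperature=2.0)
        a = cb.simulate_agent(params, blocks, seqs, config, seed=9)
        b = cb.simulate_agent(params, blocks, seqs, config, seed=9)
        assert a == b

    def test_cost_extremes_drive_draws(self, blocks, config):
        # At zero cost the low-temperature agent keeps sampling wherever
        # sampling is strictly better; only on extreme-evidence paths, where
        # sampling and declaring are exactly tied, may it stop early (the
        # softmax splits ties ~50/50), so draws are long and every early
        # declaration follows the posterior mode.
        seqs = cb.generate_sequences(config, 8, seed=2)
        free = cb.SubjectParams(cs=0.0, temperature=1e-4)
        recs = cb.simulate_agent(free, blocks[:1], seqs, config, seed=0)
        assert min(r.dtd for r in recs) >= 8
        assert np.mean([r.dtd for r in recs]) > 12
        for r in recs:
            diff = 2 * r.n_gold - r.dtd
            assert r.declared_lake == ("G" if diff > 0 else "B")
            assert r.dtd == config.draw_cap or abs(diff) >= 2
        costly = cb.SubjectParams(cs=500.0, temperature=1.0)
        recs = cb.simulate_agent(costly, blocks[:1], seqs, config, seed=0)
        assert {r.dtd for r in recs} == {1}
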