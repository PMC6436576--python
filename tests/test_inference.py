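"""Likelihood evaluation, hierarchical EM, and model comparison plumbing."""

import numpy as np
import pytest

import costedbeads as cb


def _uncapped_record(dtd=5):
    colors = ("g" * dtd)[:dtd]
    return cb.TrialRecord("s", "g", 2, 1, colors, ("S",) * (dtd - 1) + ("DG",))


class TestTrialLoglik:
    def test_uniform_limit_at_high_temperature(self, blocks, config):
        rec = _uncapped_record(5)
        params = cb.SubjectParams(cs=1.0, temperature=1e7)
        ll = cb.trial_loglik(rec, params, blocks[1], config)
        assert ll == pytest.approx(5 * np.log(1 / 3), rel=1e-4)

    def test_greedy_record_at_low_temperature(self, blocks, config):
        # flat-cost block, CS=5: sample at |difference| 1, declare at 2 —
        # strictly preferred everywhere along the path, so the log
        # probability of the greedy trajectory tends to zero
        rec = cb.TrialRecord("s", "g", 3, 1, "gg", ("S", "DG"))
        params = cb.SubjectParams(cs=5.0, temperature=1e-3)
        ll = cb.trial_loglik(rec, params, blocks[2], config)
        assert -1e-6 < ll <= 0.0


class TestParamGrid:
    def test_default_grid_shape_and_monotonicity(self):
        grid = cb.ParamGrid.default()
        assert len(grid.cs_nodes) == 50 and len(grid.t_nodes) == 50
        assert np.all(np.diff(grid.cs_nodes) > 0) and np.all(np.diff(grid.t_nodes) > 0)
        assert grid.cs_weights.sum() == pytest.approx(
            grid.cs_nodes[-1] - grid.cs_nodes[0]
        )

    def test_invalid_grids_rejected(self):
        with pytest.raises(ValueError):
            cb.ParamGrid(np.array([1.0, 0.5]), np.array([1.0, 2.0]))

    def test_coverage_of_fitted_prior(self):
        # Heavy-tailed CS priors (gamma shape << 1) pile mass toward zero;
        # everything below the smallest CS node is behaviourally identical
        # to a zero cost, so only the T coverage can be held near-complete.
        grid = cb.ParamGrid.default()
        prior = cb.GroupPrior(cb.GammaMoments(1.7, 13.0), cb.GammaMoments(4.2, 13.0))
        assert grid.coverage(prior) > 0.90
        tame = cb.GroupPrior(cb.GammaMoments(2.0, 2.0), cb.GammaMoments(4.2, 13.0))
        assert grid.coverage(tame) > 0.995


class TestEmFit:
    def test_marginal_likelihood_is_nondecreasing(self, small_dataset, small_grid):
        data, _ = small_dataset
        fit = cb.em_fit(data, grouping="by-label", grid=small_grid, n_iter=15)
        for trace in fit.trace.values():
            diffs = np.diff(trace[1:])  # first step leaves the flat prior
            assert np.all(diffs >= -1e-6 * np.abs(trace[1]))

    def test_separates_cost_groups(self, small_dataset, small_grid):
        data, _ = small_dataset
        fit = cb.em_fit(data, grouping="by-label", grid=small_grid)
        assert fit.priors["high"].cs.mean > 10 * fit.priors["low"].cs.mean

    def test_degenerate_cohort_shrinks_variance(self, config, blocks):
        seqs = {b.block_id: cb.generate_sequences(config, 5, seed=4) for b in blocks[:3]}
        params = cb.SubjectParams(cs=2.0, temperature=0.5)
        records = []
        for i in range(6):
            recs = cb.simulate_agent(params, blocks[:3], seqs, config, seed=30 + i,
                                     subject_id=f"s{i}", group="g")
            records.extend(recs)
        fit = cb.em_fit(cb.Dataset(records), grid=cb.ParamGrid.default(30, 20))
        prior = fit.priors["all"]
        assert prior.cs.variance < 4.0  # far below the generic-cohort scale
        assert 0.5 < prior.cs.mean < 8.0

    def test_single_subject_dataset_runs(self, config, blocks):
        seqs = {b.block_id: cb.generate_sequences(config, 5, seed=4) for b in blocks[:3]}
        recs = cb.simulate_agent(cb.SubjectParams(2.0, 1.0), blocks[:3], seqs, config,
                                 seed=1, subject_id="only", group="g")
        fit = cb.em_fit(cb.Dataset(recs), grid=cb.ParamGrid.default(20, 15))
        assert fit.priors["all"].cs.mean > 0
        assert len(fit.subject_summaries) == 1

    def test_rejects_empty_block_selection(self, small_dataset, small_grid):
        data, _ = small_dataset
        with pytest.raises(ValueError, match="no trials"):
            cb.em_fit(data, grid=small_grid, blocks=(9,))

    def test_grid_refinement_stability(self, small_dataset):
        """Doubling the default grid density moves fitted means by < 5%."""
        data, _ = small_dataset
        coarse = cb.em_fit(data, grid=cb.ParamGrid.default(50, 50))
        fine = cb.em_fit(data, grid=cb.ParamGrid.default(100, 100))
        for attr in ("cs", "temperature"):
            a = getattr(coarse.priors["all"], attr).mean
            b = getattr(fine.priors["all"], attr).mean
            assert abs(a - b) / b < 0.05


class TestIndividualEstimates:
    def test_extreme_subject_ranks_high_and_order_invariance(self, small_dataset,
                                                             small_grid):
        data, truth = small_dataset
        fit = cb.em_fit(data, grouping="combined", grid=small_grid)
        est = cb.individual_estimates(data, fit)
        merged = est.merge(truth, on="subject_id")
        top_true = merged.loc[merged.cs.idxmax(), "subject_id"]
        ranks = merged.set_index("subject_id")["cs_median"].rank()
        assert ranks[top_true] >= 0.9 * len(merged)
        # permuting record order leaves the estimates unchanged
        shuffled = cb.Dataset(list(np.random.default_rng(0).permutation(data.records)))
        fit2 = cb.em_fit(shuffled, grouping="combined", grid=small_grid)
        est2 = cb.individual_estimates(shuffled, fit2)
        a = est.sort_values("subject_id").reset_index(drop=True)
        b = est2.sort_values("subject_id").reset_index(drop=True)
        assert np.allclose(a["cs_mean"], b["cs_mean"])

    def test_requires_combined_fit(self, small_dataset, small_grid):
        data, _ = small_dataset
        fit = cb.em_fit(data, grouping="by-label", grid=small_grid)
        with pytest.raises(ValueError):
            cb.individual_estimates(data, fit)


class TestIbicPlumbing:
    def test_mismatched_fits_rejected(self, small_dataset, small_grid):
        data, _ = small_dataset
        fc = cb.em_fit(data, grouping="combined", grid=small_grid)
        fs = cb.em_fit(data, grouping="by-label", grid=small_grid)
        with pytest.raises(ValueError):
            cb.ibic(data, small_grid, fs, fc)  # swapped order
        with pytest.raises(ValueError):
            cb.ibic(data, small_grid, fc, fs, blocks=(1,))

    def test_report_sign_convention(self, small_dataset, small_grid):
        data, _ = small_dataset
        fc = cb.em_fit(data, grouping="combined", grid=small_grid)
        fs = cb.em_fit(data, grouping="by-label", grid=small_grid)
        rep = cb.ibic(data, small_grid, fc, fs)
        assert rep.difference == pytest.approx(rep.ibic_combined - rep.ibic_separate)
        assert rep.preferred == ("separate" if rep.difference > 0 else "combined")
        assert rep.k_combined == 4 and rep.k_separate == 8
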