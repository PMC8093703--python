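"""Assessment metrics, the 30-scenario grid, and validation checks."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy import stats as sps

from intabund import (
    MCMCConfig,
    ModelComparison,
    PosteriorSummary,
    ScenarioConfig,
    TrueState,
    assess_scenario,
    compare_iam_vs_nmixture,
    generate_dataset,
    leave_one_expert_out,
    results_table,
    run_scenario,
    run_table1_grid,
    table1_grid,
)
from intabund.experiments import K_SWEEP, COVERAGE_SWEEP, M_SWEEP, \
    ABUNDANCE_SWEEP, OCCUPANCY_SWEEP, replicate_seeds


def _summary(n_cri, p_cri=(0.7, 0.9), m_cri=(8.0, 12.0)):
    table = pd.DataFrame.from_dict(
        {
            "N_total": dict(mean=np.mean(n_cri), lower=n_cri[0],
                            upper=n_cri[1], width=n_cri[1] - n_cri[0],
                            rhat=1.0),
            "p": dict(mean=np.mean(p_cri), lower=p_cri[0], upper=p_cri[1],
                      width=p_cri[1] - p_cri[0], rhat=1.0),
            "m": dict(mean=np.mean(m_cri), lower=m_cri[0], upper=m_cri[1],
                      width=m_cri[1] - m_cri[0], rhat=1.0),
        },
        orient="index",
    )
    return PosteriorSummary(table=table)


def _truth(total=2000):
    n = np.zeros(20, dtype=np.int64)
    n[:16] = total // 16
    n[0] += total - n.sum()
    return TrueState(z=(n > 0).astype(np.int64), N=n, omega=0.8, total=total)


class TestAssessScenario:
    def test_truth_inside_cri_counts_as_accurate(self):
        res = assess_scenario([_summary((1900.0, 2100.0))], [_truth()],
                              m_true=10.0)
        assert res.accuracy["N_total"] == 1.0

    def test_all_replicates_capturing_gives_one(self):
        summaries = [_summary((1900.0, 2100.0))] * 100
        res = assess_scenario(summaries, [_truth()] * 100, m_true=10.0)
        assert res.accuracy["N_total"] == 1.0
        assert res.n_replicates == 100

    def test_zero_misidentification_special_rule(self):
        tight = _summary((1900.0, 2100.0), m_cri=(0.0, 0.3))
        loose = _summary((1900.0, 2100.0), m_cri=(0.0, 0.7))
        res = assess_scenario([tight, loose], [_truth()] * 2, m_true=0.0)
        assert res.accuracy["m"] == 0.5

    def test_width_quantiles_nondecreasing(self):
        summaries = [
            _summary((2000.0 - w, 2000.0 + w)) for w in (50, 80, 120, 200)
        ]
        res = assess_scenario(summaries, [_truth()] * 4, m_true=10.0)
        q5, q50, q95 = res.width_quantiles["N_total"]
        assert q5 <= q50 <= q95

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            assess_scenario([], [], m_true=10.0)

    def test_failure_fraction_marks_unreliable(self):
        res = assess_scenario([_summary((0.0, 1.0))], [_truth()],
                              m_true=10.0, n_failed=1)
        assert res.unreliable


class TestGrid:
    def test_exactly_thirty_scenarios(self):
        grid = table1_grid()
        assert len(grid) == 30

    def test_sweep_values_match_design(self):
        grid = table1_grid()
        by_label = {}
        for label, cfg in grid:
            by_label.setdefault(label, []).append(cfg)
        assert [c.expert_variance_scale for c in by_label["expert_variance"]] \
            == list(K_SWEEP)
        assert [c.expert_coverage for c in by_label["expert_coverage"]] \
            == list(COVERAGE_SWEEP)
        assert [c.misidentification for c in by_label["misidentification"]] \
            == list(M_SWEEP)
        assert [c.total_abundance for c in by_label["abundance"]] \
            == list(ABUNDANCE_SWEEP)
        assert [c.occupancy for c in by_label["occupancy"]] \
            == list(OCCUPANCY_SWEEP)

    def test_non_swept_parameters_stay_at_defaults(self):
        base = ScenarioConfig()
        for label, cfg in table1_grid():
            if label != "expert_variance":
                assert cfg.expert_variance_scale == base.expert_variance_scale
            if label != "misidentification":
                assert cfg.misidentification == base.misidentification
            assert cfg.n_sites == 20 and cfg.n_replicates == 10
            assert cfg.detection == 0.8

    def test_desk_scale_replicate_count(self):
        # scale = 0.25 of the nominal 100 simulations
        results = None
        grid = table1_grid(n_simulations=max(1, round(100 * 0.25)))
        assert all(cfg.n_simulations == 25 for _, cfg in grid)
        assert results is None

    def test_scale_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            run_table1_grid(scale=0.0)

    def test_tiny_full_grid_runs_and_tabulates(self):
        # one replicate per scenario exercises every scenario shape,
        # including total confounding at 100% occupancy
        results = run_table1_grid(
            MCMCConfig(n_iter=4000, burn_in=2000, seed=1), scale=0.01
        )
        assert len(results) == 30
        assert all(r.n_replicates == 1 for _, r in results)
        tab = results_table(results)
        assert len(tab) == 30 * 3 * 4  # scenario x parameter x metric
        assert set(tab["metric"]) == {
            "accuracy", "width_q5", "width_q50", "width_q95"
        }


class TestRunScenario:
    def test_single_replicate_result(self, desk_mcmc):
        cfg = ScenarioConfig(n_simulations=1, seed=5)
        res = run_scenario(cfg, desk_mcmc)
        assert res.n_replicates == 1 and res.n_failed == 0

    def test_replicate_datasets_reproducible(self):
        cfg = ScenarioConfig(n_simulations=3, seed=5)
        for rep in range(3):
            data_seed, _ = replicate_seeds(cfg, rep)
            a = generate_dataset(replace(cfg, seed=data_seed))
            b = generate_dataset(replace(cfg, seed=data_seed))
            assert np.array_equal(a.y, b.y)

    def test_bias_offsets_center_near_truth(self, desk_mcmc):
        cfg = ScenarioConfig(n_simulations=4, seed=19)
        res = run_scenario(cfg, desk_mcmc, keep_draws=True)
        assert res.bias is not None
        # pooled posterior-minus-truth for total N at baseline: small
        # relative to the ~175-wide credible intervals
        assert abs(res.bias_median["N_total"]) < 100.0
        assert abs(res.bias_median["p"]) < 0.05


class TestOccupancyConfounding:
    def test_full_occupancy_widens_m_and_p(self, desk_mcmc):
        """Without confirmed-empty sites, detection and misidentification
        are confounded: their intervals blow up while abundance holds."""
        r_partial = run_scenario(
            ScenarioConfig(occupancy=0.8, n_simulations=6, seed=41), desk_mcmc
        )
        r_full = run_scenario(
            ScenarioConfig(occupancy=1.0, n_simulations=6, seed=41), desk_mcmc
        )
        assert r_full.width_quantiles["m"][1] > 3 * r_partial.width_quantiles["m"][1]
        assert r_full.width_quantiles["p"][1] > 2 * r_partial.width_quantiles["p"][1]

    def test_abundance_width_grows_with_population(self, desk_mcmc):
        widths = []
        for total in ABUNDANCE_SWEEP:
            res = run_scenario(
                ScenarioConfig(total_abundance=total, n_simulations=5,
                               seed=51),
                desk_mcmc,
            )
            widths.append(res.width_quantiles["N_total"][1])
        rho = sps.spearmanr(ABUNDANCE_SWEEP, widths).statistic
        assert rho > 0


class TestComparison:
    def test_false_positives_separate_the_models(self, desk_mcmc):
        ds = generate_dataset(ScenarioConfig(seed=7))
        comp = compare_iam_vs_nmixture(ds, desk_mcmc)
        assert comp.nmixture_mean > comp.iam_mean
        assert not comp.cri_overlap

    def test_identical_intervals_overlap(self):
        comp = ModelComparison(
            iam_mean=100.0, iam_cri=(90.0, 110.0),
            nmixture_mean=100.0, nmixture_cri=(90.0, 110.0),
        )
        assert comp.cri_overlap

    def test_agreement_when_both_models_hold(self, desk_mcmc):
        """Without false positives the two estimates should agree.

        Agreement requires data satisfying both models' assumptions: m = 0,
        full occupancy (the baseline's homogeneous-Poisson abundance layer
        cannot represent confirmed-empty sites) and a binomial observation
        layer (Poisson replicate counts are overdispersed relative to
        binomial and inflate the baseline even at m = 0).
        """
        hits = 0
        for seed in range(5):
            ds = generate_dataset(
                ScenarioConfig(misidentification=0.0, occupancy=1.0,
                               seed=60 + seed)
            )
            rng = np.random.default_rng(1000 + seed)
            y = rng.binomial(ds.truth.N[:, None], 0.8,
                             size=ds.y.shape).astype(np.int64)
            hits += compare_iam_vs_nmixture(
                replace(ds, y=y, w_raw=None), desk_mcmc
            ).cri_overlap
        assert hits >= 4


class TestLeaveOneExpertOut:
    def test_homogeneous_data_no_flags(self, desk_mcmc):
        ds = generate_dataset(ScenarioConfig(expert_coverage=0.4, seed=23))
        loo = leave_one_expert_out(ds, desk_mcmc)
        assert len(loo.summaries) == ds.expert_mask.sum()
        assert loo.flagged_sites == []

    def test_planted_outlier_is_flagged(self, desk_mcmc):
        ds = generate_dataset(
            ScenarioConfig(expert_coverage=0.4, expert_variance_scale=0.0,
                           seed=23)
        )
        w = ds.w.copy()
        outlier = np.flatnonzero(ds.expert_mask & (ds.truth.N > 0))[0]
        w[outlier] = 900.0  # an expert count wildly above the site's truth
        corrupted = replace(ds, w=w, w_raw=None)
        loo = leave_one_expert_out(corrupted, desk_mcmc)
        assert int(outlier) in loo.flagged_sites

    def test_requires_two_expert_sites(self, desk_mcmc):
        ds = generate_dataset(ScenarioConfig(seed=23))
        mask = np.zeros_like(ds.expert_mask)
        mask[0] = True
        with pytest.raises(ValueError):
            leave_one_expert_out(replace(ds, expert_mask=mask, w_raw=None),
                                 desk_mcmc)
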