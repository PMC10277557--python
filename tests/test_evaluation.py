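"""Evaluation conventions: abstention-aware LOO metrics, percent-classified,
node-degree summaries, parameter sweeps and the stability table."""

import numpy as np
import pytest

from chronet import (
    ClassifierConfig,
    CohortSpec,
    evaluate_loo,
    generate_edge_level_cohort,
    network_degree_summary,
    percent_definite,
    random_planted_edges,
    stability_analysis,
    summarize_outcomes,
    sweep_alpha,
    sweep_threshold,
)
from chronet.containers import ECP, LCP, UNCLEAR
from chronet.datasets import (
    NETWORK_TOPOLOGIES,
    N_PARCELLATION,
    SESSION_LABELS,
    TRUE_LABELS,
    synthetic_component,
)
from chronet.evaluation import materialized_quads


class TestSummarizeOutcomes:
    def test_one_misclassified_of_38(self):
        # 16 ECP all correct; one of 22 LCP misassigned as ECP
        assigned = [ECP] * 16 + [LCP] * 22
        assigned[35] = ECP
        s = summarize_outcomes(TRUE_LABELS, assigned)
        assert round(100 * s.accuracy, 2) == 97.37
        assert s.sensitivity == 1.0
        assert round(100 * s.specificity, 1) == 95.5
        assert s.misclassification == pytest.approx(1 / 38)
        assert s.unclear == 0.0

    def test_all_unclear(self):
        s = summarize_outcomes(TRUE_LABELS, [UNCLEAR] * 38)
        assert s.accuracy == 0.0
        assert s.unclear == 1.0
        assert s.misclassification == 0.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        assigned = rng.choice([ECP, LCP, UNCLEAR], size=38).tolist()
        s = summarize_outcomes(TRUE_LABELS, assigned)
        assert s.accuracy + s.misclassification + s.unclear == pytest.approx(1.0, abs=1e-12)

    def test_balanced_accuracy_is_mean_of_sens_spec(self):
        assigned = [ECP] * 10 + [UNCLEAR] * 6 + [LCP] * 20 + [ECP] * 2
        s = summarize_outcomes(TRUE_LABELS, assigned)
        assert s.balanced_accuracy == pytest.approx((s.sensitivity + s.specificity) / 2)

    def test_na_entries_excluded(self):
        true = [ECP, ECP, LCP, LCP]
        assigned = [ECP, "NA", LCP, UNCLEAR]
        s = summarize_outcomes(true, assigned)
        assert len(s.per_subject) == 3
        assert s.accuracy == pytest.approx(2 / 3)

    def test_step_counts_tabulated(self):
        true = [ECP, ECP, LCP, LCP, LCP]
        assigned = [ECP, UNCLEAR, LCP, LCP, ECP]
        steps = [1, 1, 2, 3, 3]
        s = summarize_outcomes(true, assigned, steps)
        assert s.step_counts.loc[1, ECP] == 2
        assert s.step_counts.loc[3, LCP] == 2


class TestPercentDefinite:
    def test_reference_afternoon_column(self):
        # 11 definite labels among 37 valid entries -> 29.7
        assert percent_definite(SESSION_LABELS["afternoon_ecp_lt_lcp"]) == 29.7

    def test_reference_morning_column(self):
        # 9 definite labels among 38 valid entries -> 23.7
        assert percent_definite(SESSION_LABELS["morning_ecp_lt_lcp"]) == 23.7

    def test_all_unclear_gives_zero(self):
        assert percent_definite(["UNC"] * 10) == 0.0

    def test_all_na_errors(self):
        with pytest.raises(ValueError, match="NA"):
            percent_definite(["NA", "NA"])


class TestNetworkDegreeSummary:
    @pytest.mark.parametrize(
        "n_edges, n_nodes, expected_mean",
        [(t["n_edges"], t["n_nodes"], m)
         for t, m in zip(NETWORK_TOPOLOGIES, [1.57, 4.17, 1.51, 0.17])],
    )
    def test_reference_mean_degrees_under_divide_by_70(self, n_edges, n_nodes,
                                                       expected_mean):
        net = synthetic_component(n_edges, n_nodes)
        d = network_degree_summary(net, N_PARCELLATION)
        assert round(d.mean_degree, 2) == expected_mean
        # mean-degree identity: mean = 2E / N_total
        assert d.mean_degree == pytest.approx(2 * n_edges / N_PARCELLATION)

    def test_degrees_counted_on_actual_topology(self):
        net = synthetic_component(3, 4)  # path on 4 nodes: degrees 1,2,2,1,0...
        d = network_degree_summary(net, 6)
        assert d.max_degree == 2
        assert d.mean_degree == pytest.approx(1.0)
        assert set(d.argmax_nodes) == {1, 2}

    def test_n_total_too_small_errors(self):
        with pytest.raises(ValueError, match="n_total"):
            network_degree_summary(synthetic_component(3, 4), 3)


class TestLooEvaluation:
    def test_outcome_fractions_sum_to_one(self, small_edge_cohort, fast_cfg):
        s = evaluate_loo(small_edge_cohort, fast_cfg)
        assert s.accuracy + s.misclassification + s.unclear == pytest.approx(1.0, abs=1e-12)

    def test_loo_deterministic(self, small_edge_cohort, fast_cfg):
        a = evaluate_loo(small_edge_cohort, fast_cfg)
        b = evaluate_loo(small_edge_cohort, fast_cfg)
        assert a.per_subject.equals(b.per_subject)

    def test_small_group_errors(self):
        spec = CohortSpec(n_ecp=2, n_lcp=5, n_rois=5, subject_sd=0.1, seed=0)
        cohort = generate_edge_level_cohort(spec)
        with pytest.raises(ValueError, match="at least 3"):
            evaluate_loo(cohort, ClassifierConfig(n_perm=10, seed=0))


class TestSweepAlpha:
    def test_alpha_zero_gives_all_unclear(self, small_edge_cohort, fast_cfg):
        res = sweep_alpha(small_edge_cohort, fast_cfg, np.array([0.0, 0.05]))
        assert res.summaries[0].unclear == 1.0

    def test_accuracy_constant_above_max_pvalue(self, small_edge_cohort, fast_cfg):
        quads = materialized_quads(small_edge_cohort, fast_cfg)
        max_p = max(
            net.p_value
            for q in quads
            for net in (q.net_E_tE, q.net_L_tL, q.net_E_tL, q.net_L_tE)
            if net is not None and net.p_value is not None
        )
        lo = min(max_p + 0.01, 1.0)
        grid = np.unique(np.round(np.linspace(lo, 1.0, 5), 6))
        res = sweep_alpha(small_edge_cohort, fast_cfg, grid, quads=quads)
        accs = [s.accuracy for s in res.summaries]
        assert all(a == pytest.approx(accs[0]) for a in accs)

    def test_alpha_grid_point_matches_evaluate_loo(self, small_edge_cohort, fast_cfg):
        res = sweep_alpha(small_edge_cohort, fast_cfg, np.array([0.01, 0.05, 0.2]))
        loo = evaluate_loo(small_edge_cohort, fast_cfg)
        s = res.summaries[1]  # alpha = 0.05 with the same seeds
        assert s.accuracy == loo.accuracy
        assert s.unclear == loo.unclear
        assert s.misclassification == loo.misclassification

    def test_fraction_conservation_at_every_grid_point(self, small_edge_cohort, fast_cfg):
        res = sweep_alpha(small_edge_cohort, fast_cfg, np.array([0.0, 0.3, 0.7, 1.0]))
        for s in res.summaries:
            assert s.accuracy + s.misclassification + s.unclear == pytest.approx(1.0)


class TestSweepThreshold:
    def test_threshold_beyond_max_t_gives_all_unclear(self, small_edge_cohort, fast_cfg):
        res = sweep_threshold(small_edge_cohort, fast_cfg, np.array([0.5, 100.0]))
        assert res.summaries[-1].unclear == 1.0

    def test_grid_point_matches_fixed_threshold_classifier(self, small_edge_cohort,
                                                           fast_cfg):
        tau = 1.0
        res = sweep_threshold(small_edge_cohort, fast_cfg, np.array([0.5, tau]))
        fixed_cfg = ClassifierConfig(
            contrast=fast_cfg.contrast, alpha=fast_cfg.alpha, threshold=tau,
            n_perm=fast_cfg.n_perm, seed=fast_cfg.seed,
        )
        loo = evaluate_loo(small_edge_cohort, fixed_cfg)
        s = res.summaries[1]
        assert s.accuracy == loo.accuracy
        assert s.unclear == loo.unclear

    def test_records_correct_labeling_percolation_threshold(self, small_edge_cohort,
                                                            fast_cfg):
        res = sweep_threshold(small_edge_cohort, fast_cfg, np.array([1.0]))
        assert np.isfinite(res.extra["correct_labeling_percolation_threshold"])

    def test_definite_labels_only_under_matching_contrast(self):
        # the planted effect makes ECP partial correlations more positive:
        # only the ECP > LCP contrast should ever produce definite labels
        from chronet import Contrast

        spec = CohortSpec(n_ecp=8, n_lcp=10, n_rois=10,
                          planted_edges=random_planted_edges(10, 12, seed=5),
                          effect_size=0.25, subject_sd=0.06, seed=8)
        cohort = generate_edge_level_cohort(spec)
        grid = np.arange(0.5, 4.51, 0.5)
        match = sweep_threshold(
            cohort, ClassifierConfig(contrast=Contrast.ECP_GT_LCP, n_perm=100, seed=0),
            grid)
        oppose = sweep_threshold(
            cohort, ClassifierConfig(contrast=Contrast.ECP_LT_LCP, n_perm=100, seed=0),
            grid)
        assert max(s.accuracy for s in match.summaries) > 0.5
        assert max(s.accuracy for s in oppose.summaries) == 0.0


class TestStability:
    def test_row_count_and_fraction_conservation(self):
        spec = CohortSpec(n_ecp=4, n_lcp=5, n_rois=6,
                          planted_edges=random_planted_edges(6, 5, seed=1),
                          effect_size=0.3, subject_sd=0.1, seed=5)
        cohort = generate_edge_level_cohort(spec)
        cfg = ClassifierConfig(n_perm=30, seed=1)
        table = stability_analysis(cohort, cfg)
        assert len(table.rows) == len(cohort)
        sums = table.rows.accuracy + table.rows.unclear + table.rows.misclassification
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_row_reproducible_in_isolation(self):
        spec = CohortSpec(n_ecp=4, n_lcp=4, n_rois=6,
                          planted_edges=random_planted_edges(6, 4, seed=2),
                          effect_size=0.3, subject_sd=0.1, seed=6)
        cohort = generate_edge_level_cohort(spec)
        cfg = ClassifierConfig(n_perm=30, seed=2)
        table = stability_analysis(cohort, cfg)
        # re-running one partial dataset alone reproduces its row bit-for-bit
        r = 3
        again = evaluate_loo(cohort.without(r), cfg)
        sid = cohort.subject_ids[r]
        assert table.rows.loc[sid, "accuracy"] == again.accuracy
        assert table.rows.loc[sid, "unclear"] == again.unclear

    def test_too_small_groups_error(self):
        spec = CohortSpec(n_ecp=3, n_lcp=5, n_rois=5, subject_sd=0.1, seed=0)
        cohort = generate_edge_level_cohort(spec)
        with pytest.raises(ValueError, match="at least 4"):
            stability_analysis(cohort, ClassifierConfig(n_perm=10, seed=0))
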