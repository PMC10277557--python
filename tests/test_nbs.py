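"""NBS core: edgewise t-statistics, suprathreshold components, percolation
threshold, permutation FWE p-values and the component selection rule."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats

from chronet import (
    CohortSpec,
    Contrast,
    FunctionalNetwork,
    NetworkCohort,
    PermutationConfig,
    edge_t_statistics,
    generate_edge_level_cohort,
    percolation_threshold,
    permutation_pvalue,
    random_planted_edges,
    run_nbs,
    select_component,
    suprathreshold_components,
)
from chronet.nbs import (
    PERCOLATION,
    DysconnectedNetwork,
    TStatMatrix,
    null_max_intensities,
    verify_percolation,
)


def _nets_from_edge(values_a, values_b):
    """Cohort of 2-ROI networks with a single edge per subject."""
    nets = []
    for k, v in enumerate(values_a):
        w = np.array([[np.nan, v], [v, np.nan]])
        nets.append(FunctionalNetwork(w, subject_id=f"e{k}", label="ECP"))
    for k, v in enumerate(values_b):
        w = np.array([[np.nan, v], [v, np.nan]])
        nets.append(FunctionalNetwork(w, subject_id=f"l{k}", label="LCP"))
    return NetworkCohort(nets)


def _tmat(vals):
    v = np.asarray(vals, dtype=float)
    np.fill_diagonal(v, np.nan)
    return TStatMatrix(values=v, n_a=2, n_b=2, contrast=Contrast.ECP_GT_LCP)


class TestEdgeTStatistics:
    def test_hand_computed_pooled_t(self):
        # the hand example ECP {0, 2} vs LCP {3, 5} scaled into [-1, 1]
        # edge weights; the t-statistic is scale-invariant:
        # t = (1 - 4) / (sqrt(2) * sqrt(1/2 + 1/2)) = -3/sqrt(2)
        cohort = _nets_from_edge([0.0, 0.2], [0.3, 0.5])
        t = edge_t_statistics(cohort, contrast=Contrast.ECP_GT_LCP)
        expected = scipy.stats.ttest_ind([0.0, 0.2], [0.3, 0.5]).statistic
        assert t.values[0, 1] == pytest.approx(expected)
        assert t.values[0, 1] == pytest.approx(-3 / math.sqrt(2))

    def test_generic_oracle_on_random_cohort(self, small_edge_cohort):
        t = edge_t_statistics(small_edge_cohort, contrast=Contrast.ECP_GT_LCP)
        stack = small_edge_cohort.stack()
        labels = np.array(small_edge_cohort.labels)
        i, j = 2, 5
        ref = scipy.stats.ttest_ind(
            stack[labels == "ECP", i, j], stack[labels == "LCP", i, j]
        ).statistic
        assert t.values[i, j] == pytest.approx(ref)
        assert t.values[j, i] == pytest.approx(ref)

    def test_zero_t_for_identical_groups(self):
        cohort = _nets_from_edge([0.1, 0.3], [0.1, 0.3])
        t = edge_t_statistics(cohort)
        assert t.values[0, 1] == pytest.approx(0.0)

    def test_contrast_flip_negates(self, small_edge_cohort):
        t_gt = edge_t_statistics(small_edge_cohort, contrast=Contrast.ECP_GT_LCP)
        t_lt = edge_t_statistics(small_edge_cohort, contrast=Contrast.ECP_LT_LCP)
        np.testing.assert_allclose(t_gt.values, -t_lt.values, equal_nan=True)

    def test_degenerate_edge_gets_sentinel(self):
        cohort = _nets_from_edge([0.2, 0.2], [0.2, 0.2])
        t = edge_t_statistics(cohort)
        assert t.values[0, 1] == -np.inf

    def test_single_subject_group_errors(self):
        cohort = _nets_from_edge([0.1], [0.2, 0.3])
        with pytest.raises(ValueError, match="at least 2"):
            edge_t_statistics(cohort)


class TestSuprathresholdComponents:
    def test_above_max_gives_empty(self):
        t = _tmat([[0, 3, 2], [3, 0, 1], [2, 1, 0]])
        assert suprathreshold_components(t, 10.0) == []

    def test_three_node_example(self):
        t = _tmat([[0, 3, 2], [3, 0, 1], [2, 1, 0]])
        comps = suprathreshold_components(t, 2.0)
        assert len(comps) == 1
        comp = comps[0]
        assert set(comp.edges) == {(0, 1), (0, 2)}
        assert comp.n_edges == 2
        assert comp.intensity == pytest.approx(5.0)

    def test_below_min_gives_complete_graph(self):
        t = _tmat([[0, 3, 2], [3, 0, 1], [2, 1, 0]])
        comps = suprathreshold_components(t, 0.5)
        assert len(comps) == 1
        assert comps[0].n_edges == 3

    def test_multiple_components(self):
        v = np.full((4, 4), -5.0)
        v[0, 1] = v[1, 0] = 3.0
        v[2, 3] = v[3, 2] = 2.5
        comps = suprathreshold_components(_tmat(v), 2.0)
        assert len(comps) == 2
        assert {frozenset(c.nodes) for c in comps} == {frozenset({0, 1}), frozenset({2, 3})}


def _percolation_scan_oracle(values):
    """Linear scan over sorted unique t-values for the percolation threshold."""
    import networkx as nx

    n = values.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    ts = np.unique(values[iu, ju])
    best = None
    for tau in ts:
        g = nx.Graph()
        g.add_nodes_from(range(n))
        for i, j in zip(iu, ju):
            if values[i, j] >= tau:
                g.add_edge(i, j)
        if nx.is_connected(g):
            best = tau
    return best


class TestPercolationThreshold:
    def test_three_node_example(self):
        t = _tmat([[0, 3, 2], [3, 0, 1], [2, 1, 0]])
        tau, mcc = percolation_threshold(t)
        assert tau == pytest.approx(2.0)
        assert set(mcc.edges) == {(0, 1), (0, 2)}

    def test_all_equal_gives_complete_graph(self):
        v = np.full((4, 4), 1.5)
        tau, mcc = percolation_threshold(_tmat(v))
        assert tau == pytest.approx(1.5)
        assert mcc.n_edges == 6

    def test_matches_linear_scan_oracle_on_random_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            v = rng.normal(size=(12, 12))
            v = (v + v.T) / 2
            t = _tmat(v)
            tau, mcc = percolation_threshold(t)
            assert tau == _percolation_scan_oracle(t.values)
            assert mcc.n_nodes == 12
            assert verify_percolation(t, tau)

    def test_sentinel_isolation_errors(self):
        v = np.full((3, 3), -np.inf)
        v[0, 1] = v[1, 0] = 1.0
        with pytest.raises(ValueError, match="disconnected"):
            percolation_threshold(_tmat(v))


class TestPermutationPvalue:
    def test_observed_beats_all_nulls(self, small_edge_cohort):
        net = run_nbs(small_edge_cohort, cfg=PermutationConfig(n_perm=50, seed=0))
        # strong planted effect: no permuted max intensity should beat it
        assert net.p_value == 0.0

    def test_exhaustive_enumeration_matches_independent_oracle(self):
        spec = CohortSpec(n_ecp=3, n_lcp=3, n_rois=4,
                          planted_edges=random_planted_edges(4, 2, seed=0),
                          effect_size=0.3, subject_sd=0.1, seed=4)
        cohort = generate_edge_level_cohort(spec)
        tmat = edge_t_statistics(cohort)
        tau, mcc = percolation_threshold(tmat)
        # C(6, 3) = 20 distinct assignments -> automatic full enumeration
        p = permutation_pvalue(cohort, None, Contrast.ECP_GT_LCP, tau, mcc,
                               PermutationConfig(n_perm=1000, seed=0))
        # independent oracle: enumerate assignments, scipy t-tests,
        # networkx components
        import networkx as nx

        stack = cohort.stack()
        count = 0
        combos = list(itertools.combinations(range(6), 3))
        assert len(combos) == 20
        for combo in combos:
            a = np.zeros(6, dtype=bool)
            a[list(combo)] = True
            best = 0.0
            g = nx.Graph()
            iu, ju = np.triu_indices(4, k=1)
            tvals = {}
            for i, j in zip(iu, ju):
                t = scipy.stats.ttest_ind(stack[a, i, j], stack[~a, i, j]).statistic
                tvals[(i, j)] = t
                if t >= tau:
                    g.add_edge(i, j)
            for comp in nx.connected_components(g):
                inten = sum(t for (i, j), t in tvals.items()
                            if i in comp and j in comp and t >= tau)
                best = max(best, inten)
            if best > mcc.intensity + 1e-9:  # tolerance: oracle sums in a
                count += 1                   # different order (last-ulp ties)
        assert p == pytest.approx(count / 20)

    def test_null_distribution_size_and_determinism(self, null_edge_cohort):
        cfg = PermutationConfig(n_perm=64, seed=5)
        tmat = edge_t_statistics(null_edge_cohort)
        tau, _ = percolation_threshold(tmat)
        a = null_max_intensities(null_edge_cohort, None, Contrast.ECP_GT_LCP, tau, cfg)
        b = null_max_intensities(null_edge_cohort, None, Contrast.ECP_GT_LCP, tau, cfg)
        assert a.shape == (64,)
        np.testing.assert_array_equal(a, b)

    def test_roi_relabeling_invariance(self):
        spec = CohortSpec(n_ecp=3, n_lcp=3, n_rois=5,
                          planted_edges=frozenset({(0, 1), (2, 4)}),
                          effect_size=0.2, subject_sd=0.1, seed=6)
        cohort = generate_edge_level_cohort(spec)
        perm = np.array([3, 0, 4, 1, 2])
        permuted = NetworkCohort([
            FunctionalNetwork(n.weights[np.ix_(perm, perm)], n.subject_id, n.label)
            for n in cohort
        ])
        def p_of(c):
            tmat = edge_t_statistics(c)
            tau, mcc = percolation_threshold(tmat)
            return permutation_pvalue(c, None, Contrast.ECP_GT_LCP, tau, mcc,
                                      PermutationConfig(n_perm=100, seed=0))
        assert p_of(cohort) == p_of(permuted)


class TestSelectComponent:
    def _net(self, p, n_edges, first_node=0):
        edges = {(first_node + k, first_node + k + 1): 1.0 for k in range(n_edges)}
        return DysconnectedNetwork(edges=edges, threshold=0.0, p_value=p)

    def test_smallest_p_wins(self):
        a, b = self._net(0.03, 3), self._net(0.2, 9)
        assert select_component([a, b]) is a

    def test_p_tie_most_edges_wins(self):
        a, b = self._net(0.1, 5), self._net(0.1, 9)
        assert select_component([a, b]) is b

    def test_full_tie_lowest_node_wins_deterministically(self):
        a, b = self._net(0.1, 4, first_node=10), self._net(0.1, 4, first_node=2)
        for _ in range(3):
            assert select_component([b, a]) is b
            assert select_component([a, b]) is b

    def test_empty_gives_none(self):
        assert select_component([]) is None

    def test_missing_pvalue_errors(self):
        net = self._net(None, 2)
        with pytest.raises(ValueError, match="p-value"):
            select_component([net])


class TestRunNbs:
    def test_fixed_threshold_above_max_gives_none(self, small_edge_cohort):
        net = run_nbs(small_edge_cohort, threshold=1e6,
                      cfg=PermutationConfig(n_perm=10, seed=0))
        assert net is None

    def test_percolation_mode_spans_all_rois(self, small_edge_cohort):
        net = run_nbs(small_edge_cohort, threshold=PERCOLATION,
                      cfg=PermutationConfig(n_perm=20, seed=0))
        assert net.n_nodes == small_edge_cohort.n_rois
        assert 0.0 <= net.p_value <= 1.0

    def test_intensity_additivity(self, small_edge_cohort):
        tmat = edge_t_statistics(small_edge_cohort)
        tau, mcc = percolation_threshold(tmat)
        total = sum(tmat.values[i, j] for (i, j) in mcc.edges)
        assert mcc.intensity == pytest.approx(total, abs=1e-8)

    def test_planted_effect_detected_at_high_power(self):
        hits = 0
        for rep in range(20):
            spec = CohortSpec(n_ecp=8, n_lcp=8, n_rois=10,
                              planted_edges=random_planted_edges(10, 8, seed=1),
                              effect_size=0.4, subject_sd=0.1, seed=100 + rep)
            cohort = generate_edge_level_cohort(spec)
            net = run_nbs(cohort, cfg=PermutationConfig(n_perm=200, seed=rep))
            hits += net.p_value < 0.05
        assert hits >= 18  # >= 90% power
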