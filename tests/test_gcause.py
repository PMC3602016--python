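"""Granger causality: segmented VAR fitting, F-tests, graphs, degrees."""

import numpy as np
import pytest

from restconn import gcause, synthio
from restconn.errors import DegenerateInputError, RankError, ValidationError
from restconn.pipeline import ROI_NAMES, load_published_edges, published_degree_table


class TestSegments:
    def test_usable_rows_exclude_lag_reserve(self, rng):
        segs = [rng.standard_normal((2, 150)) for _ in range(2)]
        series = gcause.concatenate_segments(segs, ["a", "b"], order_reserve=2)
        assert series.usable_rows(2) == 2 * 148

    def test_single_segment_is_plain_var_input(self, rng):
        x = rng.standard_normal((2, 100))
        series = gcause.concatenate_segments([x], ["a", "b"])
        np.testing.assert_array_equal(series.segments[0], x)

    def test_wrong_node_count_rejected(self, rng):
        with pytest.raises(ValidationError):
            gcause.concatenate_segments(
                [rng.standard_normal((2, 50)), rng.standard_normal((3, 50))], ["a", "b"]
            )


class TestFitVar:
    def test_noiseless_recurrence_recovered_exactly(self):
        x = np.empty(100)
        x[0] = 1.0
        for t in range(1, 100):
            x[t] = 0.5 * x[t - 1]
        series = gcause.SegmentedSeries(("a",), [x[None, :]])
        model = gcause.fit_var(series, 1)
        assert model.coeffs[0, 0, 0] == pytest.approx(0.5, abs=1e-10)
        assert model.rss[0] == pytest.approx(0.0, abs=1e-18)

    def test_cross_coefficient_consistent(self):
        spec = synthio.CausalSpec(
            1, np.array([[[0.3, 0.0], [0.8, 0.3]]]), np.ones(2)
        )
        x = synthio.simulate_var_timecourses(2000, spec, seed=4)
        model = gcause.fit_var(gcause.SegmentedSeries(("a", "b"), [x]), 1)
        # coeffs[lag][target][source]: influence of a on b
        assert 0.75 <= model.coeffs[0, 1, 0] <= 0.85

    def test_duplicated_node_raises_rank_error(self, rng):
        x = rng.standard_normal(200)
        series = gcause.SegmentedSeries(("a", "b"), [np.stack([x, x])])
        with pytest.raises(RankError):
            gcause.fit_var(series, 1)

    def test_segment_boundary_matches_block_ols_oracle(self, rng):
        """Pooled segmented fit equals explicit block OLS and differs from a
        naive concatenation that regresses across the seam."""
        seg1 = rng.standard_normal((2, 80))
        seg2 = rng.standard_normal((2, 80))
        series = gcause.SegmentedSeries(("a", "b"), [seg1, seg2])
        model = gcause.fit_var(series, 2)
        # oracle: build the two design blocks by hand and solve jointly
        xs, ys = [], []
        for seg in (seg1, seg2):
            rows = seg.shape[1] - 2
            x = np.empty((rows, 4))
            x[:, 0:2] = seg[:, 1:-1].T  # lag 1
            x[:, 2:4] = seg[:, 0:-2].T  # lag 2
            xs.append(x)
            ys.append(seg[:, 2:].T)
        beta = np.linalg.lstsq(np.concatenate(xs), np.concatenate(ys), rcond=None)[0]
        for lag in range(2):
            np.testing.assert_allclose(
                model.coeffs[lag], beta[2 * lag : 2 * lag + 2, :].T, atol=1e-10
            )
        # naive concatenation crossing the seam gives different estimates
        naive = gcause.fit_var(
            gcause.SegmentedSeries(("a", "b"), [np.concatenate([seg1, seg2], axis=1)]), 2
        )
        assert not np.allclose(naive.coeffs, model.coeffs)

    def test_n_obs_accounting(self, rng):
        series = gcause.SegmentedSeries(("a",), [rng.standard_normal((1, 50)) for _ in range(3)])
        assert gcause.fit_var(series, 3).n_obs == 3 * 47


class TestOrderSelection:
    def test_var2_recovered(self):
        a1 = np.array([[0.3, 0.0], [0.2, 0.3]])
        a2 = np.array([[0.25, 0.15], [0.0, 0.25]])
        spec = synthio.CausalSpec(2, np.stack([a1, a2]), np.ones(2))
        hits = 0
        for seed in range(20):
            x = synthio.simulate_var_timecourses(500, spec, seed=seed)
            series = gcause.SegmentedSeries(("a", "b"), [x])
            hits += gcause.select_order_bic(series, 5) == 2
        assert hits >= 18

    def test_white_noise_prefers_smallest_order(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal((2, 400))
            series = gcause.SegmentedSeries(("a", "b"), [x])
            hits += gcause.select_order_bic(series, 5) == 1
        assert hits >= 16

    def test_excessive_order_rejected(self, rng):
        series = gcause.SegmentedSeries(("a",), [rng.standard_normal((1, 40))])
        with pytest.raises(ValidationError):
            gcause.select_order_bic(series, 9)


class TestGrangerF:
    def test_driven_pair_detected_one_direction(self):
        spec = synthio.CausalSpec(1, np.array([[[0.3, 0.0], [0.8, 0.3]]]), np.ones(2))
        x = synthio.simulate_var_timecourses(2000, spec, seed=9)
        series = gcause.SegmentedSeries(("a", "b"), [x])
        forward = gcause.granger_f(series, "a", "b", 1)
        backward = gcause.granger_f(series, "b", "a", 1)
        assert forward.p_value < 1e-6
        assert backward.p_value > 1e-4
        assert forward.f_score > backward.f_score

    def test_deterministic_copy_flagged(self):
        x = np.sin(np.arange(301) / 5)
        # b is exactly a shifted by one lag (no wrap-around)
        series = gcause.SegmentedSeries(("a", "b"), [np.stack([x[1:], x[:-1]])])
        with pytest.warns(RuntimeWarning):
            edge = gcause.granger_f(series, "b", "a", 1)
        assert np.isinf(edge.f_score) and edge.p_value == 0.0

    def test_rss_restricted_at_least_full(self, rng):
        x = rng.standard_normal((2, 300))
        series = gcause.SegmentedSeries(("a", "b"), [x])
        edge = gcause.granger_f(series, "a", "b", 3)
        assert edge.f_score >= 0.0

    def test_self_edge_rejected(self, rng):
        series = gcause.SegmentedSeries(("a", "b"), [rng.standard_normal((2, 100))])
        with pytest.raises(ValidationError):
            gcause.granger_f(series, "a", "a", 1)


class TestPairwise:
    @pytest.mark.parametrize("k,expected", [(4, 12), (8, 56)])
    def test_edge_count(self, rng, k, expected):
        names = [f"n{i}" for i in range(k)]
        series = gcause.SegmentedSeries(tuple(names), [rng.standard_normal((k, 200))])
        assert len(gcause.pairwise_granger(series, 1)) == expected

    def test_deterministic_source_major_order(self, rng):
        series = gcause.SegmentedSeries(("a", "b", "c"), [rng.standard_normal((3, 100))])
        edges = gcause.pairwise_granger(series, 1)
        assert [(e.source, e.target) for e in edges] == [
            ("a", "b"), ("a", "c"), ("b", "a"), ("b", "c"), ("c", "a"), ("c", "b"),
        ]

    def test_mediated_chain_can_show_direct_edge(self):
        """Pairwise (bivariate) testing cannot distinguish a -> c mediation
        through b from a direct a -> c influence; the conditional mode can."""
        coeffs = np.zeros((1, 3, 3))
        coeffs[0] = np.diag([0.3, 0.3, 0.3])
        coeffs[0, 1, 0] = 0.8  # a -> b
        coeffs[0, 2, 1] = 0.8  # b -> c
        spec = synthio.CausalSpec(1, coeffs, np.ones(3))
        x = synthio.simulate_var_timecourses(4000, spec, seed=12)
        series = gcause.SegmentedSeries(("a", "b", "c"), [x])
        pair_ac = gcause.granger_f(series.subset(["a", "c"]), "a", "c", 2)
        cond_ac = gcause.granger_f(series, "a", "c", 2)
        assert pair_ac.p_value < 0.01  # mediated edge appears in bivariate GC
        assert cond_ac.p_value > pair_ac.p_value  # conditioning weakens it


class TestGraphs:
    def test_all_null_pvalues_give_empty_graph(self):
        edges = [gcause.CausalEdge("a", "b", 1.0, 0.5), gcause.CausalEdge("b", "a", 1.0, 0.5)]
        graph = gcause.build_causal_graph(edges, 0.01)
        assert graph.edges == []

    def test_minimum_p_survives_among_many(self, rng):
        edges = [
            gcause.CausalEdge(f"n{i}", f"n{j}", 1.0, 0.6 + 0.3 * rng.uniform())
            for i in range(8) for j in range(8) if i != j
        ][:55]
        edges.append(gcause.CausalEdge("n0", "n7", 50.0, 1e-9))
        graph = gcause.build_causal_graph(edges, 0.001)
        assert graph.edge_set() == {("n0", "n7")}

    def test_empty_edge_list_rejected(self):
        with pytest.raises(ValidationError):
            gcause.build_causal_graph([], 0.01)


class TestDegrees:
    def test_published_abstinence_degrees(self):
        table = published_degree_table("abstinence")
        assert table.nodes == ROI_NAMES
        assert table.out_in.tolist() == [2, -3, 2, -2, 1, 0, 2, -2]

    def test_published_satiety_degrees(self):
        table = published_degree_table("satiety")
        assert table.out_in.tolist() == [-1, 0, 3, -1, 0, -1, 0, 0]

    def test_empty_graph_all_zero(self):
        graph = gcause.CausalGraph(("a", "b"), [], q=0.01)
        table = gcause.out_in_degree(graph)
        assert table.out_in.tolist() == [0, 0]

    def test_single_edge(self):
        graph = gcause.CausalGraph(("a", "b", "c"), [gcause.CausalEdge("a", "b", 2.0, 0.001)], 0.01)
        assert gcause.out_in_degree(graph).as_dict() == {
            "a": (1, 0, 1), "b": (0, 1, -1), "c": (0, 0, 0)
        }

    @pytest.mark.parametrize("condition", ["abstinence", "satiety"])
    def test_out_in_sums_to_zero(self, condition):
        table = published_degree_table(condition)
        assert int(table.out_in.sum()) == 0

    def test_edge_lists_have_expected_sizes(self):
        assert len(load_published_edges("abstinence")) == 24
        assert len(load_published_edges("satiety")) == 26


class TestFullRoute:
    def test_type_one_error_of_fdr_pipeline(self):
        """On null cohorts the FDR'd edge family rejects anything at all in
        well under q of the replicates (familywise over 12 edges)."""
        false_any = 0
        n_rep = 60
        for seed in range(n_rep):
            rng = np.random.default_rng(seed + 10_000)
            segs = [rng.standard_normal((4, 120)) for _ in range(4)]
            graph, _, _ = gcause.effective_connectivity(
                segs, ["w", "x", "y", "z"], q=0.05, order=1
            )
            false_any += bool(graph.edges)
        assert false_any / n_rep <= 0.15

    def test_planted_coefficients_within_two_se(self):
        spec = synthio.default_causal_specs()["abstinence"]
        segs = [
            synthio.simulate_var_timecourses(150, spec, seed=s) for s in range(21)
        ]
        series = gcause.concatenate_segments(segs, synthio.NETWORK_NAMES, order_reserve=2)
        model = gcause.fit_var(series, 2)
        x, _ = gcause._lagged_design(series, 2)
        xtx_inv = np.linalg.inv(x.T @ x)
        for lag in range(2):
            for tgt in range(4):
                sigma2 = model.rss[tgt] / (model.n_obs - 8)
                for src in range(4):
                    se = np.sqrt(sigma2 * xtx_inv[lag * 4 + src, lag * 4 + src])
                    err = abs(model.coeffs[lag, tgt, src] - spec.coeffs[lag, tgt, src])
                    assert err < 3 * se + 1e-9
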