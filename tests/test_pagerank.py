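"""PageRank power iteration: analytic cases, oracle and networkx cross-checks."""

import numpy as np
import pytest

from citerank.errors import EmptyGraphError, GraphSizeError
from citerank.graph import CitationGraph, build_inverted_index, from_edges
from citerank.pagerank import (
    PageRankParams,
    compute_pagerank,
    pagerank_oracle,
    read_scores,
    write_scores,
)
from citerank.simulate import GrowthParams, generate_network

# Tight tolerance used when the iteration must be resolved far below the
# default stopping rule, e.g. to compare against the exact dense solve.
TIGHT = PageRankParams(epsilon=1e-12, max_iterations=2000)


def scores_array(vector, nodes):
    return np.array([vector.scores[p] for p in nodes])


class TestAnalyticCases:
    def test_single_node_holds_all_mass(self):
        g = CitationGraph(nodes=(7,), edges=(), sources=frozenset({7}))
        v = compute_pagerank(g)
        assert v.scores[7] == pytest.approx(1.0, abs=1e-12)
        assert v.converged and v.iterations <= 2

    def test_two_cycle_splits_evenly(self, two_cycle):
        v = compute_pagerank(two_cycle)
        assert v.scores[1] == pytest.approx(0.5, abs=1e-12)
        assert v.scores[2] == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("k", [3, 5, 12])
    def test_k_cycle_is_uniform(self, k):
        g = from_edges([(i, (i % k) + 1) for i in range(1, k + 1)])
        v = compute_pagerank(g)
        for p in g.nodes:
            assert v.scores[p] == pytest.approx(1.0 / k, abs=1e-12)

    def test_chain_matches_oracle(self, chain3):
        v = compute_pagerank(chain3, TIGHT)
        o = pagerank_oracle(chain3)
        np.testing.assert_allclose(
            scores_array(v, chain3.nodes), scores_array(o, chain3.nodes), atol=1e-8
        )

    def test_isolated_node_gets_only_teleport_and_dangling_share(self, isolated_plus_cycle):
        v = compute_pagerank(isolated_plus_cycle, TIGHT)
        o = pagerank_oracle(isolated_plus_cycle)
        nodes = isolated_plus_cycle.nodes
        np.testing.assert_allclose(scores_array(v, nodes), scores_array(o, nodes), atol=1e-8)
        # the isolated node is strictly poorest: no inbound citations
        assert v.scores[3] < v.scores[1]

    def test_star_hub_outranks_leaves(self, star5):
        v = compute_pagerank(star5)
        assert all(v.scores[10] > v.scores[leaf] for leaf in range(1, 6))

    def test_damping_to_zero_gives_uniform(self):
        g = generate_network(GrowthParams(n_articles=40, seed=5))
        v = compute_pagerank(g, PageRankParams(d=1e-6, epsilon=1e-10, max_iterations=500))
        for p in g.nodes:
            assert v.scores[p] == pytest.approx(1.0 / g.n_nodes, abs=1e-4)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(100))
    def test_price_model_graphs_match_dense_solve(self, seed):
        params = GrowthParams(
            n_articles=4 + seed % 12,
            mean_refs=1 + (seed % 4),
            external_fraction=(seed % 4) * 0.1,
            seed=seed,
        )
        g = generate_network(params)
        assert g.n_nodes <= 50
        v = compute_pagerank(g, TIGHT)
        o = pagerank_oracle(g)
        diff = np.abs(scores_array(v, g.nodes) - scores_array(o, g.nodes)).max()
        assert diff < 1e-8

    def test_oracle_two_cycle(self, two_cycle):
        o = pagerank_oracle(two_cycle)
        assert o.scores[1] == pytest.approx(0.5, abs=1e-12)

    def test_oracle_refuses_large_graphs(self):
        g = from_edges([(i, i + 1) for i in range(1, 400)])
        with pytest.raises(GraphSizeError):
            pagerank_oracle(g)

    def test_networkx_agrees_with_oracle(self):
        """Independent reference: networkx pagerank on the same small graph."""
        nx = pytest.importorskip("networkx")
        g = generate_network(GrowthParams(n_articles=30, mean_refs=4, seed=9))
        o = pagerank_oracle(g)
        dg = nx.DiGraph(list(g.edges))
        dg.add_nodes_from(g.nodes)
        ref = nx.pagerank(dg, alpha=0.85, tol=1e-12, max_iter=2000)
        for p in g.nodes:
            assert o.scores[p] == pytest.approx(ref[p], abs=1e-8)


class TestIterationContract:
    def test_scores_sum_to_one_and_respect_lower_bound(self):
        for seed in (0, 1, 2):
            g = generate_network(GrowthParams(n_articles=200, seed=seed))
            v = compute_pagerank(g)
            assert sum(v.scores.values()) == pytest.approx(1.0, abs=1e-9)
            floor = (1 - 0.85) / g.n_nodes
            assert min(v.scores.values()) >= floor - 1e-12

    def test_mass_conserved_at_every_iteration(self):
        """Run with max_iterations=k for increasing k: each iterate sums to 1."""
        g = generate_network(GrowthParams(n_articles=50, seed=4))
        import warnings

        for k in range(1, 8):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                v = compute_pagerank(g, PageRankParams(epsilon=1e-300, max_iterations=k))
            assert sum(v.scores.values()) == pytest.approx(1.0, abs=1e-9)

    def test_converged_implies_final_residual_below_epsilon(self):
        g = generate_network(GrowthParams(n_articles=100, seed=6))
        v = compute_pagerank(g)
        assert v.converged
        assert v.residual < v.params.epsilon
        assert v.residuals[-1] == v.residual

    def test_nonconvergence_warns_and_flags(self):
        g = generate_network(GrowthParams(n_articles=100, seed=6))
        with pytest.warns(RuntimeWarning, match="did not converge"):
            v = compute_pagerank(g, PageRankParams(epsilon=1e-300, max_iterations=3))
        assert not v.converged and v.iterations == 3

    def test_empty_graph_is_an_error(self):
        g = CitationGraph(nodes=(), edges=(), sources=frozenset())
        with pytest.raises(EmptyGraphError):
            compute_pagerank(g)

    def test_permutation_equivariance(self):
        """Relabeling PMIDs permutes the scores identically."""
        g = generate_network(GrowthParams(n_articles=30, seed=8))
        shift = 10**7
        h = from_edges(
            [(u + shift, v + shift) for u, v in g.edges],
            sources=[p + shift for p in g.sources],
        )
        v, w = compute_pagerank(g, TIGHT), compute_pagerank(h, TIGHT)
        for p in g.nodes:
            assert v.scores[p] == pytest.approx(w.scores[p + shift], abs=1e-12)


class TestParamValidation:
    @pytest.mark.parametrize("kwargs", [
        {"d": 0.0}, {"d": 1.0}, {"d": -0.1}, {"epsilon": 0.0}, {"max_iterations": 0},
    ])
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PageRankParams(**kwargs)


class TestScoreIO:
    def test_two_cycle_written_in_scientific_notation(self, tmp_path, two_cycle):
        v = compute_pagerank(two_cycle)
        idx = build_inverted_index(two_cycle)
        path = tmp_path / "scores.tsv"
        write_scores(v, idx, path)
        assert path.read_text() == "1\t5.000000e-01\t1\n2\t5.000000e-01\t1\n"

    def test_read_back_reproduces_scores_to_printed_precision(self, tmp_path):
        g = generate_network(GrowthParams(n_articles=60, seed=2))
        v = compute_pagerank(g)
        idx = build_inverted_index(g)
        path = tmp_path / "scores.tsv"
        write_scores(v, idx, path)
        scores, counts = read_scores(path)
        assert counts == idx.citation_count
        for p in g.nodes:
            assert scores[p] == pytest.approx(v.scores[p], rel=1e-5)

    def test_output_bytes_stable_across_runs(self, tmp_path):
        g = generate_network(GrowthParams(n_articles=60, seed=2))
        blobs = []
        for run in range(2):
            path = tmp_path / f"run{run}.tsv"
            write_scores(compute_pagerank(g), build_inverted_index(g), path)
            blobs.append(path.read_bytes())
        assert blobs[0] == blobs[1]
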