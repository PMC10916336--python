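import numpy as np
import networkx as nx
import pytest

from conftest import make_sbm
from dva import ppi_embedding as pe
from dva.exceptions import (ContractError, DeadEndError, EmptyGraphError,
                            FormatError, ParameterError)
from dva.ppi_embedding import (WalkConfig, build_adjacency, generate_corpus,
                               read_corpus, sample_steps, simulate_walk,
                               step_distribution, train_skipgram,
                               transition_weight, variant_embedding,
                               write_corpus)
from dva.variant_io import VariantRecord


class TestBuildAdjacency:
    def test_thresholding(self):
        g = build_adjacency([("a", "b", 900), ("b", "c", 300)], 700)
        assert sorted(g.edges) == [("a", "b")]

    def test_self_edge_dropped(self):
        g = build_adjacency([("a", "a", 999), ("a", "b", 800)], 700)
        assert sorted(g.edges) == [("a", "b")]

    def test_duplicate_pair_merged_keeping_max(self):
        g = build_adjacency([("a", "b", 650), ("b", "a", 850)], 700)
        assert sorted(g.edges) == [("a", "b")]

    @pytest.mark.parametrize("score", [-1, 1001])
    def test_score_out_of_string_range(self, score):
        with pytest.raises(FormatError):
            build_adjacency([("a", "b", score)], 700)

    def test_empty_after_threshold(self):
        with pytest.raises(EmptyGraphError):
            build_adjacency([("a", "b", 100)], 700)

    def test_roster_keeps_isolated_nodes(self):
        g = build_adjacency([("a", "b", 900)], 700, roster=["a", "b", "z"])
        assert "z" in g.nodes and g.degree("z") == 0


class TestTransitionWeight:
    def test_return_step_weighted_one_over_p(self, path_graph):
        cfg = WalkConfig(p=4.0, q=1.0)
        assert transition_weight("a", "b", "a", cfg, path_graph) == 0.25

    def test_unbiased_when_p_q_one(self, triangle):
        cfg = WalkConfig(p=1.0, q=1.0)
        for x in ("a", "c"):
            assert transition_weight("a", "b", x, cfg, triangle) == 1.0

    def test_triangle_common_neighbor_weight_one(self, triangle):
        # t-x edge exists: the d(t,x)=1 branch, independent of p and q
        cfg = WalkConfig(p=0.25, q=4.0)
        assert transition_weight("a", "b", "c", cfg, triangle) == 1.0

    def test_outward_step_weighted_one_over_q(self, path_graph):
        cfg = WalkConfig(p=1.0, q=2.0)
        assert transition_weight("a", "b", "c", cfg, path_graph) == 0.5

    def test_first_step_uniform(self, path_graph):
        cfg = WalkConfig()
        assert transition_weight(None, "b", "c", cfg, path_graph) == 1.0

    def test_non_neighbor_rejected(self, path_graph):
        with pytest.raises(ContractError):
            transition_weight("a", "a", "c", WalkConfig(), path_graph)

    @pytest.mark.parametrize("kwargs", [
        {"p": 0.0}, {"q": -1.0}, {"walk_length": 1}, {"walks_per_node": 0}])
    def test_config_validation(self, kwargs):
        with pytest.raises(ParameterError):
            WalkConfig(**kwargs)


class TestStepDistribution:
    def test_star_first_step_uniform(self):
        g = nx.star_graph(4)
        nbrs, probs = step_distribution(None, 0, WalkConfig(), g)
        np.testing.assert_allclose(probs, 0.25)

    def test_path_hand_normalization(self, path_graph):
        # at v=b coming from a with p=2, q=0.5: weights {a: 0.5, c: 2}
        nbrs, probs = step_distribution("a", "b", WalkConfig(p=2.0, q=0.5),
                                        path_graph)
        assert dict(zip(nbrs, probs)) == pytest.approx({"a": 0.2, "c": 0.8})

    def test_probabilities_sum_to_one(self):
        g, _ = make_sbm(20, 2, 0.5, 0.2, seed=3)
        cfg = WalkConfig(p=0.3, q=2.5)
        for v in g.nodes:
            if g.degree(v) == 0:
                continue
            t = next(iter(g.neighbors(v)))
            _, probs = step_distribution(t, v, cfg, g)
            assert probs.sum() == pytest.approx(1.0, abs=1e-12)

    def test_isolated_node_dead_end(self):
        g = nx.Graph()
        g.add_node("solo")
        with pytest.raises(DeadEndError):
            step_distribution(None, "solo", WalkConfig(), g)

    def test_return_probability_monotone_in_inverse_p(self, path_graph):
        # on the triad a-b-c, the probability of b -> a (a return) must
        # increase as 1/p increases
        probs = []
        for p in (8.0, 2.0, 1.0, 0.25):
            nbrs, pr = step_distribution("a", "b", WalkConfig(p=p, q=1.0),
                                         path_graph)
            probs.append(dict(zip(nbrs, pr))["a"])
        assert probs == sorted(probs)


class TestWalks:
    def test_walk_starts_at_start_and_respects_adjacency(self, path_graph):
        rng = np.random.default_rng(0)
        walk = simulate_walk("a", WalkConfig(walk_length=6), path_graph, rng)
        assert walk[0] == "a"
        assert walk[1] == "b"  # a's only neighbor
        for u, v in zip(walk, walk[1:]):
            assert path_graph.has_edge(u, v)

    def test_fixed_seed_reproducible(self, triangle):
        cfg = WalkConfig(walk_length=20, seed=5)
        w1 = simulate_walk("a", cfg, triangle, np.random.default_rng(42))
        w2 = simulate_walk("a", cfg, triangle, np.random.default_rng(42))
        assert w1 == w2

    def test_isolated_start_gives_length_one_walk(self):
        g = nx.Graph()
        g.add_node("solo")
        walk = simulate_walk("solo", WalkConfig(), g,
                             np.random.default_rng(0))
        assert walk == ["solo"]

    def test_monte_carlo_matches_step_distribution(self, triangle):
        cfg = WalkConfig(p=2.0, q=0.5)
        rng = np.random.default_rng(0)
        n = 100_000
        nbrs, probs = step_distribution("a", "b", cfg, triangle)
        draws = sample_steps("a", "b", cfg, triangle, rng, n)
        freq = np.array([draws.count(x) / n for x in nbrs])
        np.testing.assert_allclose(freq, probs, atol=0.01)


class TestCorpus:
    def test_corpus_counts_and_starts(self, triangle):
        cfg = WalkConfig(walk_length=5, walks_per_node=4, seed=0)
        corpus = generate_corpus(triangle, cfg)
        assert len(corpus) == 3 * 4
        starts = [w[0] for w in corpus]
        expected = [n for n in sorted(triangle.nodes) for _ in range(4)]
        assert starts == expected

    def test_consecutive_nodes_adjacent(self):
        g, _ = make_sbm(20, 2, 0.4, 0.1, seed=1)
        corpus = generate_corpus(g, WalkConfig(walk_length=10,
                                               walks_per_node=2, seed=2))
        for walk in corpus:
            for u, v in zip(walk, walk[1:]):
                assert g.has_edge(u, v)

    def test_corpus_byte_identical_across_runs(self, tmp_path, triangle):
        cfg = WalkConfig(walk_length=8, walks_per_node=3, seed=9)
        p1, p2 = tmp_path / "c1.txt", tmp_path / "c2.txt"
        write_corpus(generate_corpus(triangle, cfg), p1)
        write_corpus(generate_corpus(triangle, cfg), p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert read_corpus(p1) == generate_corpus(triangle, cfg)


class TestSkipgram:
    def test_output_shape_covers_all_nodes(self, triangle):
        corpus = generate_corpus(triangle, WalkConfig(walk_length=10,
                                                      walks_per_node=3))
        emb = train_skipgram(corpus, k=8, epochs=2, seed=0,
                             nodes=triangle.nodes)
        assert emb.U.shape == (3, 8)
        assert set(emb.node_index) == set(triangle.nodes)

    def test_deterministic_under_seed(self, triangle):
        corpus = generate_corpus(triangle, WalkConfig(walk_length=10,
                                                      walks_per_node=3))
        e1 = train_skipgram(corpus, k=8, epochs=2, seed=3, nodes=triangle.nodes)
        e2 = train_skipgram(corpus, k=8, epochs=2, seed=3, nodes=triangle.nodes)
        np.testing.assert_array_equal(e1.U, e2.U)

    def test_node_absent_from_corpus_gets_zero_vector(self, triangle):
        corpus = generate_corpus(triangle, WalkConfig(walk_length=10,
                                                      walks_per_node=2))
        emb = train_skipgram(corpus, k=8, epochs=2, seed=0,
                             nodes=list(triangle.nodes) + ["ghost"])
        np.testing.assert_array_equal(emb.vector("ghost"), np.zeros(8))

    def test_training_loss_decreases(self):
        g, _ = make_sbm(30, 2, 0.4, 0.05, seed=0)
        corpus = generate_corpus(g, WalkConfig(walk_length=20,
                                               walks_per_node=5, seed=0))
        emb = train_skipgram(corpus, k=16, epochs=4, seed=0, nodes=g.nodes)
        assert emb.epoch_loss[-1] < emb.epoch_loss[0]

    def test_invalid_dimension(self, triangle):
        corpus = generate_corpus(triangle, WalkConfig())
        with pytest.raises(ParameterError):
            train_skipgram(corpus, k=1)

    def test_community_structure_separates(self):
        g, block = make_sbm(40, 2, 0.4, 0.02, seed=0)
        corpus = generate_corpus(g, WalkConfig(walk_length=40,
                                               walks_per_node=5, seed=0))
        emb = train_skipgram(corpus, k=16, epochs=8, seed=0, nodes=g.nodes)
        U = emb.U / np.linalg.norm(emb.U, axis=1, keepdims=True)
        S = U @ U.T
        same = block[:, None] == block[None, :]
        off = ~np.eye(len(block), dtype=bool)
        assert S[same & off].mean() - S[~same].mean() > 0.1


class TestVariantEmbedding:
    def test_lookup_and_fallbacks(self, triangle):
        corpus = generate_corpus(triangle, WalkConfig(walk_length=10,
                                                      walks_per_node=2))
        emb = train_skipgram(corpus, k=4, epochs=1, seed=0, nodes=triangle.nodes)
        gene_map = {"GENE_A": "a", "GENE_X": "missing_protein"}

        def mk(gene, pos):
            return VariantRecord(chrom="1", pos=pos, ref="A", alt="G",
                                 gene=gene, label="neutral", source="other")

        np.testing.assert_array_equal(variant_embedding(mk("GENE_A", 1), emb,
                                                        gene_map),
                                      emb.vector("a"))
        np.testing.assert_array_equal(variant_embedding(mk("GENE_X", 2), emb,
                                                        gene_map),
                                      np.zeros(4))
        np.testing.assert_array_equal(variant_embedding(mk("UNMAPPED", 3), emb,
                                                        gene_map),
                                      np.zeros(4))
        # same gene -> identical block
        np.testing.assert_array_equal(
            variant_embedding(mk("GENE_A", 4), emb, gene_map),
            variant_embedding(mk("GENE_A", 5), emb, gene_map))


class TestEmbeddingIO:
    def test_round_trip(self, tmp_path, triangle):
        corpus = generate_corpus(triangle, WalkConfig(walk_length=10,
                                                      walks_per_node=2))
        emb = train_skipgram(corpus, k=4, epochs=1, seed=0, nodes=triangle.nodes)
        path = tmp_path / "emb.tsv"
        pe.write_embedding(emb, path)
        back = pe.read_embedding(path)
        assert set(back.node_index) == set(emb.node_index)
        for node in emb.node_index:
            np.testing.assert_allclose(back.vector(node), emb.vector(node),
                                       atol=1e-7)
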