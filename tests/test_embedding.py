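"""Random walks, Huffman hierarchical softmax, and SkipGram training."""

import itertools

import numpy as np
import pytest

from mirgo.embedding import (
    DeepWalkEmbedding,
    EmbeddingMatrix,
    WalkConfig,
    WalkCorpus,
    build_hs_tree,
    corpus_loss,
    generate_walks,
    hs_probability,
    train_skipgram,
    window_loss,
    window_loss_and_grad,
)
from mirgo.netbuild import GlobalNetwork, WeightedEdgeList, assemble_global_network


def graph_from_edges(pairs, extra_mirnas=()):
    m = WeightedEdgeList()
    for a, b, w in pairs:
        m.add(a, b, w)
    return assemble_global_network(
        m, WeightedEdgeList(), WeightedEdgeList(), mirna_nodes=extra_mirnas
    )


def cfg(**kw):
    base = dict(walks_per_node=1, walk_length=5, window=2, dim=8, seed=0)
    base.update(kw)
    return WalkConfig(**base)


class TestWalks:
    def test_path_graph_forces_alternation(self):
        g = graph_from_edges([("a", "b", 1.0)])
        corpus = generate_walks(g, cfg(walks_per_node=3, walk_length=5))
        for walk in corpus.walks:
            assert len(walk) == 5
            for u, v in zip(walk, walk[1:]):
                assert {u, v} == {"mirna:a", "mirna:b"}
                assert u != v

    def test_isolated_node_yields_length_one_walk(self):
        g = graph_from_edges([("a", "b", 1.0)], extra_mirnas=["z"])
        corpus = generate_walks(g, cfg())
        assert ["mirna:z"] in corpus.walks

    def test_same_seed_identical_corpora(self):
        g = graph_from_edges([("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)])
        c1 = generate_walks(g, cfg(walks_per_node=4, seed=7))
        c2 = generate_walks(g, cfg(walks_per_node=4, seed=7))
        assert c1.walks == c2.walks

    def test_weighted_transition_frequencies(self):
        # from b, neighbors a (0.9) and c (0.1)
        g = graph_from_edges([("a", "b", 0.9), ("b", "c", 0.1)])
        corpus = generate_walks(g, cfg(walks_per_node=40, walk_length=90, seed=3))
        taken = {"mirna:a": 0, "mirna:c": 0}
        for walk in corpus.walks:
            for u, v in zip(walk, walk[1:]):
                if u == "mirna:b":
                    taken[v] += 1
        n = sum(taken.values())
        p_hat = taken["mirna:a"] / n
        se = np.sqrt(0.9 * 0.1 / n)
        assert abs(p_hat - 0.9) < 3 * se

    def test_uniform_when_unweighted(self):
        g = graph_from_edges([("a", "b", 0.9), ("b", "c", 0.1)])
        corpus = generate_walks(
            g, cfg(walks_per_node=40, walk_length=90, seed=3, weighted=False)
        )
        taken = {"mirna:a": 0, "mirna:c": 0}
        for walk in corpus.walks:
            for u, v in zip(walk, walk[1:]):
                if u == "mirna:b":
                    taken[v] += 1
        n = sum(taken.values())
        se = np.sqrt(0.25 / n)
        assert abs(taken["mirna:a"] / n - 0.5) < 3 * se

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            WalkConfig(walks_per_node=0)
        with pytest.raises(ValueError):
            WalkConfig(window=10, walk_length=5)


class TestHuffmanTree:
    def test_two_leaves_at_depth_one(self):
        tree = build_hs_tree({"a": 3, "b": 1}, d=4)
        assert tree.depth("a") == 1 and tree.depth("b") == 1
        codes = {tuple(tree.codes["a"]), tuple(tree.codes["b"])}
        assert codes == {(0,), (1,)}

    def test_textbook_counts_give_optimal_depths(self):
        tree = build_hs_tree({"a": 4, "b": 2, "c": 1, "d": 1}, d=4)
        depths = {v: tree.depth(v) for v in "abcd"}
        assert depths == {"a": 1, "b": 2, "c": 3, "d": 3}
        # weighted path length minimal over all full binary trees on 4 leaves
        counts = {"a": 4, "b": 2, "c": 1, "d": 1}
        wpl = sum(counts[v] * depths[v] for v in counts)
        assert wpl == 14
        best = min(
            sum(c * d for c, d in zip(perm, shape))
            for shape in ([2, 2, 2, 2], [1, 2, 3, 3])
            for perm in itertools.permutations(counts.values())
        )
        assert wpl == best

    def test_equal_counts_deterministic(self):
        t1 = build_hs_tree({"a": 1, "b": 1, "c": 1, "d": 1}, d=2)
        t2 = build_hs_tree({"a": 1, "b": 1, "c": 1, "d": 1}, d=2)
        assert all(np.array_equal(t1.paths[v], t2.paths[v]) for v in "abcd")
        assert all(np.array_equal(t1.codes[v], t2.codes[v]) for v in "abcd")

    def test_tiny_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            build_hs_tree({"a": 5}, d=4)

    def test_path_length_bounded_for_balanced_counts(self):
        n = 32
        tree = build_hs_tree({f"v{i:02d}": 1 for i in range(n)}, d=2)
        assert max(tree.depth(v) for v in tree.vocab) <= int(np.ceil(np.log2(n))) + 1


class TestHSProbability:
    def test_zero_vectors_give_half_per_level(self):
        tree = build_hs_tree({"a": 4, "b": 2, "c": 1, "d": 1}, d=3)
        phi = np.ones(3)
        for v in "abcd":
            assert hs_probability(phi, tree, v) == pytest.approx(0.5 ** tree.depth(v))

    def test_two_leaf_probabilities_complementary(self, rng):
        tree = build_hs_tree({"a": 3, "b": 1}, d=6)
        tree.psi[:] = rng.normal(size=tree.psi.shape)
        phi = rng.normal(size=6)
        assert hs_probability(phi, tree, "a") + hs_probability(phi, tree, "b") == pytest.approx(1.0)

    def test_eight_leaves_sum_to_one_and_match_edge_oracle(self, rng):
        counts = {f"n{i}": int(c) for i, c in enumerate(rng.integers(1, 20, size=8))}
        tree = build_hs_tree(counts, d=5)
        tree.psi[:] = rng.normal(scale=0.8, size=tree.psi.shape)
        phi = rng.normal(size=5)
        total = 0.0
        for leaf in tree.vocab:
            p = hs_probability(phi, tree, leaf)
            # per-edge sigmoid oracle
            oracle = 1.0
            for idx, c in zip(tree.paths[leaf], tree.codes[leaf]):
                x = float(tree.psi[idx] @ phi)
                s = 1.0 / (1.0 + np.exp(-x))
                oracle *= s if c == 0 else 1.0 - s
            assert p == pytest.approx(oracle, rel=1e-12)
            total += p
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_dimension_mismatch_raises(self):
        tree = build_hs_tree({"a": 1, "b": 1}, d=4)
        with pytest.raises(ValueError, match="dimension"):
            hs_probability(np.zeros(3), tree, "a")


class TestWindowLoss:
    def test_no_context_gives_zero_loss(self):
        tree = build_hs_tree({"a": 1, "b": 1}, d=4)
        phi = np.zeros((2, 4))
        assert window_loss(phi, tree, ["a"], 0, 2) == 0.0

    def test_zero_psi_closed_form(self):
        tree = build_hs_tree({"a": 4, "b": 2, "c": 1, "d": 1}, d=4)
        phi = np.ones((4, 4))
        walk = ["a", "b", "c", "d"]
        loss = window_loss(phi, tree, walk, 1, 2)
        depths = tree.depth("a") + tree.depth("c") + tree.depth("d")
        assert loss == pytest.approx(np.log(2) * depths)

    def test_equals_hs_probability_factorization(self, rng):
        counts = {f"n{i}": int(c) for i, c in enumerate(rng.integers(1, 10, size=6))}
        tree = build_hs_tree(counts, d=4)
        tree.psi[:] = rng.normal(size=tree.psi.shape)
        phi = rng.normal(size=(6, 4))
        index = tree.index
        walk = list(rng.choice(tree.vocab, size=8))
        i = 4
        loss = window_loss(phi, tree, walk, i, 2, index)
        expected = 0.0
        for j in (2, 3, 5, 6):
            expected -= np.log(hs_probability(phi[index[walk[i]]], tree, walk[j]))
        assert loss == pytest.approx(expected, rel=1e-10)


class TestGradients:
    @pytest.mark.parametrize("trial", range(5))
    def test_analytic_matches_finite_differences(self, trial):
        rng = np.random.default_rng(100 + trial)
        counts = {f"n{i}": int(c) for i, c in enumerate(rng.integers(1, 8, size=5))}
        tree = build_hs_tree(counts, d=3)
        tree.psi[:] = rng.normal(scale=0.5, size=tree.psi.shape)
        phi = rng.normal(scale=0.5, size=(5, 3))
        index = tree.index
        walk = list(rng.choice(tree.vocab, size=6))
        i = int(rng.integers(len(walk)))
        loss, g_center, psi_grads = window_loss_and_grad(phi, tree, walk, i, 2, index)
        eps = 1e-5
        ci = index[walk[i]]
        for k in range(3):
            phi[ci, k] += eps
            lp = window_loss(phi, tree, walk, i, 2, index)
            phi[ci, k] -= 2 * eps
            lm = window_loss(phi, tree, walk, i, 2, index)
            phi[ci, k] += eps
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(g_center[k], rel=1e-4, abs=1e-8)
        for idx, grad in psi_grads.items():
            for k in range(3):
                tree.psi[idx, k] += eps
                lp = window_loss(phi, tree, walk, i, 2, index)
                tree.psi[idx, k] -= 2 * eps
                lm = window_loss(phi, tree, walk, i, 2, index)
                tree.psi[idx, k] += eps
                num = (lp - lm) / (2 * eps)
                assert num == pytest.approx(grad[k], rel=1e-4, abs=1e-8)


def clique_corpus():
    """Walk corpus over two disconnected 6-node cliques."""
    m = WeightedEdgeList()
    for grp, names in (("x", [f"x{i}" for i in range(6)]),
                       ("y", [f"y{i}" for i in range(6)])):
        for a, b in itertools.combinations(names, 2):
            m.add(a, b, 1.0)
    g = assemble_global_network(m, WeightedEdgeList(), WeightedEdgeList())
    return generate_walks(g, WalkConfig(walks_per_node=8, walk_length=10, window=3,
                                        dim=16, seed=5))


class TestSkipGramTraining:
    def test_same_seed_identical_embeddings(self):
        corpus = clique_corpus()
        c = WalkConfig(walks_per_node=8, walk_length=10, window=3, dim=16, seed=5)
        e1 = train_skipgram(corpus, c)
        e2 = train_skipgram(corpus, c)
        np.testing.assert_array_equal(e1.vectors, e2.vectors)

    def test_zero_epochs_returns_initialization(self):
        corpus = clique_corpus()
        c = WalkConfig(walks_per_node=8, walk_length=10, window=3, dim=16, seed=5)
        emb = train_skipgram(corpus, c, epochs=0)
        d = c.dim
        assert np.all(np.abs(emb.vectors) <= 0.5 / d + 1e-12)

    def test_training_reduces_corpus_loss(self):
        corpus = clique_corpus()
        c = WalkConfig(walks_per_node=8, walk_length=10, window=3, dim=16, seed=5)
        tree = build_hs_tree(corpus, c.dim)  # psi starts at zero
        init = train_skipgram(corpus, c, epochs=0)
        loss0 = corpus_loss(init.vectors, tree, corpus, c.window)
        trained = train_skipgram(corpus, c, epochs=1, tree=tree)  # mutates psi
        loss1 = corpus_loss(trained.vectors, tree, corpus, c.window)
        assert loss1 <= loss0

    def test_cliques_separate_in_cosine_similarity(self):
        corpus = clique_corpus()
        c = WalkConfig(walks_per_node=8, walk_length=10, window=3, dim=16, seed=5)
        emb = train_skipgram(corpus, c, epochs=2)
        X = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
        groups = [n.split(":")[1][0] for n in emb.node_ids]
        within, between = [], []
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                (within if groups[i] == groups[j] else between).append(X[i] @ X[j])
        assert np.mean(within) > np.mean(between)

    def test_nonincreasing_loss_across_epochs(self):
        corpus = clique_corpus()
        c = WalkConfig(walks_per_node=8, walk_length=10, window=3, dim=16, seed=5)
        losses = []
        for ep in (1, 2, 3):
            tree = build_hs_tree(corpus, c.dim)
            emb = train_skipgram(corpus, c, epochs=ep, tree=tree)
            losses.append(corpus_loss(emb.vectors, tree, corpus, c.window))
        # 1% slack for SGD noise
        assert losses[1] <= losses[0] * 1.01
        assert losses[2] <= losses[1] * 1.01

    def test_sbm_link_prediction_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(11)
        n, k = 60, 2
        block = np.array([i % k for i in range(n)])
        m = WeightedEdgeList()
        held_out = []
        for i in range(n):
            for j in range(i + 1, n):
                same = block[i] == block[j]
                p = 0.3 if same else 0.02
                if rng.random() < p:
                    if same and rng.random() < 0.1:
                        held_out.append((i, j))  # held-out positive pair
                    else:
                        m.add(f"n{i:02d}", f"n{j:02d}", 1.0)
        g = assemble_global_network(
            m, WeightedEdgeList(), WeightedEdgeList(),
            mirna_nodes=[f"n{i:02d}" for i in range(n)],
        )
        est = DeepWalkEmbedding(walks_per_node=10, walk_length=20, window=4,
                                dim=32, epochs=2, seed=11)
        est.fit(g)
        idx = {nid: i for i, nid in enumerate(est.node_ids_)}
        X = est.embedding_ / np.linalg.norm(est.embedding_, axis=1, keepdims=True)

        def cos(i, j):
            return float(X[idx[f"mirna:n{i:02d}"]] @ X[idx[f"mirna:n{j:02d}"]])

        neg = [(i, j) for i in range(n) for j in range(i + 1, n)
               if block[i] != block[j] and (f"n{i:02d}", f"n{j:02d}") not in m]
        neg = [neg[t] for t in rng.choice(len(neg), size=len(held_out), replace=False)]
        y = [1] * len(held_out) + [0] * len(neg)
        s = [cos(i, j) for i, j in held_out + neg]
        assert roc_auc_score(y, s) > 0.8


class TestEmbeddingIO:
    def test_text_round_trip(self, tmp_path, rng):
        emb = EmbeddingMatrix([f"n{i}" for i in range(4)], rng.normal(size=(4, 6)))
        path = tmp_path / "emb.txt"
        emb.write(path)
        back = EmbeddingMatrix.read(path)
        assert back.node_ids == emb.node_ids
        np.testing.assert_allclose(back.vectors, emb.vectors, rtol=1e-7)

    def test_subset_missing_node_raises(self, rng):
        emb = EmbeddingMatrix(["a", "b"], rng.normal(size=(2, 3)))
        with pytest.raises(KeyError, match="zzz"):
            emb.subset(["a", "zzz"])
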