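"""Graph-transformer components against brute-force oracles, plus training
contracts (determinism, schedule, capacity, gradient flow)."""

import numpy as np
import pytest

import patchgraph.nn as pnn
from patchgraph.autograd import Tensor
from patchgraph.graph_builder import build_graph, normalize_adjacency
from patchgraph.gtp_model import (GTPConfig, GraphTransformer, MinCutPool,
                                  TransformerBlock, gc_layer, total_loss, train)


@pytest.fixture()
def f64_params():
    """Build modules in double precision for 1e-6 oracle comparisons."""
    old = pnn.DTYPE
    pnn.DTYPE = np.float64
    yield
    pnn.DTYPE = old


def random_grid_graph(rng, n_side=3, d=4, label=0):
    coords = [(r, c) for r in range(n_side) for c in range(n_side)]
    F = rng.normal(size=(len(coords), d))
    return build_graph(F, coords, label=label)


class TestGCLayer:
    def test_identity_propagation(self):
        H = np.abs(np.random.default_rng(0).normal(size=(4, 3)))
        out = gc_layer(H, np.eye(4), np.eye(3))
        assert np.allclose(out.data, H)

    def test_two_node_hand_product(self):
        A_hat = np.full((2, 2), 0.5)
        out = gc_layer(np.eye(2), A_hat, np.eye(2))
        assert np.allclose(out.data, A_hat)

    def test_matches_triple_loop_oracle(self, rng):
        N, D, C = 10, 4, 5
        A_hat = normalize_adjacency((lambda m: np.triu(m, 1) + np.triu(m, 1).T)(
            rng.integers(0, 2, size=(N, N))))
        H = rng.normal(size=(N, D))
        W = rng.normal(size=(D, C))
        out = gc_layer(H, A_hat, W).data
        expected = np.zeros((N, C))
        for i in range(N):
            for k in range(C):
                acc = 0.0
                for j in range(N):
                    for d in range(D):
                        acc += A_hat[i, j] * H[j, d] * W[d, k]
                expected[i, k] = max(acc, 0.0)
        assert np.abs(out - expected).max() < 1e-6


class TestMinCutPool:
    def force_pool(self, hidden, clusters, W, b, f64=True):
        pool = MinCutPool(hidden, clusters, np.random.default_rng(0))
        pool.assign.weight.data = np.asarray(W, dtype=pool.assign.weight.dtype)
        pool.assign.bias.data = np.asarray(b, dtype=pool.assign.bias.dtype)
        return pool

    def test_all_nodes_one_cluster_sums_features(self, f64_params, rng):
        H = rng.normal(size=(5, 3))
        pool = self.force_pool(3, 2, np.zeros((3, 2)), [50.0, 0.0])
        X_pool, _, S, _ = pool(Tensor(H), np.zeros((5, 5)))
        assert np.allclose(S.data[:, 0], 1.0)
        assert np.abs(X_pool.data[0] - H.sum(axis=0)).max() < 1e-6

    def test_identity_assignment_preserves_features(self, f64_params):
        H = np.eye(3)
        pool = self.force_pool(3, 3, 80.0 * np.eye(3), np.zeros(3))
        X_pool, _, S, _ = pool(Tensor(H), np.zeros((3, 3)))
        assert np.abs(S.data - np.eye(3)).max() < 1e-6
        assert np.abs(X_pool.data - H).max() < 1e-6

    def test_hand_partition_pools_sums(self, f64_params):
        """Nodes {1,2} -> cluster 1, {3} -> cluster 2: X_pool = S^T H."""
        H = np.array([[1.0, 1.0], [3.0, 3.0], [5.0, 5.0]])
        W = np.array([[-10.0, 10.0], [0.0, 0.0]])
        pool = self.force_pool(2, 2, W, [40.0, -40.0])
        X_pool, _, S, _ = pool(Tensor(H), np.zeros((3, 3)))
        assert np.abs(X_pool.data - [[4.0, 4.0], [5.0, 5.0]]).max() < 1e-6

    def test_assignment_rows_sum_to_one_and_aux_ranges(self, rng):
        for trial in range(5):
            H = rng.normal(size=(12, 6))
            raw = rng.integers(0, 2, size=(12, 12))
            A = np.triu(raw, 1) + np.triu(raw, 1).T
            pool = MinCutPool(6, 4, np.random.default_rng(trial))
            X_pool, A_pool, S, (cut, ortho) = pool(Tensor(H.astype(np.float32)), A)
            assert np.allclose(S.data.sum(axis=1), 1.0, atol=1e-6)
            assert (S.data >= 0).all()
            assert -1.0 - 1e-6 <= cut.item() <= 0.0 + 1e-6
            assert 0.0 <= ortho.item() <= np.sqrt(2) + 1e-6
            assert np.allclose(A_pool, A_pool.T)

    def test_invalid_cluster_count(self):
        with pytest.raises(ValueError):
            MinCutPool(4, 0, np.random.default_rng(0))


class TestAttention:
    def test_rows_sum_to_one(self, rng):
        cfg = GTPConfig(n_features=4, hidden_dim=8, n_heads=2, mlp_dim=16,
                        n_clusters=4, n_classes=2)
        block = TransformerBlock(cfg, np.random.default_rng(0))
        _, A = block.attention(Tensor(rng.normal(size=(6, 8)).astype(np.float32)))
        assert np.allclose(A.data.sum(axis=-1), 1.0, atol=1e-5)

    def test_single_token_attention_is_one(self, rng):
        cfg = GTPConfig(n_features=4, hidden_dim=8, n_heads=2, mlp_dim=16,
                        n_clusters=1, n_classes=2)
        block = TransformerBlock(cfg, np.random.default_rng(0))
        _, A = block.attention(Tensor(rng.normal(size=(1, 8)).astype(np.float32)))
        assert np.allclose(A.data, 1.0)

    def test_hand_softmax_scores(self):
        # q = k = [[1],[0]], D_h = 1: row 1 softmax([1,0]), row 2 softmax([0,0])
        q = Tensor(np.array([[1.0], [0.0]]))
        A = ((q @ q.T) * 1.0).softmax(axis=-1).data
        assert np.allclose(A[0], [np.e / (np.e + 1), 1 / (np.e + 1)], atol=1e-9)
        assert np.allclose(A[1], [0.5, 0.5])

    def test_block_matches_loop_oracle(self, f64_params, rng):
        cfg = GTPConfig(n_features=4, hidden_dim=6, n_heads=2, head_dim=3,
                        mlp_dim=5, n_clusters=4, n_classes=2)
        block = TransformerBlock(cfg, np.random.default_rng(7))
        T, D, k, Dh = 5, 6, 2, 3
        t_in = rng.normal(size=(T, D))
        out, A, _ = block(Tensor(t_in))

        def ln(x, w, b, eps=1e-5):
            mu = x.mean(axis=-1, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
            return (x - mu) / np.sqrt(var + eps) * w + b

        x = ln(t_in, block.ln1.weight.data, block.ln1.bias.data)
        qkv = (x @ block.U_qkv.data).reshape(T, 3, k, Dh)
        sa_heads = np.zeros((k, T, Dh))
        A_exp = np.zeros((k, T, T))
        for h in range(k):
            for t in range(T):
                scores = np.array([
                    qkv[t, 0, h] @ qkv[j, 1, h] / np.sqrt(Dh) for j in range(T)
                ])
                e = np.exp(scores - scores.max())
                w = e / e.sum()
                A_exp[h, t] = w
                sa_heads[h, t] = sum(w[j] * qkv[j, 2, h] for j in range(T))
        cat = np.concatenate([sa_heads[h] for h in range(k)], axis=1)
        t_mid = cat @ block.U_msa.data + t_in
        x2 = ln(t_mid, block.ln2.weight.data, block.ln2.bias.data)
        h1 = x2 @ block.mlp.fc1.weight.data + block.mlp.fc1.bias.data
        c = np.sqrt(2 / np.pi)
        h1 = 0.5 * h1 * (1 + np.tanh(c * (h1 + 0.044715 * h1**3)))
        expected = h1 @ block.mlp.fc2.weight.data + block.mlp.fc2.bias.data + t_mid
        assert np.abs(A.data - A_exp).max() < 1e-6
        assert np.abs(out.data - expected).max() < 1e-6


class TestForward:
    cfg = dict(n_features=4, hidden_dim=8, n_heads=2, mlp_dim=16,
               n_clusters=4, n_classes=3, n_transformer_blocks=2)

    def test_probabilities_sum_to_one(self, rng):
        model = GraphTransformer(GTPConfig(**self.cfg))
        probs, trace = model.forward(random_grid_graph(rng))
        assert probs.shape == (3,)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        for A in trace.attn:
            assert np.allclose(A.data.sum(axis=-1), 1.0, atol=1e-5)

    def test_zero_classifier_head_gives_uniform(self, rng):
        model = GraphTransformer(GTPConfig(**self.cfg))
        model.head.weight.data[:] = 0
        model.head.bias.data[:] = 0
        probs, _ = model.forward(random_grid_graph(rng))
        assert np.allclose(probs, 1 / 3, atol=1e-7)

    def test_permutation_invariance(self, rng):
        """20 random joint node permutations x 5 random graphs."""
        from conftest import permute_graph

        model = GraphTransformer(GTPConfig(**self.cfg))
        for g_idx in range(5):
            graph = random_grid_graph(rng, n_side=3 + g_idx % 2)
            base, _ = model.forward(graph)
            for _ in range(20):
                perm = rng.permutation(graph.n_nodes)
                probs, _ = model.forward(permute_graph(graph, perm))
                assert np.abs(probs - base).max() < 1e-5

    @pytest.mark.parametrize("n_nodes", [1, 5, 500])
    def test_variable_graph_sizes(self, rng, n_nodes):
        import warnings

        side = int(np.ceil(np.sqrt(n_nodes)))
        coords = [(r, c) for r in range(side) for c in range(side)][:n_nodes]
        F = rng.normal(size=(n_nodes, 4))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # single-node graphs warn
            graph = build_graph(F, coords)
        model = GraphTransformer(GTPConfig(**self.cfg))
        probs, _ = model.forward(graph)
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)

    def test_feature_dim_mismatch_rejected(self, rng):
        model = GraphTransformer(GTPConfig(**self.cfg))
        with pytest.raises(ValueError, match="features"):
            model.forward(random_grid_graph(rng, d=7))

    def test_gradient_reaches_every_parameter(self, rng):
        from patchgraph.nn import cross_entropy

        model = GraphTransformer(GTPConfig(**self.cfg))
        model.zero_grad()
        for label in (0, 1, 2):
            _, trace = model.forward(random_grid_graph(rng, label=label))
            loss = cross_entropy(trace.logits, label) + trace.cut_loss + trace.ortho_loss
            loss.backward()
        for name, p in model.named_parameters().items():
            assert p.grad is not None and np.abs(p.grad).max() > 0, name

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = GraphTransformer(GTPConfig(**self.cfg))
        graph = random_grid_graph(rng)
        model.save(tmp_path / "m")
        loaded = GraphTransformer.load(tmp_path / "m")
        assert np.allclose(model.predict_proba(graph), loaded.predict_proba(graph))


class TestTotalLoss:
    def test_perfect_prediction_zero_loss(self):
        assert total_loss([1.0, 0.0, 0.0], 0).item() == pytest.approx(0.0)

    def test_uniform_prediction_log3(self):
        loss = total_loss([1 / 3] * 3, 1)
        assert loss.item() == pytest.approx(np.log(3), abs=1e-9)

    def test_zero_aux_weights_reduce_to_cross_entropy(self):
        probs = [0.2, 0.5, 0.3]
        plain = total_loss(probs, 1, aux_losses=(0.0, 0.0))
        weighted = total_loss(probs, 1, aux_losses=(-0.5, 0.8),
                              lambda_cut=0.0, lambda_ortho=0.0)
        assert weighted.item() == pytest.approx(plain.item())

    def test_label_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            total_loss([0.5, 0.5], 2)


class TestTraining:
    def test_step_decay_schedule_values(self):
        from patchgraph.nn import step_decay_lr

        assert step_decay_lr(0) == pytest.approx(1e-3)
        assert step_decay_lr(29) == pytest.approx(1e-3)
        assert step_decay_lr(30) == pytest.approx(1e-4)
        assert step_decay_lr(100) == pytest.approx(1e-5)
        assert step_decay_lr(149) == pytest.approx(1e-5)

    def make_separable_graphs(self, rng, n_per_class=4, d=4):
        graphs, labels = [], []
        offsets = [np.full(d, 0.0), np.full(d, 3.0), np.full(d, -3.0)]
        for cls in range(3):
            for _ in range(n_per_class):
                coords = [(r, c) for r in range(3) for c in range(3)]
                F = rng.normal(size=(9, d)) * 0.3 + offsets[cls]
                graphs.append(build_graph(F, coords, label=cls))
                labels.append(cls)
        return graphs, labels

    def test_single_class_rejected(self, rng):
        graphs, _ = self.make_separable_graphs(rng, n_per_class=2)
        cfg = GTPConfig(**TestForward.cfg, n_steps=2)
        with pytest.raises(ValueError, match="two classes"):
            train(graphs[:2], [0, 0], cfg)

    def test_fixed_seed_reproduces_loss_trajectory(self, rng):
        graphs, labels = self.make_separable_graphs(rng, n_per_class=2)
        cfg = GTPConfig(**TestForward.cfg, n_steps=8, batch_size=4, seed=3)
        r1 = train(graphs, labels, cfg)
        r2 = train(graphs, labels, cfg)
        assert r1.history["loss"] == r2.history["loss"]
        assert r1.best_step == r2.best_step

    def test_overfits_small_training_set(self, rng):
        """Capacity check: 8 graphs reach training accuracy 1.0 (2/3 seeds)."""
        wins = 0
        for seed in (0, 1, 2):
            graphs, labels = self.make_separable_graphs(
                np.random.default_rng(50 + seed), n_per_class=3)
            tr_graphs, tr_labels = graphs[:8], labels[:8]
            cfg = GTPConfig(**TestForward.cfg, n_steps=200, batch_size=8, seed=seed)
            result = train(tr_graphs, tr_labels, cfg,
                           val_graphs=tr_graphs, val_labels=tr_labels)
            preds = [int(np.argmax(result.model.predict_proba(g))) for g in tr_graphs]
            wins += preds == list(tr_labels)
        assert wins >= 2
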