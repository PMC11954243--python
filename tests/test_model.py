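"""Attention layer, encoders, fusion head and training behavior."""

import numpy as np
import pytest

from amogel.autodiff import Tensor
from amogel.graph_build import FinalGraph, SampleGraph
from amogel.model import (AttentionRecord, ModelConfig, _forward, _init_params,
                          cross_entropy, extract_attention, gat_layer_forward,
                          global_encoder_forward, graph_encoder_forward,
                          predict_proba, train)


def random_graph(m, rng, edge_prob=0.4):
    """Random symmetric 4-channel graph on m nodes."""
    attr = np.zeros((m, m, 4))
    for i in range(m):
        for j in range(i + 1, m):
            if rng.random() < edge_prob:
                vals = rng.random(4) * np.array([1.0, 0.3, 0.3, 0.3])
                attr[i, j] = attr[j, i] = vals
    return FinalGraph([f"mRNA:g{i}" for i in range(m)], attr, 0.3)


def sample_graphs(fg, n, rng, classes=("A", "B")):
    m = len(fg.nodes)
    out = []
    for i in range(n):
        levels = rng.integers(0, 3, size=m)
        out.append(SampleGraph(fg, np.eye(3)[levels], classes[i % len(classes)],
                               f"s{i}"))
    return out


def small_cfg(**kw):
    kw.setdefault("hidden_dim", 8)
    kw.setdefault("heads", 2)
    kw.setdefault("epochs", 5)
    kw.setdefault("lr", 0.01)
    kw.setdefault("mlp_dims", (8,))
    return ModelConfig(**kw)


def row_sums(alpha, dst, m):
    """Sum attention per (sample, target node)."""
    S = alpha.shape[0]
    sums = np.zeros((S, m))
    for e, d in enumerate(dst):
        sums[:, d] += alpha[:, e]
    return sums


class TestGatLayer:
    def _layer(self, fg, cfg, x, seed=0):
        params = _init_params(cfg, len(fg.nodes), 2)
        src, dst, attr = fg.directed_edges()
        h = Tensor(x) @ params["proj.W"] + params["proj.b"]
        out, alpha = gat_layer_forward(params, "gat0", cfg, h, src, dst, attr)
        m = len(fg.nodes)
        loops = np.arange(m)
        return out, alpha, np.concatenate([dst, loops]), m

    def test_attention_rows_sum_to_one(self):
        rng = np.random.default_rng(0)
        fg = random_graph(7, rng)
        x = np.eye(3)[rng.integers(0, 3, size=(3, 7))]
        _, alpha, dst_full, m = self._layer(fg, small_cfg(), x)
        np.testing.assert_allclose(row_sums(alpha, dst_full, m),
                                   np.ones((3, m)), atol=1e-6)

    def test_isolated_node_keeps_all_attention_on_itself(self):
        fg = random_graph(3, np.random.default_rng(1), edge_prob=0.0)
        x = np.eye(3)[np.zeros((2, 3), dtype=int)]
        _, alpha, dst_full, m = self._layer(fg, small_cfg(), x)
        # only self-loops exist: every coefficient is exactly 1
        np.testing.assert_allclose(alpha, 1.0)

    def test_two_identical_nodes_split_attention_evenly_with_tied_transforms(self):
        attr = np.zeros((2, 2, 4))
        attr[0, 1, 0] = attr[1, 0, 0] = 0.5
        fg = FinalGraph(["mRNA:a", "mRNA:b"], attr, 0.5)
        cfg = small_cfg(use_edge_attr=False)
        params = _init_params(cfg, 2, 2)
        # tie the self and neighbor transforms so symmetry is exact
        params["gat0.theta_t.W"].data = params["gat0.theta_s.W"].data.copy()
        params["gat0.theta_t.b"].data = params["gat0.theta_s.b"].data.copy()
        x = np.eye(3)[np.array([[1, 1]])]  # identical node features
        src, dst, attr_e = fg.directed_edges()
        h = Tensor(x) @ params["proj.W"] + params["proj.b"]
        _, alpha = gat_layer_forward(params, "gat0", cfg, h, src, dst, attr_e)
        np.testing.assert_allclose(alpha, 0.5, atol=1e-12)

    def test_exchangeable_nodes_have_symmetric_attention(self):
        attr = np.zeros((2, 2, 4))
        attr[0, 1, 0] = attr[1, 0, 0] = 0.5
        fg = FinalGraph(["mRNA:a", "mRNA:b"], attr, 0.5)
        cfg = small_cfg()
        params = _init_params(cfg, 2, 2)
        x = np.eye(3)[np.array([[2, 2]])]
        src, dst, attr_e = fg.directed_edges()
        h = Tensor(x) @ params["proj.W"] + params["proj.b"]
        _, alpha = gat_layer_forward(params, "gat0", cfg, h, src, dst, attr_e)
        # directed edges (0<-1) and (1<-0) carry equal weight; self terms equal
        assert alpha[0, 0] == pytest.approx(alpha[0, 1])
        assert alpha[0, 2] == pytest.approx(alpha[0, 3])


class TestGraphEncoder:
    def test_permutation_invariant_embedding(self):
        rng = np.random.default_rng(2)
        m = 6
        fg = random_graph(m, rng)
        cfg = small_cfg()
        params = _init_params(cfg, m, 2)
        levels = rng.integers(0, 3, size=(4, m))
        x = np.eye(3)[levels]
        src, dst, attr = fg.directed_edges()
        emb, _ = graph_encoder_forward(params, cfg, Tensor(x), src, dst, attr)

        perm = rng.permutation(m)
        inv = np.argsort(perm)
        x_p = x[:, perm, :]
        attr_p = fg.edge_attr[perm][:, perm]
        fg_p = FinalGraph([fg.nodes[i] for i in perm], attr_p, fg.lam)
        src_p, dst_p, attr_ep = fg_p.directed_edges()
        emb_p, _ = graph_encoder_forward(params, cfg, Tensor(x_p), src_p, dst_p,
                                         attr_ep)
        np.testing.assert_allclose(emb.data, emb_p.data, atol=1e-5)

    def test_zero_edge_graph_runs_on_node_features_only(self):
        rng = np.random.default_rng(3)
        fg = random_graph(4, rng, edge_prob=0.0)
        cfg = small_cfg()
        params = _init_params(cfg, 4, 2)
        x = np.eye(3)[rng.integers(0, 3, size=(2, 4))]
        src, dst, attr = fg.directed_edges()
        emb, att = graph_encoder_forward(params, cfg, Tensor(x), src, dst, attr)
        assert emb.data.shape == (2, cfg.hidden_dim)
        assert np.isfinite(emb.data).all()

    def test_identical_samples_identical_embeddings(self):
        rng = np.random.default_rng(4)
        fg = random_graph(5, rng)
        cfg = small_cfg()
        params = _init_params(cfg, 5, 2)
        x1 = np.eye(3)[rng.integers(0, 3, size=(1, 5))]
        x = np.concatenate([x1, x1])
        src, dst, attr = fg.directed_edges()
        emb, _ = graph_encoder_forward(params, cfg, Tensor(x), src, dst, attr)
        np.testing.assert_allclose(emb.data[0], emb.data[1])


class TestGlobalEncoderAndFusion:
    def test_shape_contract(self):
        cfg = small_cfg()
        params = _init_params(cfg, 10, 3)
        out = global_encoder_forward(params, cfg, Tensor(np.random.default_rng(0)
                                                         .normal(size=(4, 10))))
        assert out.data.shape == (4, cfg.hidden_dim)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(5)
        fg = random_graph(5, rng)
        graphs = sample_graphs(fg, 6, rng)
        xg = rng.normal(size=(6, 5))
        cfg = small_cfg(epochs=2)
        model = train(graphs, xg, [g.label for g in graphs], cfg)
        probs = predict_proba(model, graphs, xg)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape == (6, 2)

    def test_gradient_flows_to_both_branches(self):
        rng = np.random.default_rng(6)
        fg = random_graph(4, rng)
        graphs = sample_graphs(fg, 4, rng)
        cfg = small_cfg(dropout=0.0)
        params = _init_params(cfg, 4, 2)
        x_onehot = np.stack([g.node_features for g in graphs])
        xg = rng.normal(size=(4, 4))
        src, dst, attr = fg.directed_edges()
        logits, _ = _forward(params, cfg, Tensor(x_onehot), Tensor(xg), src, dst, attr)
        loss = cross_entropy(logits, np.eye(2)[[0, 1, 0, 1]])
        loss.backward()
        assert np.abs(params["gat0.theta_t.W"].grad).max() > 0
        assert np.abs(params["global0.W"].grad).max() > 0
        assert np.abs(params["gat0.W_e"].grad).max() > 0


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        logits = Tensor(np.array([[100.0, 0.0], [0.0, 100.0]]))
        assert float(cross_entropy(logits, np.eye(2)).data) == pytest.approx(0.0, abs=1e-8)

    def test_uniform_prediction_is_log_c(self):
        for c in (2, 3, 5):
            logits = Tensor(np.zeros((4, c)))
            y = np.eye(c)[np.zeros(4, dtype=int)]
            assert float(cross_entropy(logits, y).data) == pytest.approx(np.log(c))


class TestTraining:
    def _separable(self, rng, n=30, m=6):
        fg = random_graph(m, rng)
        graphs = []
        xg = np.zeros((n, m))
        labels = []
        for i in range(n):
            cls = i % 2
            levels = np.full(m, 2 if cls else 0)
            graphs.append(SampleGraph(fg, np.eye(3)[levels], "AB"[cls], f"s{i}"))
            xg[i] = rng.normal(size=m) + (3.0 if cls else -3.0)
            labels.append("AB"[cls])
        return graphs, xg, labels

    def test_separable_data_trains_to_high_accuracy(self):
        rng = np.random.default_rng(7)
        graphs, xg, labels = self._separable(rng)
        cfg = small_cfg(epochs=60)
        model = train(graphs, xg, labels, cfg)
        probs = predict_proba(model, graphs, xg)
        preds = np.array(["AB"[i] for i in probs.argmax(axis=1)])
        assert (preds == np.array(labels)).mean() >= 0.95

    def test_seeded_determinism(self):
        rng1, rng2 = np.random.default_rng(8), np.random.default_rng(8)
        g1, x1, y1 = self._separable(rng1, n=10, m=4)
        g2, x2, y2 = self._separable(rng2, n=10, m=4)
        cfg = small_cfg(epochs=5, seed=3)
        m1 = train(g1, x1, y1, cfg)
        m2 = train(g2, x2, y2, cfg)
        assert m1.loss_history == m2.loss_history

    def test_single_class_raises(self):
        rng = np.random.default_rng(9)
        fg = random_graph(3, rng)
        graphs = sample_graphs(fg, 4, rng, classes=("A",))
        with pytest.raises(ValueError):
            train(graphs, rng.normal(size=(4, 3)), ["A"] * 4, small_cfg())

    def test_branch_ablations_run(self):
        rng = np.random.default_rng(10)
        graphs, xg, labels = self._separable(rng, n=8, m=4)
        for flags in ({"use_gnn": False}, {"use_dnn": False}):
            cfg = small_cfg(epochs=3, **flags)
            model = train(graphs, xg, labels, cfg)
            assert len(model.loss_history) == 3
        with pytest.raises(ValueError):
            small_cfg(use_gnn=False, use_dnn=False)


class TestExtractAttention:
    def test_records_cover_directed_edges_plus_self_loops(self):
        rng = np.random.default_rng(11)
        fg = random_graph(5, rng)
        graphs = sample_graphs(fg, 4, rng)
        model = train(graphs, rng.normal(size=(4, 5)), [g.label for g in graphs],
                      small_cfg(epochs=2))
        att = extract_attention(model, graphs)
        src, dst, _ = fg.directed_edges()
        assert len(att.edge_src) == len(src) + 5
        assert att.self_mask.sum() == 5
        directed = set(zip(att.edge_src[~att.self_mask], att.edge_dst[~att.self_mask]))
        assert directed == set(zip(src, dst))

    def test_rows_normalized_for_every_sample_and_layer(self):
        rng = np.random.default_rng(12)
        fg = random_graph(6, rng)
        graphs = sample_graphs(fg, 3, rng)
        model = train(graphs, rng.normal(size=(3, 6)), [g.label for g in graphs],
                      small_cfg(epochs=2))
        att = extract_attention(model, graphs)
        for layer in att.alpha:
            np.testing.assert_allclose(row_sums(att.alpha[layer], att.edge_dst, 6),
                                       1.0, atol=1e-6)

    def test_single_sample_average_is_that_sample(self):
        rng = np.random.default_rng(13)
        fg = random_graph(4, rng)
        graphs = sample_graphs(fg, 2, rng)
        model = train(graphs, rng.normal(size=(2, 4)), [g.label for g in graphs],
                      small_cfg(epochs=2))
        att_one = extract_attention(model, graphs[:1])
        att_two = extract_attention(model, graphs)
        np.testing.assert_allclose(att_one.alpha[0][0], att_two.alpha[0][0])
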