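"""Graph construction and the graph attention task classifier."""

import numpy as np
import pytest
from scipy.special import logsumexp

from causalfp import (
    SignatureGraph,
    TaskClassifierConfig,
    build_signature_graph,
    init_classifier,
    predict_task,
    train_classifier,
)
from causalfp.task import _TopKPool, _stack_graphs, evaluate_accuracy

from conftest import make_stable_signature


class TestBuildSignatureGraph:
    def test_feature_width_is_2m_plus_2n(self, rng):
        sig = make_stable_signature(rng, m=6, n=3)
        g = build_signature_graph(sig, label=2)
        assert g.num_nodes == 6
        assert g.feature_dim == 2 * 6 + 2 * 3
        np.testing.assert_array_equal(g.node_features, sig.R)

    def test_row_normalized_adjacency_sums_to_one(self, rng):
        sig = make_stable_signature(rng, m=5, n=2)
        g = build_signature_graph(sig, label=0)
        # direct recomputation oracle
        expected = np.abs(sig.A) / np.abs(sig.A).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(g.adjacency, expected, atol=1e-12)
        np.testing.assert_allclose(g.adjacency.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_transition_gives_empty_edge_set(self):
        from causalfp import CausalSignature

        sig = CausalSignature(
            Q=np.zeros((4, 4)), A=np.zeros((4, 4)),
            B1=np.zeros((4, 1)), B2=np.zeros((4, 1)), dt=0.72,
        )
        g = build_signature_graph(sig, label=1)
        assert g.edges == []
        assert g.node_features.shape == (4, 10)

    def test_alternative_normalizations(self, rng):
        sig = make_stable_signature(rng, m=4, n=1)
        sym = build_signature_graph(sig, 0, adjacency_scheme="sym").adjacency
        mx = build_signature_graph(sig, 0, adjacency_scheme="maxabs").adjacency
        assert np.allclose(sym, sym.T) == np.allclose(np.abs(sig.A), np.abs(sig.A).T)
        assert mx.max() == pytest.approx(1.0)


class TestClassifierConfig:
    def test_width_invariants_enforced(self):
        with pytest.raises(ValueError, match="skip1"):
            TaskClassifierConfig(heads1=4, out1=32, skip1=64)
        with pytest.raises(ValueError, match="pool_ratio"):
            TaskClassifierConfig(pool_ratio=1.5)

    def test_default_widths_match_architecture(self):
        cfg = TaskClassifierConfig()
        assert (cfg.heads1, cfg.out1, cfg.skip1) == (4, 32, 128)
        assert (cfg.heads2, cfg.out2, cfg.skip2) == (2, 2 * 16, 64)


def toy_graphs(rng, n_per_class=12, classes=3, m=6):
    """Separable toy set: class signal injected into node features."""
    graphs = []
    for c in range(classes):
        pattern = rng.normal(size=(m, 2 * m))
        for _ in range(n_per_class):
            feats = pattern + 0.3 * rng.normal(size=(m, 2 * m))
            adj = np.abs(rng.normal(size=(m, m)))
            adj /= adj.sum(axis=1, keepdims=True)
            graphs.append(SignatureGraph(feats, adj, label=c))
    return graphs


class TestClassifier:
    def test_forward_outputs_valid_log_probabilities(self, rng):
        cfg = TaskClassifierConfig(classes=8, seed=0)
        graphs = toy_graphs(rng, n_per_class=2, classes=2, m=6)
        clf = init_classifier(cfg, graphs[0].feature_dim)
        feats, adj, _ = _stack_graphs(graphs)
        logp = clf.forward(feats, adj)
        assert logp.shape == (len(graphs), 8)
        np.testing.assert_allclose(logsumexp(logp.data, axis=1), 0.0, atol=1e-6)

    def test_topk_pooling_keeps_ceil_ratio_nodes(self, rng):
        # 90-node graph at ratio 0.8 keeps ceil(72) = 72 nodes
        from causalfp.nn import Tensor

        pool = _TopKPool(np.random.default_rng(0), in_dim=8, ratio=0.8)
        X = Tensor(rng.normal(size=(2, 90, 8)))
        adj = rng.normal(size=(2, 90, 90))
        Xk, adj_k = pool(X, adj)
        assert Xk.shape == (2, 72, 8)
        assert adj_k.shape == (2, 72, 72)

    def test_training_loss_decreases_on_separable_toy(self, rng):
        # median over 5 seeds: loss after 10 epochs below the initial loss
        drops = []
        for seed in range(5):
            graphs = toy_graphs(np.random.default_rng(seed), n_per_class=8, classes=3)
            cfg = TaskClassifierConfig(
                classes=3, epochs=10, seed=seed, val_fraction=0.0, patience=100
            )
            clf = init_classifier(cfg, graphs[0].feature_dim)
            hist = train_classifier(clf, graphs, cfg)
            drops.append(hist["loss"][0] - hist["loss"][-1])
        assert np.median(drops) > 0

    def test_inference_is_deterministic(self, rng):
        graphs = toy_graphs(rng, n_per_class=4, classes=2)
        cfg = TaskClassifierConfig(classes=2, epochs=5, seed=1, val_fraction=0.0)
        clf = init_classifier(cfg, graphs[0].feature_dim)
        train_classifier(clf, graphs, cfg)
        _, lp1 = predict_task(clf, graphs[0])
        _, lp2 = predict_task(clf, graphs[0])
        np.testing.assert_array_equal(lp1, lp2)

    def test_seed_determinism_of_training(self, rng):
        graphs = toy_graphs(rng, n_per_class=4, classes=2)
        params = []
        for _ in range(2):
            cfg = TaskClassifierConfig(classes=2, epochs=3, seed=42, val_fraction=0.0)
            clf = init_classifier(cfg, graphs[0].feature_dim)
            train_classifier(clf, graphs, cfg)
            params.append(np.concatenate([p.data.ravel() for p in clf.params()]))
        np.testing.assert_array_equal(params[0], params[1])

    def test_single_class_training_rejected(self, rng):
        graphs = [g for g in toy_graphs(rng, n_per_class=4, classes=2) if g.label == 0]
        cfg = TaskClassifierConfig(classes=2, epochs=2, seed=0)
        clf = init_classifier(cfg, graphs[0].feature_dim)
        with pytest.raises(ValueError, match="single class"):
            train_classifier(clf, graphs, cfg)

    def test_untrained_predict_rejected(self, rng):
        graphs = toy_graphs(rng, n_per_class=1, classes=2)
        clf = init_classifier(TaskClassifierConfig(classes=2), graphs[0].feature_dim)
        with pytest.raises(RuntimeError):
            predict_task(clf, graphs[0])

    def test_feature_width_mismatch_rejected(self, rng):
        graphs = toy_graphs(rng, n_per_class=2, classes=2, m=6)
        clf = init_classifier(TaskClassifierConfig(classes=2), feature_dim=99)
        feats, adj, _ = _stack_graphs(graphs)
        with pytest.raises(ValueError, match="width"):
            clf.forward(feats, adj)

    def test_degenerate_labels_predict_majority_class(self, rng):
        # two classes present but heavily imbalanced: prediction should lean
        # to the majority prior on uninformative features
        m = 5
        graphs = []
        for i in range(20):
            feats = rng.normal(size=(m, 2 * m))
            adj = np.abs(rng.normal(size=(m, m)))
            adj /= adj.sum(axis=1, keepdims=True)
            graphs.append(SignatureGraph(feats, adj, label=0 if i < 18 else 1))
        cfg = TaskClassifierConfig(classes=2, epochs=30, seed=0, val_fraction=0.0)
        clf = init_classifier(cfg, graphs[0].feature_dim)
        train_classifier(clf, graphs, cfg)
        fresh = SignatureGraph(
            rng.normal(size=(m, 2 * m)), np.eye(m), label=0
        )
        label, _ = predict_task(clf, fresh)
        assert label == 0

    def test_save_load_round_trip(self, rng, tmp_path):
        from causalfp.task import load_classifier, save_classifier

        graphs = toy_graphs(rng, n_per_class=3, classes=2)
        cfg = TaskClassifierConfig(classes=2, epochs=3, seed=0, val_fraction=0.0)
        clf = init_classifier(cfg, graphs[0].feature_dim)
        train_classifier(clf, graphs, cfg)
        save_classifier(clf, tmp_path / "model.npz")
        clf2 = load_classifier(tmp_path / "model.npz")
        assert evaluate_accuracy(clf, graphs) == evaluate_accuracy(clf2, graphs)
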