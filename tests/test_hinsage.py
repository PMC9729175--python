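import numpy as np
import pandas as pd
import pytest

from conftest import random_bipartite
from emrgraph.bipartite import BipartiteGraph
from emrgraph.errors import ConfigError, ConsistencyError
from emrgraph.hinsage import (
    PATIENT,
    DIAGNOSIS,
    HinsageLinkModel,
    SamplerConfig,
    TrainConfig,
    link_score,
    predict_links,
    sample_neighbors,
    stratified_edge_split,
    train_link_model,
)
from oracles import dense_hinsage_embedding


def _star_graph() -> BipartiteGraph:
    """One diagnosis node shared by five patients (degree 5)."""
    pat = pd.DataFrame(np.eye(5), index=[f"p_{i}" for i in range(5)])
    diag = pd.DataFrame([[1.0, 2.0]], index=["d_0"])
    edges = pd.DataFrame(
        {"source": [f"p_{i}" for i in range(5)], "target": ["d_0"] * 5, "outcome": [0, 1, 0, 1, 0]}
    )
    return BipartiteGraph(pat, diag, edges)


class TestSampling:
    def test_samples_are_neighbors(self):
        graph = _star_graph()
        layers = sample_neighbors(graph, ["d_0"], SamplerConfig(num_samples=(2, 2), seed=0))
        first = layers[0][0]
        assert len(first) == 2
        assert set(first) <= {f"p_{i}" for i in range(5)}

    def test_single_neighbor_repeats_with_replacement(self):
        graph = _star_graph()
        layers = sample_neighbors(graph, ["p_3"], SamplerConfig(num_samples=(3, 1), seed=0))
        assert layers[0][0] == ["d_0", "d_0", "d_0"]

    def test_exhaustive_returns_full_multiset(self):
        graph = _star_graph()
        layers = sample_neighbors(graph, ["d_0"], SamplerConfig(num_samples=(2, 2), seed=0, exhaustive=True))
        assert sorted(layers[0][0]) == [f"p_{i}" for i in range(5)]

    def test_invalid_sampler_config(self):
        with pytest.raises(ConfigError):
            SamplerConfig(num_samples=(0, 4))


class TestForward:
    def test_identity_weight_concatenation(self):
        """With identity weights and linear output, the embedding is
        [self features, mean neighbor features]."""
        pat = pd.DataFrame([[1.0, 0.0]], index=["p_0"])
        diag = pd.DataFrame([[2.0, -1.0]], index=["d_0"])
        edges = pd.DataFrame({"source": ["p_0"], "target": ["d_0"], "outcome": [1]})
        graph = BipartiteGraph(pat, diag, edges)
        model = HinsageLinkModel(graph, hidden=(4, 4), seed=0)
        for t in (PATIENT, DIAGNOSIS):
            model.params[f"W_self_1_{t}"] = np.eye(2)
            model.params[f"W_neigh_1_{t}"] = np.eye(2)
            model.params[f"b_1_{t}"] = np.zeros(4)
            model.params[f"W_self_2_{t}"] = np.eye(4)[:, :2]
            model.params[f"W_neigh_2_{t}"] = np.eye(4)[:, :2]
            model.params[f"b_2_{t}"] = np.zeros(4)
        cfg = SamplerConfig(num_samples=(1, 1), seed=0, exhaustive=True)
        nodes = np.array([0])
        rng = np.random.default_rng(0)
        z, cache = model._forward_tree(nodes, PATIENT, rng, True, (1, 1))
        # layer-1 output before layer 2: [x_p, x_d] = [1, 0, 2, -1]
        assert np.allclose(cache["h1_self"], np.maximum([1.0, 0.0, 2.0, -1.0], 0))

    def test_zero_params_give_zero_pre_normalization_embeddings(self):
        graph = _star_graph()
        model = HinsageLinkModel(graph, hidden=(4, 4), seed=0)
        for key, val in model.params.items():
            model.params[key] = np.zeros_like(val)
        rng = np.random.default_rng(0)
        _, cache = model._forward_tree(np.array([0, 1]), PATIENT, rng, True, (2, 2))
        pre = cache["z"] * cache["norms"]  # undo normalization
        assert np.allclose(pre, 0.0)

    def test_matches_dense_oracle_on_fuzzed_graphs(self):
        rng = np.random.default_rng(7)
        for trial in range(30):
            graph = random_bipartite(rng)
            model = HinsageLinkModel(graph, hidden=(6, 4), seed=trial)
            cfg = SamplerConfig(exhaustive=True, seed=0)
            for part, ids in [
                (PATIENT, graph.patient_features.index),
                (DIAGNOSIS, graph.diagnosis_features.index),
            ]:
                z = model.embed(list(ids), part, cfg)
                for i, nid in enumerate(ids):
                    expected = dense_hinsage_embedding(graph, model.params, nid)
                    assert np.allclose(z[i], expected, atol=1e-6)

    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        graph = random_bipartite(rng, n_patients=5, n_diag=3)
        model = HinsageLinkModel(graph, hidden=(4, 4), seed=5)
        p, d, y = model._edge_indices(graph.edges)

        def loss_at(key, idx, delta):
            saved = model.params[key].copy()
            model.params[key].flat[idx] += delta
            probs, _ = model._forward_edges(p, d, np.random.default_rng(0), True, (2, 2))
            model.params[key] = saved
            eps = 1e-12
            return float(-np.mean(y * np.log(probs + eps) + (1 - y) * np.log(1 - probs + eps)))

        probs, (zp, cp, zd, cd, u) = model._forward_edges(p, d, np.random.default_rng(0), True, (2, 2))
        grads = {k: np.zeros_like(v) for k, v in model.params.items()}
        g = (probs - y) / len(y)
        grads["w_link"] += u.T @ g
        grads["b_link"] += g.sum()
        du = g[:, None] * model.params["w_link"][None, :]
        h2 = model.hidden[1]
        model._backward_tree(du[:, :h2], cp, grads)
        model._backward_tree(du[:, h2:], cd, grads)
        for key in ["W_self_1_patient", "W_neigh_2_diagnosis", "b_1_diagnosis", "w_link"]:
            for idx in range(0, model.params[key].size, max(1, model.params[key].size // 4)):
                numeric = (loss_at(key, idx, 1e-6) - loss_at(key, idx, -1e-6)) / 2e-6
                assert grads[key].flat[idx] == pytest.approx(numeric, abs=1e-6)


class TestLinkHead:
    def test_zero_head_gives_half(self):
        z = np.ones((3, 4))
        assert np.allclose(link_score(z, z, np.zeros(8), 0.0), 0.5)

    def test_hadamard_annihilation(self):
        z = np.zeros((2, 4))
        w = np.ones(4)
        probs = link_score(z, np.ones((2, 4)), w, 0.7, operator="hadamard")
        assert np.allclose(probs, 1.0 / (1.0 + np.exp(-0.7)))

    def test_monotone_in_logit(self):
        w = np.ones(4)
        low = link_score(np.full((1, 2), 0.1), np.full((1, 2), 0.1), w, 0.0)
        high = link_score(np.full((1, 2), 0.9), np.full((1, 2), 0.9), w, 0.0)
        assert high > low

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ConsistencyError):
            link_score(np.ones((1, 3)), np.ones((1, 4)), np.ones(6), 0.0)


class TestTraining:
    def test_history_has_one_entry_per_epoch(self, small_bipartite):
        train, val = stratified_edge_split(small_bipartite.edges, 0.8, 0)
        _, history = train_link_model(
            small_bipartite, train, val, SamplerConfig(seed=1), TrainConfig(epochs=4, seed=1)
        )
        assert len(history) == 4
        for series in (history.train_loss, history.train_acc, history.val_loss, history.val_acc):
            assert len(series) == 4

    def test_training_is_seed_deterministic(self, small_bipartite):
        train, val = stratified_edge_split(small_bipartite.edges, 0.8, 0)
        histories = []
        for _ in range(2):
            _, h = train_link_model(
                small_bipartite, train, val, SamplerConfig(seed=2), TrainConfig(epochs=3, seed=2)
            )
            histories.append(h)
        assert histories[0] == histories[1]

    def test_single_class_labels_warn_but_train(self, small_bipartite):
        edges = small_bipartite.edges.copy()
        edges["outcome"] = 0
        with pytest.warns(UserWarning):
            _, history = train_link_model(
                small_bipartite, edges, edges, SamplerConfig(seed=1), TrainConfig(epochs=1, seed=1)
            )
        assert len(history) == 1

    def test_sgd_small_step_loss_non_increasing(self):
        """On one fixed tiny batch with lr=1e-4, the first 10 plain-gradient
        steps never increase the loss."""
        rng = np.random.default_rng(11)
        graph = random_bipartite(rng, n_patients=8, n_diag=4)
        model = HinsageLinkModel(graph, seed=4)
        p, d, y = model._edge_indices(graph.edges)
        losses = []
        for step in range(10):
            loss, _, grads = model._loss_and_grads(p, d, y, np.random.default_rng(0), (2, 2))
            model._step(grads, 1e-4, "sgd")
            losses.append(loss)
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))

    def test_predictions_deterministic_and_bounded(self, small_bipartite):
        train, val = stratified_edge_split(small_bipartite.edges, 0.8, 0)
        model, _ = train_link_model(
            small_bipartite, train, val, SamplerConfig(seed=5), TrainConfig(epochs=2, seed=5)
        )
        a = predict_links(model, small_bipartite, val, SamplerConfig(seed=9))
        b = predict_links(model, small_bipartite, val, SamplerConfig(seed=9))
        assert np.array_equal(a, b)
        assert ((a > 0) & (a < 1)).all()

    def test_missing_endpoint_rejected(self, small_bipartite):
        model = HinsageLinkModel(small_bipartite, seed=0)
        bad = pd.DataFrame({"source": ["p_nope"], "target": ["d_nope"], "outcome": [0]})
        with pytest.raises(ConsistencyError):
            model.predict(bad)

    def test_save_load_roundtrip(self, small_bipartite, tmp_path):
        model = HinsageLinkModel(small_bipartite, seed=3)
        path = tmp_path / "model.npz"
        model.save(path)
        back = HinsageLinkModel.load(path, small_bipartite)
        probs_a = model.predict(small_bipartite.edges.head(10), SamplerConfig(seed=1))
        probs_b = back.predict(small_bipartite.edges.head(10), SamplerConfig(seed=1))
        assert np.allclose(probs_a, probs_b)

    def test_exhaustive_prediction_matches_dense_oracle_scoring(self):
        rng = np.random.default_rng(23)
        graph = random_bipartite(rng, n_patients=6, n_diag=3)
        model = HinsageLinkModel(graph, seed=8)
        probs = model.predict(graph.edges, SamplerConfig(exhaustive=True, seed=0))
        w, b = model.params["w_link"], float(model.params["b_link"])
        for i, row in graph.edges.iterrows():
            zs = dense_hinsage_embedding(graph, model.params, row["source"])
            zd = dense_hinsage_embedding(graph, model.params, row["target"])
            expected = link_score(zs, zd, w, b, model.operator)[0]
            assert probs[i] == pytest.approx(expected, abs=1e-6)
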