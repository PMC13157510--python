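"""The heat-kernel GIN: update rule, readouts, losses, invariances."""

import numpy as np
import networkx as nx
import pytest

from heatconn.autodiff import SGD, Tensor
from heatconn.model import (GinLayerParams, GraphBatch, HkdMgin,
                            HkdMginConfig, ModelError, Prediction,
                            concat_layer_readouts, fuse_modalities,
                            gin_update, readout_sum, reconstruction_loss,
                            supervised_loss, total_loss)

from conftest import manual_batch


class TestGinUpdate:
    def test_no_edges_identity(self):
        h = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = gin_update(h, np.zeros((2, 2)), GinLayerParams.identity())
        np.testing.assert_array_equal(out, h)

    def test_two_node_hand_value(self):
        h = np.array([[1.0], [2.0]])
        w = np.array([[0.0, 1.0], [1.0, 0.0]])
        out = gin_update(h, w, GinLayerParams.identity())
        np.testing.assert_array_equal(out, [[3.0], [3.0]])

    def test_eps_minus_one_zeroes_self_term(self):
        h = np.array([[1.0], [2.0]])
        out = gin_update(h, np.zeros((2, 2)),
                         GinLayerParams.identity(eps=-1.0))
        np.testing.assert_array_equal(out, 0.0)

    def test_invalid_weights_rejected(self):
        h = np.ones((2, 2))
        with pytest.raises(ModelError, match="symmetric"):
            gin_update(h, np.array([[0, 1.0], [0.5, 0]]),
                       GinLayerParams.identity())
        with pytest.raises(ModelError, match="diagonal"):
            gin_update(h, np.eye(2), GinLayerParams.identity())


class TestReadoutAndFusion:
    def test_readout_sum_values(self):
        np.testing.assert_array_equal(
            readout_sum(np.array([[1.0, 2.0], [3.0, 4.0]])), [4.0, 6.0])
        np.testing.assert_array_equal(readout_sum(np.zeros((3, 2))), 0.0)
        np.testing.assert_array_equal(
            readout_sum(np.array([[5.0, -1.0]])), [5.0, -1.0])

    def test_concat_layer_readouts(self):
        out = concat_layer_readouts([np.array([1.0]), np.array([2.0, 3.0])])
        np.testing.assert_array_equal(out, [1.0, 2.0, 3.0])
        np.testing.assert_array_equal(
            concat_layer_readouts([np.array([7.0])]), [7.0])
        dims = concat_layer_readouts(
            [np.zeros(3), np.zeros(2), np.zeros(2)]).size
        assert dims == 7

    def test_fuse_modalities_order_and_missing(self):
        emb = {"emoid": np.array([1.0, -2.0]), "nback": np.array([3.0])}
        np.testing.assert_array_equal(
            fuse_modalities(emb, ("emoid", "nback")), [1.0, -2.0, 3.0])
        np.testing.assert_array_equal(
            fuse_modalities(emb, ("nback", "emoid")), [3.0, 1.0, -2.0])
        np.testing.assert_array_equal(
            fuse_modalities({"emoid": emb["emoid"]}, ("emoid",)), [1.0, -2.0])
        with pytest.raises(ModelError, match="missing"):
            fuse_modalities({"emoid": emb["emoid"]}, ("emoid", "nback"))


class TestLosses:
    def test_reconstruction_values(self):
        a = np.zeros((2, 2))
        k = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert reconstruction_loss({"m": a}, {"m": a}) == 0.0
        assert reconstruction_loss({"m": k}, {"m": a}) == pytest.approx(2.0)
        two = reconstruction_loss({"m1": k, "m2": k}, {"m1": a, "m2": a})
        assert two == pytest.approx(4.0)

    def test_reconstruction_shape_mismatch(self):
        with pytest.raises(ModelError, match="shape"):
            reconstruction_loss({"m": np.zeros((2, 2))},
                                {"m": np.zeros((3, 3))})

    def test_supervised_age_mse(self):
        p = Prediction(age_estimate=np.array([11.0, 13.0]))
        assert supervised_loss(p, {"age": [10.0, 12.0]}) == pytest.approx(1.0)
        perfect = Prediction(age_estimate=np.array([10.0, 12.0]))
        assert supervised_loss(perfect, {"age": [10.0, 12.0]}) == 0.0

    def test_supervised_sex_bce(self):
        p = Prediction(sex_probability=np.array([0.5, 0.5]))
        val = supervised_loss(p, {"sex": [0, 1]}, task="sex")
        assert val == pytest.approx(np.log(2), abs=1e-12)

    def test_sex_labels_validated(self):
        p = Prediction(sex_probability=np.array([0.5]))
        with pytest.raises(ModelError, match="labels"):
            supervised_loss(p, {"sex": [2]}, task="sex")

    def test_total_loss_arithmetic(self):
        a = np.zeros((2, 2))
        k = np.array([[0.0, 1.0], [1.0, 0.0]])  # reconstruction 2.0
        p = Prediction(age_estimate=np.array([11.0, 10.0, 11.0]))
        t = {"age": np.array([10.0, 11.0, 12.0])}  # per-subject sum 3.0
        assert total_loss({"m": k}, {"m": a}, p, t, lam=2.0) == pytest.approx(8.0)
        assert total_loss({"m": k}, {"m": a}, p, t, lam=0.0) == pytest.approx(2.0)
        perfect = Prediction(age_estimate=t["age"].copy())
        assert total_loss({"m": a}, {"m": a}, perfect, t, lam=3.0) == 0.0


class TestForward:
    def test_node_relabeling_invariance(self):
        rng = np.random.default_rng(11)
        batch = manual_batch(rng, s=2, n=7)
        cfg = HkdMginConfig(n_rois=7, modalities=batch.modalities,
                            hidden_dim=6, beta=0.4, learn_beta=False, seed=1)
        model = HkdMgin(cfg)
        base = model.forward(batch).age_estimate
        perm = rng.permutation(7)
        p = np.eye(7)[perm]
        permuted = GraphBatch(
            modalities=batch.modalities,
            features={m: v[:, perm, :] for m, v in batch.features.items()},
            adjacency={m: p @ v @ p.T for m, v in batch.adjacency.items()},
            eigvals=batch.eigvals,
            eigvecs={m: v[:, perm, :] for m, v in batch.eigvecs.items()},
            ages=batch.ages, sexes=batch.sexes)
        out = model.forward(permuted).age_estimate
        np.testing.assert_allclose(out, base, atol=1e-6)

    def test_identical_subjects_identical_predictions(self):
        rng = np.random.default_rng(12)
        batch = manual_batch(rng, s=1, n=6)
        dup = GraphBatch(
            modalities=batch.modalities,
            features={m: np.repeat(v, 2, axis=0) for m, v in batch.features.items()},
            adjacency={m: np.repeat(v, 2, axis=0) for m, v in batch.adjacency.items()},
            eigvals={m: np.repeat(v, 2, axis=0) for m, v in batch.eigvals.items()},
            eigvecs={m: np.repeat(v, 2, axis=0) for m, v in batch.eigvecs.items()},
            ages=np.array([10.0, 10.0]), sexes=np.array([0.0, 0.0]))
        cfg = HkdMginConfig(n_rois=6, modalities=batch.modalities,
                            hidden_dim=5, seed=3)
        pred = HkdMgin(cfg).forward(dup)
        assert pred.age_estimate[0] == pred.age_estimate[1]

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        batch = manual_batch(rng, s=3, n=6)
        cfg = HkdMginConfig(n_rois=6, modalities=batch.modalities,
                            hidden_dim=5, seed=9)
        a = HkdMgin(cfg).forward(batch).age_estimate
        b = HkdMgin(cfg).forward(batch).age_estimate
        np.testing.assert_array_equal(a, b)

    def test_checkpoint_roundtrip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(14)
        batch = manual_batch(rng, s=2, n=6)
        cfg = HkdMginConfig(n_rois=6, modalities=batch.modalities,
                            hidden_dim=4, seed=5, learn_beta=True)
        model = HkdMgin(cfg)
        model.target_mean, model.target_scale = 15.0, 4.0
        before = model.forward(batch).age_estimate
        model.save(tmp_path / "ck.npz")
        after = HkdMgin.load(tmp_path / "ck.npz").forward(batch).age_estimate
        np.testing.assert_array_equal(before, after)


class TestGradientsAndTraining:
    def test_total_loss_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(15)
        batch = manual_batch(rng, s=3, n=6)
        cfg = HkdMginConfig(n_rois=6, modalities=batch.modalities,
                            hidden_dim=4, seed=2, learn_beta=True, lam=0.5)
        model = HkdMgin(cfg)
        loss = model.loss(batch)
        loss.backward()
        params = model.parameters()
        picks = rng.choice(len(params), size=min(10, len(params)),
                           replace=False)
        eps = 1e-6
        for pi in picks:
            p = params[pi]
            flat_idx = rng.integers(p.value.size)
            idx = np.unravel_index(flat_idx, p.value.shape)
            orig = p.value[idx]
            p.value[idx] = orig + eps
            fp = float(model.loss(batch).value)
            p.value[idx] = orig - eps
            fm = float(model.loss(batch).value)
            p.value[idx] = orig
            num = (fp - fm) / (2 * eps)
            auto = p.grad[idx]
            denom = max(abs(num), abs(auto), 1e-8)
            assert abs(num - auto) / denom <= 1e-4

    def test_learnable_beta_reconstruction_descends(self):
        rng = np.random.default_rng(16)
        batch = manual_batch(rng, s=2, n=6)
        cfg = HkdMginConfig(n_rois=6, modalities=batch.modalities,
                            hidden_dim=4, seed=4, learn_beta=True, lam=0.0)
        model = HkdMgin(cfg)
        betas = list(model.beta_raw.values())
        opt = SGD(betas, lr=1e-4)
        prev = np.inf
        for _ in range(20):
            loss = model.loss(batch)  # lam=0: pure reconstruction
            val = float(loss.value)
            assert val <= prev + 1e-6
            prev = val
            opt.zero_grad()
            loss.backward()
            opt.step()


def wl_catalog():
    """Pairs of non-isomorphic small graphs distinguishable by 1-WL."""
    pairs = [
        (nx.path_graph(4), nx.star_graph(3)),
        (nx.cycle_graph(4), nx.path_graph(4)),
        (nx.cycle_graph(5), nx.path_graph(5)),
        (nx.cycle_graph(8), nx.path_graph(8)),
        (nx.complete_graph(4), nx.cycle_graph(4)),
        (nx.star_graph(5), nx.path_graph(6)),
        (nx.complete_bipartite_graph(3, 3), nx.cycle_graph(6)),
        (nx.wheel_graph(5), nx.complete_graph(5)),
        (nx.lollipop_graph(4, 2), nx.path_graph(6)),
        (nx.barbell_graph(3, 1), nx.cycle_graph(7)),
    ]
    for g, h in pairs:
        # independent 1-WL oracle: the catalog itself must be distinguishable
        assert (nx.weisfeiler_lehman_graph_hash(g)
                != nx.weisfeiler_lehman_graph_hash(h))
    return pairs


def gin_embedding(adj: np.ndarray, layers) -> np.ndarray:
    n = adj.shape[0]
    h = np.ones((n, 1))
    readouts = [readout_sum(h)]
    for lp in layers:
        h = gin_update(h if isinstance(h, np.ndarray) else h, adj, lp)
        readouts.append(readout_sum(h))
    return concat_layer_readouts(readouts)


def test_wl_expressiveness_smoke():
    """A random-init 2-layer GIN separates 1-WL-distinguishable pairs."""
    rng = np.random.default_rng(77)
    layers = [GinLayerParams.init(rng, 1, 8, 8, 1),
              GinLayerParams.init(rng, 8, 8, 8, 2)]
    distinct = 0
    for g, h in wl_catalog():
        n = max(g.number_of_nodes(), h.number_of_nodes())
        ag = np.zeros((n, n))
        ah = np.zeros((n, n))
        ag[:g.number_of_nodes(), :g.number_of_nodes()] = nx.to_numpy_array(g)
        ah[:h.number_of_nodes(), :h.number_of_nodes()] = nx.to_numpy_array(h)
        eg = gin_embedding(ag, layers)
        eh = gin_embedding(ah, layers)
        if np.max(np.abs(eg - eh)) > 1e-4:
            distinct += 1
    assert distinct >= 9
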