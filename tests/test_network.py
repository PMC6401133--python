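"""Architecture counts, prediction invariants, training behaviour,
ensembling, and the split protocol."""

import warnings

import numpy as np
import pytest

from contactnet.core import IGNORED
from contactnet.network import (ContactEnsemble, ContactNetwork,
                                NetworkConfig, SecondaryStructureNetwork,
                                TrainConfig, build_contact_network,
                                build_ss_network, ensemble_predict,
                                load_model, make_ensemble_splits,
                                predict_contact_map, save_model, train_model,
                                ss_network_input)
from contactnet.nnet import ResidualCNN


def _random_features(rng, L, C=51):
    return rng.random((L, L, C))


class TestArchitecture:
    def test_default_conv_layer_count_is_40(self):
        assert NetworkConfig().n_conv_layers == 40
        assert build_contact_network().n_conv_layers == 40

    def test_default_parameter_count_rounds_to_1_4_million(self):
        cfg = NetworkConfig()
        assert round(cfg.n_parameters / 1e6, 1) == 1.4

    def test_closed_form_matches_framework_count(self):
        """(3*3*51*64+64) + 19*2*(3*3*64*64+64) + (3*3*64*3+3) equals the
        parameter count of the instantiated network."""
        closed = (3 * 3 * 51 * 64 + 64) + 19 * 2 * (3 * 3 * 64 * 64 + 64) \
            + (3 * 3 * 64 * 3 + 3)
        cfg = NetworkConfig()
        assert cfg.n_parameters == closed
        model = build_contact_network(cfg)
        assert model.n_parameters == closed

    @pytest.mark.parametrize("n_filters,n_blocks", [(4, 1), (8, 2), (6, 5)])
    def test_counts_generalise(self, n_filters, n_blocks):
        cfg = NetworkConfig(n_filters=n_filters, n_blocks=n_blocks)
        model = build_contact_network(cfg)
        assert model.n_conv_layers == cfg.n_conv_layers == 2 * n_blocks + 2
        assert model.n_parameters == cfg.n_parameters

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_filters=0)
        with pytest.raises(ValueError):
            NetworkConfig(n_blocks=-1)


class TestPrediction:
    def test_zeroed_final_layer_gives_uniform_thirds(self):
        model = build_contact_network(NetworkConfig(n_filters=4, n_blocks=1))
        model.final.W[:] = 0.0
        model.final.b[:] = 0.0
        rng = np.random.default_rng(0)
        probs = predict_contact_map(model, _random_features(rng, 7), full=True)
        assert np.allclose(probs, 1.0 / 3.0)

    @pytest.mark.parametrize("seed", range(3))
    def test_exact_symmetry_and_softmax_normalisation(self, seed):
        rng = np.random.default_rng(seed)
        model = build_contact_network(NetworkConfig(n_filters=6, n_blocks=2),
                                      seed=seed)
        probs = predict_contact_map(model, _random_features(rng, 11),
                                    full=True)
        assert np.array_equal(probs, probs.transpose(1, 0, 2))  # bitwise
        assert np.allclose(probs.sum(axis=2), 1.0, atol=1e-6)
        assert probs.min() >= 0.0 and probs.max() <= 1.0

    def test_channel_mismatch_rejected(self):
        model = build_contact_network(NetworkConfig(n_filters=4, n_blocks=1))
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="51"):
            predict_contact_map(model, rng.random((6, 6, 50)))

    def test_gradients_match_finite_differences(self):
        """Analytic backprop through conv/residual/symmetrise/softmax agrees
        with central finite differences."""
        m = ResidualCNN(3, 4, 1, 3, seed=2, dtype=np.float64)
        rng = np.random.default_rng(0)
        x = rng.standard_normal((3, 5, 5))
        y = rng.integers(0, 3, (5, 5))
        w = np.array([1.0, 4.0, 0.0])
        probs = m.forward(x, train=True)
        _, dlogits = m.loss_and_grad(probs, y, w)
        m.zero_grad()
        m.backward(dlogits)
        for layer in m.conv_layers:
            for _ in range(3):
                i = int(rng.integers(layer.W.shape[0]))
                j = int(rng.integers(layer.W.shape[1]))
                eps, orig = 1e-6, layer.W[i, j]
                layer.W[i, j] = orig + eps
                lp, _ = m.loss_and_grad(m.forward(x, train=True), y, w)
                layer.W[i, j] = orig - eps
                lm, _ = m.loss_and_grad(m.forward(x, train=True), y, w)
                layer.W[i, j] = orig
                assert layer.dW[i, j] == pytest.approx((lp - lm) / (2 * eps),
                                                       rel=1e-4, abs=1e-8)


class TestTraining:
    def test_all_ignored_labels_zero_loss_and_gradient(self):
        model = build_contact_network(NetworkConfig(n_filters=4, n_blocks=1))
        rng = np.random.default_rng(0)
        x = rng.random((4, 4, 51)).transpose(2, 0, 1).astype(np.float32)
        labels = np.full((4, 4), IGNORED)
        probs = model.forward(x, train=True)
        loss, dlogits = model.loss_and_grad(probs, labels,
                                            np.array([1.0, 1.0, 0.0]))
        assert loss == 0.0
        assert np.array_equal(dlogits, np.zeros_like(dlogits))

    def test_all_ignored_target_skipped_with_warning(self):
        model = build_contact_network(NetworkConfig(n_filters=4, n_blocks=1))
        rng = np.random.default_rng(0)
        good = (rng.random((5, 5, 51)),
                np.zeros((5, 5), dtype=np.int8))
        bad = (rng.random((5, 5, 51)), np.full((5, 5), IGNORED, dtype=np.int8))
        with pytest.warns(UserWarning, match="ignored"):
            train_model(model, [good, bad], TrainConfig(seed=0, epochs=1))

    def test_training_is_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        data = [(rng.random((6, 6, 51)),
                 np.zeros((6, 6), dtype=np.int8)) for _ in range(2)]
        preds = []
        for _ in range(2):
            model = build_contact_network(
                NetworkConfig(n_filters=4, n_blocks=1), seed=9)
            train_model(model, data, TrainConfig(seed=9, epochs=2))
            preds.append(predict_contact_map(model, data[0][0]))
        assert np.array_equal(preds[0], preds[1])

    def test_empty_dataset_rejected(self):
        model = build_contact_network(NetworkConfig(n_filters=4, n_blocks=1))
        with pytest.raises(ValueError):
            train_model(model, [], TrainConfig(seed=0))


class TestEnsemble:
    def _members(self, n, seed0=0):
        return [build_contact_network(NetworkConfig(n_filters=4, n_blocks=1),
                                      seed=seed0 + k) for k in range(n)]

    def test_identical_members_mean_equals_member(self):
        rng = np.random.default_rng(0)
        f = _random_features(rng, 8)
        m = self._members(1)[0]
        single = predict_contact_map(m, f)
        assert np.allclose(ensemble_predict([m, m, m], f), single)

    def test_pairwise_mean(self):
        rng = np.random.default_rng(1)
        f = _random_features(rng, 6)
        a, b = self._members(2)
        pa, pb = predict_contact_map(a, f), predict_contact_map(b, f)
        assert np.allclose(ensemble_predict([a, b], f), (pa + pb) / 2)

    def test_ten_members_match_explicit_summation(self):
        rng = np.random.default_rng(2)
        f = _random_features(rng, 7)
        members = self._members(10)
        total = np.zeros((7, 7))
        for m in members:
            total += predict_contact_map(m, f)
        assert np.allclose(ensemble_predict(members, f), total / 10)

    def test_estimator_wrapper(self):
        rng = np.random.default_rng(3)
        f = _random_features(rng, 6)
        members = self._members(3)
        ens = ContactEnsemble(members=members).fit()
        assert np.allclose(ens.predict([f])[0], ensemble_predict(members, f))


class TestEnsembleSplits:
    def test_production_scale_five_disjoint_subsets(self):
        ids = [f"id{k}" for k in range(4000)]
        jobs = make_ensemble_splits(ids, n_splits=5, validation_size=800,
                                    seed=1)
        assert len(jobs) == 10
        vals = {j.split_index: set(j.validation_ids) for j in jobs}
        assert all(len(v) == 800 for v in vals.values())
        keys = sorted(vals)
        for a in keys:
            for b in keys:
                if a != b:
                    assert not (vals[a] & vals[b])

    def test_weights_are_one_and_four(self):
        jobs = make_ensemble_splits(list(range(20)), n_splits=2,
                                    validation_size=5, seed=0)
        assert sorted({j.contact_weight for j in jobs}) == [1.0, 4.0]
        for j in jobs:
            assert not (set(j.train_ids) & set(j.validation_ids))

    def test_insufficient_ids_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            make_ensemble_splits(list(range(10)), n_splits=5,
                                 validation_size=3)


class TestSecondaryStructureNetwork:
    def test_ten_conv_layers_by_default(self):
        model = build_ss_network()
        assert model.n_conv_layers == 10

    def test_output_shapes_and_normalisation(self):
        rng = np.random.default_rng(0)
        net = SecondaryStructureNetwork(n_filters=8, epochs=1)
        X = [rng.random((L, 40)) for L in (1, 9, 17)]
        y = [rng.integers(0, 3, L) for L in (1, 9, 17)]
        net.fit(X, y)
        for f, probs in zip(X, net.predict_proba(X)):
            assert probs.shape == (len(f), 3)
            assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_overfits_labelled_toy_set(self):
        """Helix/strand/coil labels derived from simple sequence motifs are
        recovered at >= 90% training accuracy."""
        rng = np.random.default_rng(1)
        X, y = [], []
        for _ in range(6):
            L = 30
            labels = np.repeat(rng.integers(0, 3, 5), 6)[:L]
            prof = np.zeros((L, 20))
            prof[np.arange(L), labels] = 1.0  # informative profile columns
            seq = "A" * L
            X.append(ss_network_input(prof, seq))
            y.append(labels)
        net = SecondaryStructureNetwork(n_filters=12, epochs=60,
                                        random_state=0).fit(X, y)
        pred = net.predict(X)
        acc = np.mean([np.mean(p == t) for p, t in zip(pred, y)])
        assert acc >= 0.9


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path):
        model = build_contact_network(NetworkConfig(n_filters=5, n_blocks=2),
                                      seed=4)
        path = tmp_path / "model.npz"
        save_model(path, model, config={"note": "test"})
        back = load_model(path)
        rng = np.random.default_rng(0)
        f = _random_features(rng, 6)
        assert np.array_equal(predict_contact_map(model, f),
                              predict_contact_map(back, f))


class TestSklearnInterface:
    def test_get_set_params_round_trip(self):
        est = ContactNetwork(n_filters=8, n_blocks=2, epochs=3)
        params = est.get_params()
        assert params["n_filters"] == 8
        clone = ContactNetwork(**params)
        assert clone.get_params() == params

    def test_fit_predict_small(self):
        rng = np.random.default_rng(0)
        X = [rng.random((6, 6, 51)) for _ in range(2)]
        y = [np.zeros((6, 6), dtype=np.int8) for _ in range(2)]
        est = ContactNetwork(n_filters=4, n_blocks=1, epochs=2,
                             random_state=0).fit(X, y)
        assert est.n_parameters_ == est.model_.n_parameters
        preds = est.predict(X)
        assert preds[0].shape == (6, 6)
        assert np.array_equal(preds[0], preds[0].T)
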