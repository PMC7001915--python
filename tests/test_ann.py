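import numpy as np
import pandas as pd
import pytest

from richworld import (
    AnnConfig,
    FeatureTable,
    InvalidInputError,
    RichnessFunction,
    RichnessTerm,
    SyntheticWorldConfig,
    TrainedRichnessModel,
    build_feature_table,
    cross_validate,
    evaluate,
    make_grid,
    predict,
    predict_surface,
    simulate_driver_fields,
    split_train_test,
    train_ann,
    true_richness_function,
)


def _table_from_arrays(X: np.ndarray, y: np.ndarray) -> FeatureTable:
    names = [f"x{i}" for i in range(X.shape[1])]
    data = pd.DataFrame(X, columns=names)
    data.insert(0, "lat", 0.0)
    data.insert(0, "lon", 0.0)
    data.insert(0, "cell_id", np.arange(len(data)))
    data["response"] = y
    prov = {"features": {}, "response": {"min": 0.0, "max": 1.0}}
    return FeatureTable(data, names, prov)


class TestSplit:
    def test_split_sizes(self):
        table = _table_from_arrays(np.random.default_rng(0).random((100, 2)), np.zeros(100))
        split = split_train_test(table, 0.8, seed=1)
        assert split.train_indices.size == 80
        assert split.test_indices.size == 20

    def test_split_deterministic_and_disjoint(self):
        table = _table_from_arrays(np.random.default_rng(0).random((50, 2)), np.zeros(50))
        a = split_train_test(table, 0.8, seed=2)
        b = split_train_test(table, 0.8, seed=2)
        assert np.array_equal(a.train_indices, b.train_indices)
        assert np.intersect1d(a.train_indices, a.test_indices).size == 0
        union = np.union1d(a.train_indices, a.test_indices)
        assert np.array_equal(union, np.arange(50))

    def test_bad_fraction_rejected(self):
        table = _table_from_arrays(np.zeros((20, 1)), np.zeros(20))
        with pytest.raises(InvalidInputError):
            split_train_test(table, 1.0)


class TestForwardPass:
    def test_manual_toy_network_oracle(self):
        # 2 inputs -> 1 ReLU unit -> linear output, computed by hand:
        # z1 = 0.5*0.4 - 0.25*0.8 + 0.1 = 0.1 -> relu 0.1 -> 2*0.1 - 0.3 = -0.1
        model = TrainedRichnessModel(
            weights=[np.array([[0.5], [-0.25]]), np.array([[2.0]])],
            biases=[np.array([0.1]), np.array([-0.3])],
            config=AnnConfig(hidden_layers=1, nodes_per_layer=1),
            feature_names=["a", "b"],
            provenance={},
        )
        out = predict(model, np.array([[0.4, 0.8]]))
        assert out[0] == pytest.approx(-0.1, abs=1e-10)
        # negative pre-activation is clipped by the rectifier
        out = predict(model, np.array([[0.0, 0.8]]))
        assert out[0] == pytest.approx(-0.3, abs=1e-10)

    def test_prediction_finite_on_unit_cube(self):
        rng = np.random.default_rng(1)
        table = _table_from_arrays(rng.random((300, 4)), rng.random(300))
        model = train_ann(table, AnnConfig(epochs=3, seed=0))
        assert np.all(np.isfinite(predict(model, rng.random((50, 4)))))

    def test_arity_mismatch_rejected(self):
        table = _table_from_arrays(np.random.default_rng(2).random((200, 3)), np.zeros(200))
        model = train_ann(table, AnnConfig(epochs=1, seed=0))
        with pytest.raises(InvalidInputError):
            predict(model, np.zeros((5, 2)))


class TestTraining:
    def test_constant_target_learned(self):
        rng = np.random.default_rng(3)
        table = _table_from_arrays(rng.random((2000, 3)), np.full(2000, 0.37))
        model = train_ann(table, AnnConfig(epochs=40, seed=1))
        pred = predict(model, table.X)
        assert np.all(np.abs(pred - 0.37) < 0.01)

    def test_seeded_training_bit_reproducible(self):
        rng = np.random.default_rng(4)
        table = _table_from_arrays(rng.random((500, 3)), rng.random(500))
        m1 = train_ann(table, AnnConfig(epochs=5, seed=7))
        m2 = train_ann(table, AnnConfig(epochs=5, seed=7))
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_test_rows_never_influence_training(self):
        rng = np.random.default_rng(5)
        X, y = rng.random((400, 3)), rng.random(400)
        split = split_train_test(_table_from_arrays(X, y), 0.8, seed=0)
        y_corrupted = y.copy()
        y_corrupted[split.test_indices] = rng.random(split.test_indices.size) * 100
        m1 = train_ann(_table_from_arrays(X, y), AnnConfig(epochs=5, seed=2), split=split)
        m2 = train_ann(
            _table_from_arrays(X, y_corrupted), AnnConfig(epochs=5, seed=2), split=split
        )
        for w1, w2 in zip(m1.weights, m2.weights):
            assert np.array_equal(w1, w2)

    def test_model_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(6)
        table = _table_from_arrays(rng.random((300, 2)), rng.random(300))
        model = train_ann(table, AnnConfig(epochs=2, seed=3))
        path = tmp_path / "model.json"
        model.to_json(path)
        loaded = TrainedRichnessModel.from_json(path)
        assert np.allclose(predict(loaded, table.X), predict(model, table.X))


class TestEvaluate:
    def _fitted(self):
        rng = np.random.default_rng(7)
        X = rng.random((600, 2))
        y = 0.3 * X[:, 0] + 0.2
        table = _table_from_arrays(X, y)
        split = split_train_test(table, 0.8, seed=1)
        return table, train_ann(table, AnnConfig(epochs=30, seed=1, dropout=0.0), split=split)

    def test_metrics_match_direct_recomputation(self):
        table, model = self._fitted()
        metrics = evaluate(model, table, "test")
        idx = model.split.test_indices
        y, y_hat = table.y[idx], predict(model, table.X[idx])
        assert metrics.r2 == pytest.approx(1 - np.sum((y - y_hat) ** 2) / np.sum((y - y.mean()) ** 2))
        assert metrics.rmse == pytest.approx(np.sqrt(np.mean((y - y_hat) ** 2)))

    def test_perfect_and_null_predictor_extremes(self):
        y = np.random.default_rng(8).random(100)
        sst = np.sum((y - y.mean()) ** 2)
        assert 1 - 0.0 / sst == 1.0  # perfect fit convention
        # null model: predicting the mean gives R^2 = 0 by definition
        sse_null = np.sum((y - y.mean()) ** 2)
        assert 1 - sse_null / sst == pytest.approx(0.0)

    def test_zero_variance_response_rejected(self):
        table = _table_from_arrays(np.random.default_rng(9).random((50, 2)), np.full(50, 0.5))
        model = train_ann(table, AnnConfig(epochs=1, seed=0))
        with pytest.raises(InvalidInputError):
            evaluate(model, table, "all")


class TestCrossValidate:
    def test_single_candidate_selected_and_folds_partition(self):
        rng = np.random.default_rng(10)
        table = _table_from_arrays(rng.random((300, 2)), rng.random(300))
        config = AnnConfig(epochs=2, seed=0)
        selected, folds = cross_validate(table, [config], k=5, seed=1)
        assert selected is config
        assert set(folds["fold"]) == set(range(5))

    def test_nonlinear_world_prefers_hidden_layers(self):
        # unimodal response: a linear (no-hidden-layer) model cannot fit it
        rng = np.random.default_rng(11)
        X = rng.random((1500, 2))
        y = np.exp(-(((X[:, 0] - 0.5) / 0.15) ** 2))
        table = _table_from_arrays(X, y)
        default = AnnConfig(epochs=60, dropout=0.0, learning_rate=0.02, seed=1)
        linear = AnnConfig(hidden_layers=0, epochs=60, dropout=0.0, learning_rate=0.02, seed=1)
        selected, _ = cross_validate(table, [linear, default], k=5, seed=2)
        assert selected is default

    def test_bad_k_rejected(self):
        table = _table_from_arrays(np.zeros((40, 1)), np.zeros(40))
        with pytest.raises(InvalidInputError):
            cross_validate(table, [AnnConfig()], k=1)


class TestRecovery:
    def test_noiseless_additive_world_high_r2(self):
        cfg = SyntheticWorldConfig(
            seed=12,
            n_true_drivers=3,
            n_distractor_drivers=0,
            noise_sd=0.0,
            richness_link="expm1",
        )
        grid = make_grid((-60, 60, -180, 180), cell_km=250.0)
        drivers = simulate_driver_fields(grid, cfg)
        richness = true_richness_function(drivers, cfg)
        layers = {n: l for n, l in drivers.static_layers.items() if n != "elevation"}
        table = build_feature_table(layers, richness, mask=grid.domain_mask(None))
        split = split_train_test(table, 0.8, seed=0)
        model = train_ann(
            table,
            AnnConfig(epochs=150, dropout=0.0, learning_rate=0.02, seed=1),
            split=split,
        )
        assert evaluate(model, table, "test").r2 > 0.95


class TestPredictSurface:
    def test_surface_consistent_with_rowwise_predictions(self, small_world, driver_table):
        _, grid, _ = small_world
        model = train_ann(driver_table, AnnConfig(epochs=3, seed=0))
        surface = predict_surface(model, driver_table, grid)
        flat = surface.values.ravel()
        cell_ids = driver_table.data["cell_id"].to_numpy(int)
        assert np.allclose(flat[cell_ids], predict(model, driver_table.X))
        missing = np.setdiff1d(np.arange(grid.n_cells), cell_ids)
        assert np.all(np.isnan(flat[missing]))

    def test_backtransformed_surface_is_valid_richness(self, small_world, driver_table):
        _, grid, _ = small_world
        model = train_ann(driver_table, AnnConfig(epochs=10, seed=0))
        surface = predict_surface(model, driver_table, grid)
        ok = np.isfinite(surface.values)
        richness = driver_table.inverse_response(surface.values[ok])
        assert np.all(richness > -1.0)  # expm1 lower bound; finite everywhere
        assert np.all(np.isfinite(richness))
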