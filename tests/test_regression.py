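import numpy as np
import pandas as pd
import pytest

from powerfate import (
    FateModel,
    ObservationTable,
    fit_fate_model,
    fit_pls,
    generate_powerlaw_dataset,
    predict_fate,
)


class TestFitPLS:
    def test_full_components_match_least_squares_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        Y = rng.normal(size=(20, 2))
        model = fit_pls(X, Y, n_components=5)
        Xa = np.hstack([X, np.ones((20, 1))])
        coef, *_ = np.linalg.lstsq(Xa, Y, rcond=None)
        np.testing.assert_allclose(model.predict(X), Xa @ coef, atol=1e-8)

    def test_exact_linear_relation_reproduced(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 4))
        Y = X @ np.array([1.0, -2.0, 0.5, 3.0]) + 4.0
        model = fit_pls(X, Y, n_components=4)
        np.testing.assert_allclose(model.predict(X)[:, 0], Y, atol=1e-8)

    def test_single_component_fits_rank_one_response(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(25, 3))
        Y = 2.0 * X[:, [0]]
        model = fit_pls(X[:, [0]], Y, n_components=1)
        np.testing.assert_allclose(model.predict(X[:, [0]]), Y, atol=1e-8)

    def test_score_vectors_orthogonal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(40, 6))
        Y = rng.normal(size=(40, 1))
        model = fit_pls(X, Y, n_components=4)
        Xc = (X - model.x_mean) / model.x_std
        scores = Xc @ model.x_rotations
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_rank_bound_enforced(self):
        X = np.random.default_rng(0).normal(size=(6, 10))
        Y = np.arange(6.0)
        with pytest.raises(ValueError, match="n_components"):
            fit_pls(X, Y, n_components=6)

    def test_zero_variance_column_rejected(self):
        X = np.ones((10, 2))
        X[:, 1] = np.arange(10.0)
        with pytest.raises(ValueError, match="zero-variance"):
            fit_pls(X, np.arange(10.0), n_components=1)


class TestFitFateModel:
    def test_noise_free_parameter_recovery(self, clean_powerlaw):
        table, truth = clean_powerlaw
        model = fit_fate_model(table, "death", "powerlaw",
                               epsilon=truth.epsilon, n_components=4)
        np.testing.assert_allclose(model.beta, truth.beta, atol=1e-6)
        assert model.beta0 == pytest.approx(truth.beta0, abs=1e-6)

    def test_recovery_error_shrinks_with_noise_and_sample_size(self):
        beta = np.array([0.5, -0.3, 0.2, 0.1])
        errs = {}
        for sd in (0.0, 0.05):
            for n in (50, 500):
                table, truth = generate_powerlaw_dataset(
                    n, 4, beta=beta, beta0=-1.0, epsilon=1e-3,
                    noise_sd=sd, seed=5)
                m = fit_fate_model(table, "death", "powerlaw",
                                   epsilon=1e-3, n_components=4)
                errs[(sd, n)] = np.abs(m.beta - beta).max()
        assert errs[(0.0, 50)] < 1e-6 and errs[(0.0, 500)] < 1e-6
        assert errs[(0.05, 500)] < errs[(0.05, 50)]
        assert errs[(0.05, 500)] < 0.02

    def test_constant_fate_gives_intercept_only_model(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0],
                           "b": [2.0, 1.0, 2.5, 0.5],
                           "death": [0.4] * 4})
        t = ObservationTable(df, ("a", "b"), ("death",))
        m = fit_fate_model(t, "death", "powerlaw", epsilon=0.1, n_components=2)
        np.testing.assert_allclose(m.beta, 0.0)
        assert m.beta0 == pytest.approx(np.log(0.4 - 0.1))

    def test_linear_kind_exact_proportionality(self):
        df = pd.DataFrame({"x1": [1.0, 2.0, 3.0, 4.0]})
        df["death"] = 2.0 * df["x1"]
        t = ObservationTable(df, ("x1",), ("death",))
        m = fit_fate_model(t, "death", "linear", n_components=1)
        assert m.beta[0] == pytest.approx(2.0, abs=1e-8)
        assert m.beta0 == pytest.approx(0.0, abs=1e-8)

    def test_epsilon_must_be_below_min_fate(self, clean_powerlaw):
        table, _ = clean_powerlaw
        with pytest.raises(ValueError, match="epsilon"):
            fit_fate_model(table, "death", "powerlaw", epsilon=10.0)

    def test_powerlaw_equals_linear_fit_on_log_table(self, noisy_powerlaw):
        table, truth = noisy_powerlaw
        eps = truth.epsilon
        m_pl = fit_fate_model(table, "death", "powerlaw", epsilon=eps,
                              n_components=3)
        logged = table.data.copy()
        for p in table.signal_names:
            logged[p] = np.log(logged[p])
        logged["death"] = np.log(logged["death"] - eps)
        # log-fate values are negative, so fit the transformed response as
        # a linear model with epsilon irrelevant
        t_log = ObservationTable(logged, table.signal_names, ("death",))
        m_lin = fit_fate_model(t_log, "death", "linear", n_components=3)
        np.testing.assert_allclose(m_pl.beta, m_lin.beta, atol=1e-10)
        assert m_pl.beta0 == pytest.approx(m_lin.beta0, abs=1e-10)


class TestPredictFate:
    def test_zero_exponents_give_constant(self):
        m = FateModel("powerlaw", 0.0, np.zeros(2), 0.01, ("a", "b"))
        out = predict_fate(m, {"a": 5.0, "b": 0.1})
        assert out[0] == pytest.approx(1.01)

    def test_unit_exponents_give_product(self):
        m = FateModel("powerlaw", 0.0, np.ones(2), 0.0, ("a", "b"))
        assert predict_fate(m, {"a": 2.0, "b": 3.0})[0] == pytest.approx(6.0)

    def test_round_trip_on_training_data(self, clean_powerlaw):
        table, truth = clean_powerlaw
        m = fit_fate_model(table, "death", "powerlaw", epsilon=truth.epsilon,
                           n_components=4)
        pred = predict_fate(m, table)
        np.testing.assert_allclose(pred, table.data["death"], atol=1e-6)

    def test_prediction_invariant_to_column_order(self, clean_powerlaw):
        table, truth = clean_powerlaw
        m = fit_fate_model(table, "death", "powerlaw", epsilon=truth.epsilon,
                           n_components=4)
        cols = list(table.signal_names)
        shuffled = table.signals()[cols[::-1]]
        np.testing.assert_allclose(predict_fate(m, shuffled),
                                   predict_fate(m, table))

    def test_nonpositive_signal_rejected(self):
        m = FateModel("powerlaw", 0.0, np.ones(1), 0.0, ("a",))
        with pytest.raises(ValueError):
            predict_fate(m, {"a": -1.0})

    def test_unknown_protein_rejected(self):
        m = FateModel("powerlaw", 0.0, np.ones(1), 0.0, ("a",))
        with pytest.raises(ValueError, match="missing"):
            predict_fate(m, pd.DataFrame({"b": [1.0]}))


def test_serialization_round_trip(clean_powerlaw):
    table, truth = clean_powerlaw
    m = fit_fate_model(table, "death", "powerlaw", epsilon=truth.epsilon,
                       n_components=4)
    m2 = FateModel.from_json(m.to_json())
    assert m2.kind == m.kind and m2.protein_names == m.protein_names
    np.testing.assert_allclose(m2.beta, m.beta)
    np.testing.assert_allclose(predict_fate(m2, table), predict_fate(m, table))
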