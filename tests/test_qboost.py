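"""Tests of the pinball-loss gradient boosting estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.ensemble import GradientBoostingRegressor

from conformalbp import qboost
from conformalbp.schema import FEATURES


def _frame(X, y):
    df = pd.DataFrame(X, columns=list(FEATURES))
    df["sbp_ref"] = y
    df["dbp_ref"] = y - 45.0
    return df


def _linear_data(n=600, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(FEATURES)))
    y = 120.0 + 2.0 * X[:, 0] - 3.0 * X[:, 1] + noise * rng.normal(size=n)
    return _frame(X, y)


class TestPinballLoss:
    @pytest.mark.parametrize("y, f, gamma, expected", [
        ([10.0], [12.0], 0.05, 1.90),   # overestimation branch
        ([10.0], [8.0], 0.05, 0.10),    # underestimation branch
        ([10.0], [12.0], 0.50, 1.00),   # symmetric case: half the MAE
    ])
    def test_single_sample_branches(self, y, f, gamma, expected):
        assert qboost.pinball_loss(y, f, gamma) == pytest.approx(expected)

    @given(st.lists(st.tuples(
        st.floats(-200, 200, allow_nan=False),
        st.floats(-200, 200, allow_nan=False)), min_size=1, max_size=50))
    @settings(deadline=None, derandomize=True)
    def test_gamma_half_is_half_the_mae(self, pairs):
        y, f = map(np.asarray, zip(*pairs))
        mae = np.mean(np.abs(y - f))
        assert qboost.pinball_loss(y, f, 0.5) == pytest.approx(0.5 * mae)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            qboost.pinball_loss([], [], 0.5)


class TestNegativeGradient:
    @pytest.mark.parametrize("y, f, gamma, expected", [
        (10.0, 8.0, 0.05, 0.05),     # under the target: +gamma
        (10.0, 12.0, 0.05, -0.95),   # over the target: -(1-gamma)
        (10.0, 10.0, 0.30, 0.0),     # tie: subgradient 0
    ])
    def test_branches(self, y, f, gamma, expected):
        assert qboost.negative_gradient([y], [f], gamma)[0] == pytest.approx(expected)


class TestFit:
    def test_constant_target_predicts_constant_for_every_gamma(self):
        df = _linear_data(n=80)
        df["sbp_ref"] = 117.0
        for gamma in (0.05, 0.5, 0.95):
            model = qboost.fit(df, "sbp", qboost.QuantileBoostConfig(
                gamma=gamma, n_estimators=20, max_depth=3))
            assert model.predict(df) == pytest.approx(np.full(len(df), 117.0))

    def test_noiseless_linear_signal_is_interpolated(self):
        """Deep trees drive the training pinball loss far below the target SD."""
        df = _linear_data(n=600, noise=0.0)
        model = qboost.fit(df, "sbp", qboost.QuantileBoostConfig())
        loss = qboost.pinball_loss(df["sbp_ref"], model.predict(df), 0.5)
        assert loss < 0.01 * df["sbp_ref"].std()

    def test_training_loss_is_monotone_non_increasing(self):
        df = _linear_data(n=300, noise=1.0)
        model = qboost.fit(df, "sbp", qboost.QuantileBoostConfig(
            gamma=0.9, learning_rate=0.05, n_estimators=100, max_depth=3))
        assert np.all(np.diff(model.train_loss_path) <= 1e-10)

    def test_prediction_invariant_to_training_row_order(self):
        df = _linear_data(n=200, noise=2.0)
        shuffled = df.sample(frac=1.0, random_state=1)
        cfg = qboost.QuantileBoostConfig(n_estimators=60, max_depth=4, seed=7)
        a = qboost.fit(df, "sbp", cfg).predict(df)
        b = qboost.fit(shuffled, "sbp", cfg).predict(df)
        assert a == pytest.approx(b, abs=1e-8)

    def test_agrees_with_independent_boosting_implementation(self):
        """Same recursion as sklearn's quantile GBR (up to split criterion)."""
        df = _linear_data(n=400, noise=1.0)
        cfg = qboost.QuantileBoostConfig(
            gamma=0.9, learning_rate=0.05, n_estimators=150,
            max_depth=3, min_samples_leaf=5)
        ours = qboost.fit(df, "sbp", cfg).predict(df)
        sk = GradientBoostingRegressor(
            loss="quantile", alpha=0.9, learning_rate=0.05, n_estimators=150,
            max_depth=3, min_samples_leaf=5, random_state=0)
        sk.fit(df[list(FEATURES)], df["sbp_ref"])
        theirs = sk.predict(df[list(FEATURES)])
        assert np.corrcoef(ours, theirs)[0, 1] > 0.99
        assert np.mean(np.abs(ours - theirs)) < 0.2 * df["sbp_ref"].std()

    def test_non_finite_features_raise(self):
        df = _linear_data(n=50)
        df.loc[3, "rpat"] = np.nan
        with pytest.raises(ValueError):
            qboost.fit(df, "sbp", qboost.QuantileBoostConfig(n_estimators=5))


class TestPredictTriple:
    def _ensembles(self, df):
        return qboost.fit_triple(df, "sbp", qboost.QuantileBoostConfig(
            n_estimators=40, max_depth=3, learning_rate=0.1))

    def test_triple_is_sorted_and_counts_repairs(self):
        df = _linear_data(n=200, noise=5.0, seed=3)
        triples = qboost.predict_triple(self._ensembles(df), df)
        assert (triples["lower"] <= triples["point"]).all()
        assert (triples["point"] <= triples["upper"]).all()
        assert triples.attrs["n_crossing_repaired"] >= 0

    def test_crossed_raw_values_are_sorted(self):
        # Degenerate single-leaf ensembles with hand-set offsets cross on purpose.
        df = _linear_data(n=50)
        ens = self._ensembles(df)
        fake = {g: qboost.BoostedEnsemble(f0=v, trees=[], gamma=g, learning_rate=0.1,
                                          feature_names=FEATURES)
                for g, v in zip((0.05, 0.5, 0.95), (105.0, 100.0, 120.0))}
        out = qboost.predict_triple(fake, df)
        assert out.iloc[0].tolist() == [100.0, 105.0, 120.0]
        assert out.attrs["n_crossing_repaired"] == len(df)

    def test_schema_mismatch_raises(self):
        df = _linear_data(n=50)
        ens = self._ensembles(df)
        with pytest.raises(ValueError, match="schema"):
            ens[0.5].predict(df[list(FEATURES)[:-1]])


class TestGridSearch:
    def test_singleton_grid_returns_defaults(self):
        df = _linear_data(n=120, noise=1.0)
        cfg = qboost.grid_search(df, df, "sbp",
                                 {"n_estimators": [30], "max_depth": [3]},
                                 base=qboost.QuantileBoostConfig())
        assert (cfg.n_estimators, cfg.max_depth) == (30, 3)

    def test_depth_grid_prefers_deep_trees_on_interaction_signal(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(800, len(FEATURES)))
        y = 120.0 + 8.0 * X[:, 0] * X[:, 1] * X[:, 2] + 0.5 * rng.normal(size=800)
        df = _frame(X, y)
        train, valid = df.iloc[:500], df.iloc[500:]
        cfg = qboost.grid_search(
            train, valid, "sbp", {"max_depth": [2, 8]},
            base=qboost.QuantileBoostConfig(n_estimators=80, learning_rate=0.1))
        assert cfg.max_depth == 8

    def test_empty_validation_raises(self):
        df = _linear_data(n=30)
        with pytest.raises(ValueError):
            qboost.grid_search(df, df.iloc[:0], "sbp", {"max_depth": [2]})
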