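"""Model builders: published equation, MLR inference, SVR, LM-trained ANN."""

import numpy as np
import pandas as pd
import pytest

from qsbr import models, synthetic, validation
from qsbr.models import (
    AnnConfig,
    PUBLISHED_COEFFS,
    RankDeficiencyError,
    SvrConfig,
    fit_ann,
    fit_mlr,
    fit_svr,
    predict_published,
    tune_svr,
)

SIX = models.DESCRIPTOR_ORDER


class TestPublishedEquation:
    def test_zero_vector_gives_intercept(self):
        assert predict_published({k: 0.0 for k in SIX}) == pytest.approx(5.45)

    def test_ones_vector_hand_sum(self):
        assert predict_published({k: 1.0 for k in SIX}) == pytest.approx(-8.03)

    def test_single_term(self):
        v = {k: 0.0 for k in SIX}
        v["SPAN"] = 10.0
        assert predict_published(v) == pytest.approx(6.45)

    def test_missing_descriptor_named(self):
        v = {k: 0.0 for k in SIX if k != "G3p"}
        with pytest.raises(KeyError, match="G3p"):
            predict_published(v)

    def test_affine_in_inputs(self, rng):
        a = {k: float(x) for k, x in zip(SIX, rng.normal(size=6))}
        b = {k: float(x) for k, x in zip(SIX, rng.normal(size=6))}
        ab = {k: a[k] + b[k] for k in SIX}
        zero = {k: 0.0 for k in SIX}
        lhs = predict_published(ab) - predict_published(a) - predict_published(b)
        assert lhs + predict_published(zero) == pytest.approx(0.0, abs=1e-12)

    def test_dataframe_input(self):
        df = pd.DataFrame([{k: 0.0 for k in SIX}, {k: 1.0 for k in SIX}])
        out = predict_published(df)
        assert np.allclose(out, [5.45, -8.03])


class TestMlr:
    def test_noise_free_exact_recovery(self, rng):
        X = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        y = 1.5 + X @ [2.0, -1.0, 0.5]
        model = fit_mlr(X, y)
        coef = model.parameters["coefficients"]
        assert coef["intercept"] == pytest.approx(1.5, abs=1e-10)
        assert coef["a"] == pytest.approx(2.0, abs=1e-10)

    def test_three_point_hand_example(self):
        X = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        model = fit_mlr(X, [1.0, 2.0, 3.0])
        assert model.parameters["coefficients"]["x"] == pytest.approx(1.0)
        assert model.parameters["coefficients"]["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert model.parameters["r2"] == pytest.approx(1.0)

    def test_slope_recovery_within_2se(self):
        """Refits on noisy equation data recover the planted coefficients
        with roughly nominal per-coefficient 2-SE coverage."""
        hits = dict.fromkeys(SIX, 0)
        reps = 40
        for rep in range(reps):
            X, _ = synthetic.gen_joint(synthetic.SyntheticConfig(n=181, seed=500 + rep))
            y = synthetic.gen_equation_response(X, noise_sd=0.43, seed=900 + rep)
            model = fit_mlr(X, y)
            coef = model.parameters["coefficients"]
            se = model.parameters["standard_errors"]
            for k in SIX:
                hits[k] += abs(coef[k] - synthetic.EQUATION_COEFFS[k]) <= 2 * se[k]
        assert all(h >= 0.85 * reps for h in hits.values()), hits

    def test_rank_deficiency_names_columns(self, rng):
        x = rng.normal(size=40)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=40)})
        with pytest.raises(RankDeficiencyError, match="a.*b"):
            fit_mlr(X, rng.normal(size=40))

    def test_column_permutation_invariant_predictions(self, six_descriptor_data):
        X, y = six_descriptor_data
        m1 = fit_mlr(X, y)
        m2 = fit_mlr(X[list(reversed(X.columns))], y)
        assert np.allclose(m1.predict(X), m2.predict(X), atol=1e-10)


class TestSvr:
    def test_epsilon_tube_on_non_support_points(self, six_descriptor_data):
        X, y = six_descriptor_data
        model = fit_svr(X, y)
        resid = np.abs(model.predict(X) - np.asarray(y))
        n_sv = model.parameters["n_support"]
        # points strictly inside the tube are exactly the non-support vectors
        assert (resid <= 0.07 + 1e-6).sum() >= len(y) - n_sv

    def test_duplicated_training_rows_with_halved_c_leave_predictions(
        self, six_descriptor_data
    ):
        # duplicating every row doubles the data term of the SVR objective,
        # so halving C restores the identical optimization problem
        X, y = six_descriptor_data
        X2 = pd.concat([X, X], ignore_index=True)
        y2 = pd.concat([pd.Series(y), pd.Series(y)], ignore_index=True)
        m1 = fit_svr(X, y)
        m2 = fit_svr(X2, y2, SvrConfig(C=91.0 / 2))
        assert np.allclose(m1.predict(X), m2.predict(X), atol=2e-3)

    def test_tuned_svr_matches_mlr_on_equation_data(self, six_descriptor_data):
        # CV-tuned SVR (the study tuned C, epsilon, gamma the same way)
        # stays within 2 MPD points of OLS on held-out in-domain activities
        X, y = six_descriptor_data
        Xt, _ = synthetic.gen_joint(synthetic.SyntheticConfig(n=100, seed=77))
        yt = synthetic.gen_equation_response(Xt, noise_sd=0.43, seed=78)
        cfg = tune_svr(
            X, y, {"C": [1.0, 10.0, 91.0], "gamma": [0.01, 0.06, 0.2]}, folds=5
        )
        mask = (yt >= 1.0) & (yt <= 5.7)  # the observed bitterness range
        svr_mpd = validation.mpd(yt[mask], fit_svr(X, y, cfg).predict(Xt)[mask]).mpd
        mlr_mpd = validation.mpd(yt[mask], fit_mlr(X, y).predict(Xt)[mask]).mpd
        assert svr_mpd <= mlr_mpd + 2.0

    def test_column_permutation_invariant(self, six_descriptor_data):
        X, y = six_descriptor_data
        m1 = fit_svr(X, y)
        m2 = fit_svr(X[list(reversed(X.columns))], y)
        assert np.allclose(m1.predict(X), m2.predict(X), atol=1e-8)


class TestTuneSvr:
    def test_single_cell_grid_returned(self, six_descriptor_data):
        X, y = six_descriptor_data
        cfg = tune_svr(X, y, {"C": [5.0], "epsilon": [0.1], "gamma": [0.2]}, folds=3)
        assert (cfg.C, cfg.epsilon, cfg.gamma) == (5.0, 0.1, 0.2)

    def test_deterministic_given_seed(self, six_descriptor_data):
        X, y = six_descriptor_data
        grid = {"C": [1.0, 10.0], "gamma": [0.05, 0.2]}
        a = tune_svr(X, y, grid, folds=5, seed=3)
        b = tune_svr(X, y, grid, folds=5, seed=3)
        assert a == b

    def test_prefers_generating_hyperparameters_at_large_n(self, rng):
        # RBF-ish smooth target: a wildly wrong gamma should lose
        X = pd.DataFrame(rng.normal(size=(300, 2)), columns=["a", "b"])
        y = np.sin(X["a"]) + 0.3 * X["b"] + rng.normal(scale=0.05, size=300)
        cfg = tune_svr(X, y, {"C": [10.0], "gamma": [0.3, 200.0]}, folds=5)
        assert cfg.gamma == 0.3


class TestAnn:
    def test_linear_target_matches_ols(self, six_descriptor_data):
        X, y = six_descriptor_data
        with pytest.warns(UserWarning):
            ann = fit_ann(X, y, AnnConfig(seed=1))
        ann_rmse = validation.fit_quality(y, ann.predict(X), 6)["rmse"]
        ols_rmse = validation.fit_quality(y, fit_mlr(X, y).predict(X), 6)["rmse"]
        assert ann_rmse <= ols_rmse + 0.01 + 0.05  # small slack for early stopping

    def test_fits_nonlinearity_mlr_cannot(self, rng):
        n = 400
        X = pd.DataFrame(rng.uniform(-1, 1, size=(n, 2)), columns=["a", "b"])
        y = np.sign(X["a"]) * np.sign(X["b"]) + rng.normal(scale=0.05, size=n)
        ann = fit_ann(X, y, AnnConfig(hidden_units=4, seed=2))
        ann_r2 = validation.fit_quality(y, ann.predict(X), 2)["r2"]
        mlr_r2 = validation.fit_quality(y, fit_mlr(X, y).predict(X), 2)["r2"]
        assert ann_r2 - mlr_r2 > 0.3

    def test_deterministic_given_seed(self, six_descriptor_data):
        X, y = six_descriptor_data
        with pytest.warns(UserWarning):
            a = fit_ann(X, y, AnnConfig(seed=5))
        with pytest.warns(UserWarning):
            b = fit_ann(X, y, AnnConfig(seed=5))
        assert np.array_equal(a.parameters["weights"], b.parameters["weights"])

    def test_serialization_includes_flat_weights(self, tmp_path, six_descriptor_data):
        X, y = six_descriptor_data
        with pytest.warns(UserWarning):
            ann = fit_ann(X, y, AnnConfig(seed=0))
        path = tmp_path / "ann.json"
        ann.to_json(path)
        import json

        payload = json.loads(path.read_text())
        assert payload["family"] == "ann"
        n_params = 3 * 6 + 2 * 3 + 1
        assert len(payload["parameters"]["weights"]) == n_params
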