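import numpy as np
import pytest
from scipy.special import logsumexp

from nichetrunc import maxent as mx

VARS = ["MTCQ", "PANN"]


@pytest.fixture(scope="module")
def fitted(small_dataset):
    """A model fitted on the current records of the reduced scenario."""
    stack, _, occ = small_dataset
    bg, _ = mx.sample_background(stack, VARS, seed=0)
    feats = mx.build_features(bg, VARS, n_hinge_knots=8, n_threshold_knots=5)
    pres = occ.covariates(VARS, period="current")
    model = mx.fit_maxent(pres, bg, feats)
    return stack, bg, feats, pres, model


class TestFeatures:
    def _bg(self):
        rng = np.random.default_rng(20)
        return {"A": rng.uniform(2.0, 10.0, 200), "B": rng.normal(0, 1, 200)}

    def test_linear_normalisation_endpoints(self):
        bg = self._bg()
        feats = mx.build_features(bg, ["A"], classes=["linear"])
        lo, hi = bg["A"].min(), bg["A"].max()
        vals = feats.evaluate({"A": np.array([lo, hi])})
        assert vals[0, 0] == 0.0 and vals[1, 0] == 1.0

    def test_threshold_step(self):
        bg = self._bg()
        feats = mx.build_features(bg, ["A"], classes=["threshold"], n_threshold_knots=3)
        k = feats.features[0].knot
        vals = feats.evaluate({"A": np.array([k, k + 1e-9])})
        assert vals[0, 0] == 0.0 and vals[1, 0] == 1.0

    def test_hinge_matches_formula_oracle(self):
        bg = self._bg()
        feats = mx.build_features(bg, ["A"], classes=["hinge"], n_hinge_knots=6)
        rng = np.random.default_rng(21)
        x = rng.uniform(bg["A"].min(), bg["A"].max(), 50)
        design = feats.evaluate({"A": x})
        lo, hi = feats.bounds["A"]
        for j, f in enumerate(feats.features):
            if f.kind == "hinge":
                expected = np.clip((x - f.knot) / (hi - f.knot), 0, 1)
            else:
                expected = np.clip((f.knot - x) / (f.knot - lo), 0, 1)
            assert np.allclose(design[:, j], expected)

    def test_all_features_within_unit_interval_on_background(self):
        bg = self._bg()
        feats = mx.build_features(bg, ["A", "B"], n_hinge_knots=6)
        design = feats.evaluate(bg)
        assert design.min() >= 0.0 and design.max() <= 1.0

    def test_zero_range_variable_drops_nonlinear(self):
        bg = {"A": np.full(50, 3.0), "B": np.linspace(0, 1, 50)}
        with pytest.warns(UserWarning, match="zero background range"):
            feats = mx.build_features(bg, ["A", "B"], n_hinge_knots=4)
        kinds_a = {f.kind for f in feats.features if "A" in f.involved}
        assert kinds_a == {"linear"}


class TestFit:
    def test_constant_features_give_uniform_model(self):
        bg = {"A": np.full(20, 1.0)}
        with pytest.warns(UserWarning):
            feats = mx.build_features(bg, ["A"])
        model = mx.fit_maxent({"A": np.full(5, 1.0)}, bg, feats)
        assert np.allclose(model.lambdas, 0.0)
        assert model.training_gain == pytest.approx(0.0, abs=1e-9)
        raw = mx.predict_values(model, bg, output="raw")
        assert np.allclose(raw, 1.0 / 20)

    def test_full_shrinkage_limit(self, fitted):
        _, bg, feats, pres, _ = fitted
        model = mx.fit_maxent(pres, bg, feats, reg_multiplier=1e5)
        assert np.allclose(model.lambdas, 0.0)

    def test_single_binary_feature_matches_grid_search_oracle(self):
        # 4 background cells, one binary feature, 2 presences on feature=1
        bg = {"B": np.array([1.0, 1.0, 0.0, 0.0])}
        pres = {"B": np.array([1.0, 1.0])}
        feats = mx.build_features(bg, ["B"], classes=["linear"])
        beta = 0.1
        model = mx.fit_maxent(pres, bg, feats, betas=beta, tol=1e-9)

        lams = np.arange(0.0, 10.0, 1e-4)
        objs = [-l + logsumexp([l, l, 0.0, 0.0]) + beta * l for l in lams]
        oracle = lams[int(np.argmin(objs))]
        assert model.lambdas[0] == pytest.approx(oracle, abs=2e-3)

    def test_objective_convexity_via_restarts(self, fitted):
        _, bg, feats, pres, base = fitted
        rng = np.random.default_rng(22)
        gains = [base.training_gain]
        for _ in range(4):
            init = rng.normal(0, 0.5, len(feats))
            gains.append(mx.fit_maxent(pres, bg, feats, init=init).training_gain)
        assert max(gains) - min(gains) < 1e-4

    def test_too_few_presences(self, fitted):
        _, bg, feats, _, _ = fitted
        with pytest.raises(ValueError, match="presence"):
            mx.fit_maxent({v: np.array([1.0]) for v in VARS}, bg, feats)


class TestPredict:
    def test_raw_sums_to_one_over_background(self, fitted):
        _, bg, _, _, model = fitted
        raw = mx.predict_values(model, bg, output="raw")
        assert raw.sum() == pytest.approx(1.0)

    def test_entropy_bounded_by_log_background(self, fitted):
        _, _, _, _, model = fitted
        assert model.entropy <= np.log(model.n_background) + 1e-9

    def test_logistic_transform_definition(self, fitted):
        _, bg, _, _, model = fitted
        raw = mx.predict_values(model, bg, output="raw")
        logi = mx.predict_values(model, bg, output="logistic")
        eh = np.exp(model.entropy) * raw
        assert np.allclose(logi, eh / (1 + eh))
        # a hypothetical cell with raw = e^-H maps to 0.5 by construction
        r0 = np.exp(-model.entropy)
        assert np.exp(model.entropy) * r0 / (1 + np.exp(model.entropy) * r0) == (
            pytest.approx(0.5)
        )
        assert ((logi > 0) & (logi < 1)).all()

    def test_logistic_monotone_in_raw(self, fitted):
        _, bg, _, _, model = fitted
        raw = mx.predict_values(model, bg, output="raw")
        logi = mx.predict_values(model, bg, output="logistic")
        order = np.argsort(raw)
        assert (np.diff(logi[order]) >= 0).all()

    def test_predict_map_masks_missing(self, fitted):
        stack, _, _, _, model = fitted
        layer = mx.predict(model, stack)
        assert layer.shape == stack.geometry.shape
        assert np.nanmin(layer) >= 0 and np.nanmax(layer) <= 1

    def test_missing_variable_raises(self, fitted, tiny_stack):
        _, _, _, _, model = fitted
        with pytest.raises(ValueError, match="missing"):
            mx.predict(model, tiny_stack)

    def test_serialization_roundtrip(self, fitted, tmp_path):
        _, bg, _, _, model = fitted
        model.to_text(tmp_path / "m.txt")
        back = mx.MaxentModel.from_text(tmp_path / "m.txt")
        assert np.allclose(
            mx.predict_values(back, bg), mx.predict_values(model, bg)
        )
        assert back.training_gain == pytest.approx(model.training_gain)


class TestResponseCurves:
    def test_single_positive_linear_weight_is_increasing(self):
        rng = np.random.default_rng(23)
        bg = {"A": rng.uniform(0, 1, 300)}
        feats = mx.build_features(bg, ["A"], classes=["linear"])
        pres = {"A": bg["A"][bg["A"] > 0.6][:50]}
        model = mx.fit_maxent(pres, bg, feats)
        assert model.lambdas[0] > 0
        _, curve = mx.response_curve(model, "A", grid_points=30)
        assert (np.diff(curve) > 0).all()

    def test_zero_weights_give_flat_curve(self, fitted):
        _, bg, feats, pres, _ = fitted
        model = mx.fit_maxent(pres, bg, feats, reg_multiplier=1e5)
        _, curve = mx.response_curve(model, "MTCQ", grid_points=10)
        assert np.allclose(curve, curve[0])

    def test_sweep_endpoints_equal_direct_predictions(self, fitted):
        _, _, _, _, model = fitted
        sweep, curve = mx.response_curve(model, "MTCQ", grid_points=7)
        for idx in (0, -1):
            data = {
                v: np.array([model.presence_means[v]]) for v in model.variables
            }
            data["MTCQ"] = np.array([sweep[idx]])
            assert curve[idx] == pytest.approx(
                mx.predict_values(model, data)[0]
            )

    def test_unknown_variable_raises(self, fitted):
        _, _, _, _, model = fitted
        with pytest.raises(ValueError):
            mx.response_curve(model, "NOPE")


class TestJackknife:
    def test_nested_gain_inequality_and_redundant_copy(self, fitted):
        _, bg, _, pres, _ = fitted
        bg2 = dict(bg, COPY=bg["MTCQ"].copy())
        pres2 = dict(pres, COPY=pres["MTCQ"].copy())
        feats = mx.build_features(
            bg2, ["MTCQ", "PANN", "COPY"],
            classes=["linear", "quadratic"],
        )
        result = mx.jackknife_importance(pres2, bg2, feats)
        for v, gains in result.items():
            assert gains["gain_without"] <= gains["gain_full"] + 1e-6
        # dropping an exact duplicate variable costs (almost) nothing
        copy = result["COPY"]
        assert copy["gain_full"] - copy["gain_without"] == pytest.approx(0.0, abs=1e-3)

    def test_informative_variable_beats_noise(self, small_dataset):
        stack, _, occ = small_dataset
        rng = np.random.default_rng(24)
        bg, _ = mx.sample_background(stack, ["MTCQ"], seed=0)
        n = len(bg["MTCQ"])
        bg["NOISE"] = rng.normal(size=n)
        pres = occ.covariates(["MTCQ"], period="current")
        m = len(pres["MTCQ"])
        pres["NOISE"] = rng.normal(size=m)
        feats = mx.build_features(
            bg, ["MTCQ", "NOISE"], classes=["linear", "quadratic"]
        )
        result = mx.jackknife_importance(pres, bg, feats)
        assert result["MTCQ"]["gain_alone"] > result["NOISE"]["gain_alone"]


class TestCrossValidation:
    def test_fold_sizes_and_determinism(self, fitted):
        _, bg, feats, pres, _ = fitted
        cv1 = mx.cross_validate(pres, bg, feats, k=4, seed=9)
        cv2 = mx.cross_validate(pres, bg, feats, k=4, seed=9)
        sizes = [m.n_presences for m in cv1.models]
        assert max(sizes) - min(sizes) <= 1
        assert cv1.fold_aucs == cv2.fold_aucs

    def test_mean_map_is_cellwise_mean(self, fitted):
        stack, bg, feats, pres, _ = fitted
        cv = mx.cross_validate(pres, bg, feats, k=3, seed=1, stack=stack)
        stackmaps = np.stack([mx.predict(m, stack) for m in cv.models])
        assert np.allclose(np.mean(stackmaps, 0), cv.mean_map, equal_nan=True)

    def test_k_exceeding_presences_raises(self, fitted):
        _, bg, feats, _, _ = fitted
        tiny = {v: np.arange(3, dtype=float) for v in VARS}
        with pytest.raises(ValueError):
            mx.cross_validate(tiny, bg, feats, k=5, seed=0)
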