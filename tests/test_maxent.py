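"""Maximum-entropy model: features, fitting, prediction, evaluation,
variable-importance diagnostics, and response curves."""

import numpy as np
import pandas as pd
import pytest

from maxhab.errors import DataError, ValidationError
from maxhab.maxent import (
    FeatureExpansion,
    MaxentParams,
    ResponseCurve,
    auc,
    build_features,
    classify_auc,
    crossvalidate,
    fit,
    jackknife,
    optimal_range,
    percent_contribution,
    permutation_importance,
    predict,
    predict_raster,
    response_curve,
    sample_background,
)
from maxhab.raster_io import GridSpec, Raster, RasterStack
from maxhab.synthetic import GeneratorConfig, gen_env_stack, true_suitability


def _toy(rng, n_bg=300, n_pres=80, slope=2.0, nvars=2):
    """Background table and presences biased along the first variable."""
    bg = pd.DataFrame(
        rng.normal(size=(n_bg, nvars)), columns=[f"v{i}" for i in range(nvars)]
    )
    w = np.exp(slope * bg["v0"])
    idx = rng.choice(n_bg, size=n_pres, replace=False, p=w / w.sum())
    pres = bg.iloc[idx].reset_index(drop=True)
    return pres, bg


class TestFeatures:
    def test_linear_feature_hits_scaling_endpoints(self):
        bg = pd.DataFrame({"v": [2.0, 4.0, 10.0]})
        exp_ = FeatureExpansion.from_background(bg, MaxentParams(feature_classes=("linear",)))
        F = exp_.transform(pd.DataFrame({"v": [2.0, 10.0]}))
        np.testing.assert_allclose(F[:, 0], [0.0, 1.0])

    def test_hinge_is_zero_at_knot_and_one_at_max(self, rng):
        bg = pd.DataFrame({"v": rng.uniform(0, 10, size=200)})
        exp_ = FeatureExpansion.from_background(bg, MaxentParams(feature_classes=("hinge",)))
        fwd = [i for i, d in enumerate(exp_.descriptors) if d["kind"] == "hinge_fwd"]
        j = fwd[3]
        knot = exp_.descriptors[j]["knot"]
        F = exp_.transform(pd.DataFrame({"v": [knot, bg["v"].max()]}))
        assert F[0, j] == pytest.approx(0.0)
        assert F[1, j] == pytest.approx(1.0)

    def test_background_features_land_in_unit_interval(self, rng):
        bg = pd.DataFrame(rng.normal(size=(150, 3)), columns=list("abc"))
        exp_ = FeatureExpansion.from_background(bg, MaxentParams())
        F = exp_.transform(bg)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_clamped_projection_matches_training_max(self, rng):
        bg = pd.DataFrame({"v": rng.uniform(0, 5, size=100), "w": rng.uniform(0, 5, size=100)})
        exp_ = FeatureExpansion.from_background(bg, MaxentParams())
        above = pd.DataFrame({"v": [99.0], "w": [2.0]})
        at_max = pd.DataFrame({"v": [bg["v"].max()], "w": [2.0]})
        np.testing.assert_allclose(
            exp_.transform(above, clamp=True), exp_.transform(at_max, clamp=True)
        )


class TestFit:
    def test_presences_equal_background_gives_null_model(self, rng):
        bg = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        params = MaxentParams()
        Fp, Fb, exp_ = build_features(bg, bg, params)
        model = fit(Fp, Fb, exp_, params)
        assert np.abs(model.lam).max() < 1e-3
        assert model.gain < 1e-3

    def test_duplicating_background_leaves_weights_unchanged(self, rng):
        pres, bg = _toy(rng)
        params = MaxentParams()
        Fp, Fb, exp_ = build_features(pres, bg, params)
        m1 = fit(Fp, Fb, exp_, params)
        m2 = fit(Fp, np.vstack([Fb, Fb]), exp_, params)
        np.testing.assert_allclose(m1.lam, m2.lam, atol=1e-3)
        assert m1.gain == pytest.approx(m2.gain, abs=1e-5)

    def test_convexity_same_objective_from_two_starts(self, rng):
        pres, bg = _toy(rng)
        params = MaxentParams()
        Fp, Fb, exp_ = build_features(pres, bg, params)
        m0 = fit(Fp, Fb, exp_, params)
        lam0 = rng.normal(scale=0.5, size=Fp.shape[1])
        m1 = fit(Fp, Fb, exp_, params, lam0=lam0)
        assert m0.penalized_gain == pytest.approx(m1.penalized_gain, abs=1e-6)

    def test_gain_nonnegative_at_convergence(self, fitted_model):
        assert fitted_model["model"].gain >= 0


class TestPredict:
    def test_raw_sums_to_one_over_background(self, study, fitted_model):
        names = study["stacks"]["current"].names
        raw = predict(fitted_model["model"], study["bg_table"][names], transform="raw")
        assert raw.sum() == pytest.approx(1.0, abs=1e-9)

    def test_transforms_share_cell_rankings(self, study, fitted_model):
        names = study["stacks"]["current"].names
        bg = study["bg_table"][names]
        raw = predict(fitted_model["model"], bg, transform="raw")
        logi = predict(fitted_model["model"], bg, transform="logistic")
        clog = predict(fitted_model["model"], bg, transform="cloglog")
        order = np.argsort(raw)
        # strictly monotone transforms: sorted-by-raw sequences never decrease
        assert (np.diff(logi[order]) >= 0).all()
        assert (np.diff(clog[order]) >= 0).all()
        assert ((logi >= 0) & (logi <= 1)).all() and ((clog >= 0) & (clog <= 1)).all()

    def test_null_model_is_uniform_over_background(self, rng):
        bg = pd.DataFrame(rng.normal(size=(128, 2)), columns=["a", "b"])
        params = MaxentParams()
        Fp, Fb, exp_ = build_features(bg, bg, params)
        model = fit(Fp, Fb, exp_, params)
        raw = predict(model, bg, transform="raw")
        np.testing.assert_allclose(raw, 1 / 128, atol=1e-6)

    def test_missing_projection_variable_named(self, fitted_model):
        spec = GridSpec(2, 2, 0.0, 0.0, 1.0)
        stack = RasterStack([Raster(spec, np.zeros((2, 2)), "env1")])
        with pytest.raises(DataError, match="env2"):
            predict_raster(fitted_model["model"], stack)


class TestAuc:
    def test_hand_oracle(self):
        assert auc([0.9, 0.4], [0.5, 0.1]) == pytest.approx(0.75)

    def test_all_ties_give_half(self):
        assert auc([0.3, 0.3], [0.3, 0.3, 0.3]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert auc([0.9, 0.8], [0.2, 0.1]) == pytest.approx(1.0)

    def test_invariant_under_monotone_transform(self, rng):
        pos = rng.normal(1, 1, size=50)
        neg = rng.normal(0, 1, size=80)
        base = auc(pos, neg)
        assert auc(np.exp(pos), np.exp(neg)) == pytest.approx(base, abs=1e-12)
        assert auc(3 * pos + 7, 3 * neg + 7) == pytest.approx(base, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        pos = rng.normal(1, 1, size=60)
        neg = rng.normal(0, 1, size=90)
        y = np.r_[np.ones(60), np.zeros(90)]
        assert auc(pos, neg) == pytest.approx(
            roc_auc_score(y, np.r_[pos, neg]), abs=1e-12
        )


class TestClassifyAuc:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0.942, "very-high"),
            (0.85, "good"),
            (0.75, "average"),
            (0.65, "poor"),
            (0.5, "failure"),
            (0.45, "worse-than-random"),
        ],
    )
    def test_bands(self, value, band):
        assert classify_auc(value) == band

    def test_rejects_out_of_range(self):
        with pytest.raises(ValidationError):
            classify_auc(1.2)


class TestImportance:
    def test_single_variable_model_gets_all_contribution(self, rng):
        pres, bg = _toy(rng, nvars=1)
        params = MaxentParams()
        Fp, Fb, exp_ = build_features(pres, bg, params)
        model = fit(Fp, Fb, exp_, params)
        assert percent_contribution(model) == {"v0": pytest.approx(100.0)}

    def test_contributions_sum_to_100_after_rounding(self, fitted_model):
        contrib = percent_contribution(fitted_model["model"])
        rounded = [round(v, 1) for v in contrib.values()]
        assert sum(rounded) == pytest.approx(100.0, abs=0.2)
        assert all(v >= 0 for v in rounded)

    def test_dominant_variable_leads_contribution(self, fitted_model):
        contrib = percent_contribution(fitted_model["model"])
        assert max(contrib, key=contrib.get) == "env1"
        assert contrib["env1"] > 50

    def test_permutation_importance_deterministic_and_dominant_first(
        self, study, fitted_model
    ):
        names = study["stacks"]["current"].names
        kwargs = dict(
            pres_values=study["pres_table"][names],
            bg_values=study["bg_table"][names],
            seed=11,
        )
        imp1 = permutation_importance(fitted_model["model"], **kwargs)
        imp2 = permutation_importance(fitted_model["model"], **kwargs)
        assert imp1 == imp2
        assert sum(imp1.values()) == pytest.approx(100.0)
        assert max(imp1, key=imp1.get) == "env1"


@pytest.fixture(scope="module")
def jk():
    pres, bg = _toy(np.random.default_rng(7), n_bg=400, n_pres=100, nvars=3)
    params = MaxentParams()
    return jackknife(pres, bg, params), params


class TestJackknife:

    def test_uninformative_variable_has_near_zero_gain(self, jk):
        out, _ = jk
        # v1 and v2 play no role in the presence sampling weights
        assert out["variables"]["v1"]["gain_with_only"] < 0.05
        assert out["variables"]["v2"]["gain_with_only"] < 0.05

    def test_informative_variable_has_highest_with_only_gain(self, jk):
        out, _ = jk
        gains = {v: d["gain_with_only"] for v, d in out["variables"].items()}
        assert max(gains, key=gains.get) == "v0"
        assert gains["v0"] > 0.2

    def test_nested_model_gain_monotonicity(self, jk):
        out, _ = jk
        for v, d in out["variables"].items():
            assert d["penalized_gain_without"] <= out["full_penalized_gain"] + 1e-6
            assert d["penalized_gain_with_only"] <= out["full_penalized_gain"] + 1e-6


class TestResponseCurves:
    def test_null_model_curve_is_flat_at_uniform_value(self, rng):
        bg = pd.DataFrame(rng.normal(size=(150, 2)), columns=["a", "b"])
        params = MaxentParams()
        Fp, Fb, exp_ = build_features(bg, bg, params)
        model = fit(Fp, Fb, exp_, params)
        curve = response_curve(model, "a")
        # uniform raw = 1/B and H = log B, so cloglog = 1 - exp(-1)
        np.testing.assert_allclose(curve.prediction, 1 - np.exp(-1), atol=1e-6)

    def test_monotone_driver_gives_nondecreasing_curve(self, rng):
        pres, bg = _toy(rng, slope=2.0)
        params = MaxentParams(feature_classes=("linear",))
        Fp, Fb, exp_ = build_features(pres, bg, params)
        model = fit(Fp, Fb, exp_, params)
        curve = response_curve(model, "v0")
        assert (np.diff(curve.prediction) >= -1e-12).all()

    def test_curve_endpoints_equal_direct_prediction(self, fitted_model):
        model = fitted_model["model"]
        curve = response_curve(model, "env3", n=50)
        exp_ = model.expansion
        for k in (0, 49):
            row = {
                v: (curve.grid[k] if v == "env3" else exp_.means[j])
                for j, v in enumerate(exp_.variables)
            }
            direct = predict(model, pd.DataFrame([row]))[0]
            assert curve.prediction[k] == pytest.approx(direct, abs=1e-12)


class TestOptimalRange:
    def test_flat_above_level_returns_whole_range(self):
        curve = ResponseCurve("x", np.linspace(0, 10, 50), np.full(50, 0.6))
        assert optimal_range(curve, 0.5) == [(0.0, 10.0)]

    def test_flat_below_level_is_empty(self):
        curve = ResponseCurve("x", np.linspace(0, 10, 50), np.full(50, 0.4))
        assert optimal_range(curve, 0.5) == []

    def test_tent_crossings_within_one_grid_step(self):
        x = np.linspace(-3, 3, 100)
        curve = ResponseCurve("x", x, np.maximum(0.0, 1 - np.abs(x) / 2))
        (lo, hi), = optimal_range(curve, 0.5)
        step = x[1] - x[0]
        assert lo == pytest.approx(-1.0, abs=step)
        assert hi == pytest.approx(1.0, abs=step)


class TestBackgroundSampling:
    def _stack(self):
        spec = GridSpec(2, 2, 0.0, 0.0, 1.0)
        return RasterStack([Raster(spec, np.arange(4.0).reshape(2, 2), "v")])

    def test_saturation_returns_all_with_warning(self):
        with pytest.warns(UserWarning, match="using all"):
            bg = sample_background(self._stack(), 10, seed=0)
        assert len(bg) == 4

    def test_same_seed_identical_sample(self, study):
        b1 = sample_background(study["stacks"]["current"], 500, seed=9)
        b2 = sample_background(study["stacks"]["current"], 500, seed=9)
        pd.testing.assert_frame_equal(b1, b2)

    def test_single_draw_frequencies_near_uniform(self):
        stack = self._stack()
        counts = np.zeros(4)
        for seed in range(200):
            bg = sample_background(stack, 1, seed=seed)
            counts[int(bg["v"].iloc[0])] += 1
        freq = counts / 200
        assert np.all(np.abs(freq - 0.25) <= 0.1)


class TestCrossValidation:
    def test_single_replicate_degenerates_to_one_fit(self, rng):
        pres, bg = _toy(rng)
        params = MaxentParams(replicates=1)
        models, evals, _ = crossvalidate(pres, bg, params)
        assert len(models) == 1
        assert np.isnan(evals.test_auc[0])

    def test_same_seed_identical_folds_and_raster(self, rng):
        spec = GridSpec(10, 10, 0.0, 0.0, 0.1)
        layers = [Raster(spec, rng.normal(size=(10, 10)), n) for n in ("a", "b")]
        stack = RasterStack(layers)
        bg = sample_background(stack, 100, seed=0)
        w = np.exp(2 * bg["a"])
        idx = np.random.default_rng(5).choice(100, 40, replace=False, p=w / w.sum())
        pres = bg.iloc[idx][["a", "b"]].reset_index(drop=True)
        params = MaxentParams(replicates=4, seed=13)
        _, ev1, r1 = crossvalidate(pres, bg, params, stack=stack)
        _, ev2, r2 = crossvalidate(pres, bg, params, stack=stack)
        assert ev1.test_auc == ev2.test_auc
        np.testing.assert_array_equal(r1.values, r2.values)


class TestParameterRecovery:
    def test_effect_signs_match_generator(self):
        """With log-linear truth and linear+quadratic features the sign of
        each fitted per-variable effect matches the generating coefficient
        for coefficients above the noise floor (|c| >= 1), in >= 9/10 seeds."""
        strong = {"env1": 5.0, "env3": 1.6, "env4": -1.2}
        ok = 0
        for seed in range(10):
            cfg = GeneratorConfig(seed=seed)
            stack = gen_env_stack(cfg)
            suit = true_suitability(stack, cfg)
            from maxhab.synthetic import sample_presences
            from maxhab.raster_io import extract_at_points

            occ = sample_presences(suit, 200, seed + 500)
            coords = occ.coords()
            pres = extract_at_points(stack, coords[:, 0], coords[:, 1])
            bg = sample_background(stack, 10_000, seed=seed + 900)
            params = MaxentParams(feature_classes=("linear", "quadratic"))
            Fp, Fb, exp_ = build_features(pres[stack.names], bg, params)
            model = fit(Fp, Fb, exp_, params)
            hi = {v: exp_.means[j] for j, v in enumerate(exp_.variables)}
            good = True
            for v, c in strong.items():
                lo_row, hi_row = dict(hi), dict(hi)
                j = exp_.variables.index(v)
                lo_row[v] = exp_.means[j] - 1.0
                hi_row[v] = exp_.means[j] + 1.0
                s = predict(model, pd.DataFrame([lo_row, hi_row]), transform="raw")
                if np.sign(s[1] - s[0]) != np.sign(c):
                    good = False
            ok += good
        assert ok >= 9
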