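import itertools
import math

import numpy as np
import pandas as pd
import pytest

from fishmet.model_attribution import (
    AnnConfig,
    AttributionResult,
    LinearModel,
    attribute_dataset,
    encode,
    evaluate,
    fit_ann,
    fit_ann_standardized,
    fit_linear,
    rank_drivers,
    shapley_exact,
)
from fishmet.risk_engine import species_safe_limit
from fishmet.toxdata import Metal

from conftest import make_profile


def _profiles_and_limits(toxref, n=10, seed=0):
    rng = np.random.default_rng(seed)
    profiles = [
        make_profile(
            species=f"s{i}",
            As=float(rng.lognormal(-1.5, 0.5)),
            Hg=float(rng.lognormal(-2.0, 0.5)),
            Zn=float(rng.lognormal(2.0, 0.5)),
        )
        for i in range(n)
    ]
    limits = [species_safe_limit(p, toxref) for p in profiles]
    return profiles, limits


class TestEncode:
    def test_ninety_ten_split(self, toxref):
        profiles, limits = _profiles_and_limits(toxref, n=10)
        ds = encode(profiles, limits, toxref, seed=5)
        assert len(ds.train_idx) == 9
        assert len(ds.test_idx) == 1
        assert set(ds.train_idx).isdisjoint(ds.test_idx)

    def test_same_seed_reproduces_split(self, toxref):
        profiles, limits = _profiles_and_limits(toxref, n=20)
        a = encode(profiles, limits, toxref, seed=11)
        b = encode(profiles, limits, toxref, seed=11)
        assert (a.train_idx == b.train_idx).all()
        assert a.X.equals(b.X)

    def test_flags_follow_strict_mpl_convention(self, toxref):
        p = make_profile(As=1.0)  # exactly at the MPL of 1
        limit = species_safe_limit(p, toxref)
        ds = encode([p] * 12, [limit] * 12, toxref, seed=0)
        assert (ds.X["As_flag"] == 0).all()

    def test_key_mismatch_errors(self, toxref):
        profiles, limits = _profiles_and_limits(toxref, n=5)
        with pytest.raises(ValueError):
            encode(profiles, limits[:-1], toxref, seed=0)

    def test_encoding_dictionary_is_bijective(self, toxref):
        profiles, limits = _profiles_and_limits(toxref, n=5)
        ds = encode(profiles, limits, toxref, seed=0)
        for mapping in ds.encoding.values():
            assert len(set(mapping.values())) == len(mapping)


class TestFitLinear:
    def test_exact_recovery_of_noiseless_line(self):
        x = pd.DataFrame({"x1": np.linspace(0, 10, 30)})
        y = 2.0 * x["x1"] + 3.0
        model = fit_linear(x, y)
        assert model.coef[0] == pytest.approx(2.0, abs=1e-10)
        assert model.intercept == pytest.approx(3.0, abs=1e-10)

    def test_constant_target(self):
        x = pd.DataFrame({"x1": [1.0, 2.0, 3.0, 4.0]})
        model = fit_linear(x, pd.Series([5.0] * 4))
        assert model.coef[0] == pytest.approx(0.0, abs=1e-10)
        assert model.intercept == pytest.approx(5.0, abs=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(50, 4))
        y = rng.normal(size=50)
        model = fit_linear(x, y)
        design = np.column_stack([np.ones(50), x])
        w = np.linalg.solve(design.T @ design, design.T @ y)
        assert model.intercept == pytest.approx(w[0], abs=1e-9)
        assert np.allclose(model.coef, w[1:], atol=1e-9)

    def test_rank_deficient_requires_ridge(self):
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0]})
        x["b"] = x["a"]  # perfectly collinear
        y = pd.Series([1.0, 2.0, 3.0, 4.0])
        with pytest.raises(ValueError, match="ridge"):
            fit_linear(x, y)
        model = fit_linear(x, y, ridge=1e-8)
        assert np.allclose(model.predict(x), y, atol=1e-3)


class TestFitAnn:
    def test_zero_hidden_layer_converges_to_ols(self):
        rng = np.random.default_rng(1)
        x = pd.DataFrame(rng.normal(size=(60, 2)), columns=["a", "b"])
        y = 1.5 * x["a"] - 0.5 * x["b"] + 0.25
        ols = fit_linear(x, y)
        net = fit_ann(x, y, AnnConfig(hidden=(), lr=0.05, alpha=0.0, epochs=4000, seed=0))
        assert np.allclose(net.weights[0].ravel(), ols.coef, atol=1e-3)
        assert net.biases[0].ravel()[0] == pytest.approx(ols.intercept, abs=1e-3)

    def test_loss_non_increasing_on_convex_configuration(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 3))
        y = x @ np.array([1.0, -2.0, 0.5])
        net = fit_ann(x, y, AnnConfig(hidden=(), lr=0.01, alpha=0.0, epochs=300, seed=0))
        diffs = np.diff(net.loss_history)
        assert (diffs <= 1e-12).all()

    def test_zero_learning_rate_rejected_but_tiny_rate_freezes(self):
        with pytest.raises(ValueError):
            AnnConfig(lr=0.0)

    def test_same_seed_identical_trajectory(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(30, 2))
        y = rng.normal(size=30)
        a = fit_ann(x, y, AnnConfig(seed=9, epochs=50))
        b = fit_ann(x, y, AnnConfig(seed=9, epochs=50))
        assert a.loss_history == b.loss_history
        for wa, wb in zip(a.weights, b.weights):
            assert (wa == wb).all()

    def test_divergence_raises_naming_learning_rate(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(30, 2)) * 100
        y = rng.normal(size=30) * 100
        with pytest.raises(FloatingPointError, match="lr"):
            fit_ann(x, y, AnnConfig(hidden=(), lr=10.0, epochs=200, seed=0))


class TestEvaluate:
    def test_perfect_predictor(self):
        model = LinearModel(intercept=0.0, coef=np.array([1.0]))
        x = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        metrics = evaluate(model, x, x["a"])
        assert metrics["rmse"] == pytest.approx(0.0, abs=1e-12)
        assert metrics["r2"] == pytest.approx(1.0)

    def test_constant_predictor_on_balanced_flags_scores_half(self):
        model = LinearModel(intercept=1.0, coef=np.array([0.0]))
        x = pd.DataFrame({"a": [0.0, 0.0, 1.0, 1.0]})
        metrics = evaluate(model, x, pd.Series([0.0, 0.0, 1.0, 1.0]), flag_target=True)
        assert metrics["accuracy"] == pytest.approx(0.5)

    def test_empty_test_set_errors(self):
        model = LinearModel(intercept=0.0, coef=np.array([1.0]))
        with pytest.raises(ValueError):
            evaluate(model, np.empty((0, 1)), np.empty(0))

    def test_learnable_flag_rule_recovered_at_scale(self, toxref):
        """Flags determined by a linear rule on concentrations are predicted
        well above chance once the sample is large."""
        rng = np.random.default_rng(5)
        x = pd.DataFrame({"c": rng.lognormal(0, 1, size=500)})
        y = (x["c"] > 1.0).astype(float)
        train = slice(0, 450)
        test = slice(450, 500)
        net = fit_ann_standardized(
            x.iloc[train], y.iloc[train], AnnConfig(hidden=(8,), lr=0.05, epochs=2000, seed=0)
        )
        metrics = evaluate(net, x.iloc[test], y.iloc[test], flag_target=True)
        assert metrics["accuracy"] > 0.9


class TestShapley:
    def test_additive_model_closed_form(self):
        w = np.array([2.0, -1.0, 0.5])
        f = lambda rows: rows @ w
        x = np.array([1.0, 2.0, 3.0])
        base = np.array([0.0, 1.0, -1.0])
        result = shapley_exact(f, x, base)
        expected = w * (x - base)
        assert np.allclose(list(result.values.values()), expected, atol=1e-10)

    def test_dummy_feature_gets_zero(self):
        f = lambda rows: rows[:, 0] ** 2  # independent of feature 1
        result = shapley_exact(f, np.array([2.0, 5.0]), np.array([0.0, 0.0]))
        assert result.values["x1"] == pytest.approx(0.0, abs=1e-12)

    def test_efficiency_axiom_on_random_nonlinear_function(self):
        rng = np.random.default_rng(6)
        w1 = rng.normal(size=6)
        w2 = rng.normal(size=(6, 6))
        f = lambda rows: rows @ w1 + np.sin(rows) @ w2[:, 0] + (rows**2) @ w2[:, 1]
        x = rng.normal(size=6)
        base = rng.normal(size=6)
        result = shapley_exact(f, x, base)
        assert abs(result.efficiency_residual) < 1e-8

    def test_symmetry_for_exchangeable_features(self):
        f = lambda rows: rows[:, 0] * rows[:, 1]
        result = shapley_exact(f, np.array([3.0, 3.0]), np.array([1.0, 1.0]))
        assert result.values["x0"] == pytest.approx(result.values["x1"], abs=1e-12)

    def test_matches_permutation_average_oracle(self):
        """Independent oracle: average marginal contribution over all 6!
        feature orderings equals the coalition-enumeration value."""
        rng = np.random.default_rng(7)
        p = 6
        w = rng.normal(size=p)
        v = rng.normal(size=p)
        f = lambda rows: np.tanh(rows @ w) + rows @ v
        x = rng.normal(size=p)
        base = rng.normal(size=p)

        def f_of_set(s: frozenset) -> float:
            row = base.copy()
            for i in s:
                row[i] = x[i]
            return float(f(row[None, :])[0])

        cache = {}
        phi_oracle = np.zeros(p)
        for order in itertools.permutations(range(p)):
            s = frozenset()
            for i in order:
                before = cache.setdefault(s, f_of_set(s))
                s2 = s | {i}
                after = cache.setdefault(s2, f_of_set(s2))
                phi_oracle[i] += after - before
                s = s2
        phi_oracle /= math.factorial(p)

        result = shapley_exact(f, x, base)
        assert np.allclose(list(result.values.values()), phi_oracle, atol=1e-8)

    def test_feature_count_gate(self):
        f = lambda rows: rows.sum(axis=1)
        with pytest.raises(ValueError, match="exceeds"):
            shapley_exact(f, np.zeros(16), np.zeros(16))


class TestRankDrivers:
    def test_single_varying_metal_ranks_first(self, toxref):
        rng = np.random.default_rng(9)
        profiles = [
            make_profile(species=f"s{i}", As=float(rng.lognormal(-1, 1)), Zn=5.0)
            for i in range(12)
        ]
        limits = [species_safe_limit(p, toxref) for p in profiles]
        ds = encode(profiles, limits, toxref, seed=0)
        # Zn is constant, so the design needs the ridge fallback
        model = fit_linear(ds.X_train[["As", "Zn"]], ds.y_train, ridge=1e-8)
        baseline = ds.X_train.mean()
        attrs = attribute_dataset(model, ds.X_train[["As", "Zn"]], baseline,
                                  features=["As", "Zn"])
        assert rank_drivers(attrs, ["As", "Zn"])[0] == "As"

    def test_all_zero_attributions_fall_back_to_metal_order(self):
        zeros = AttributionResult(
            values={"Zn": 0.0, "As": 0.0, "Hg": 0.0},
            baseline={}, fx=0.0, f_baseline=0.0,
        )
        assert rank_drivers([zeros], ["Zn", "As", "Hg"]) == ["As", "Hg", "Zn"]

    def test_order_invariant_to_row_permutation(self):
        a = AttributionResult(values={"As": 1.0, "Hg": -2.0}, baseline={}, fx=0, f_baseline=0)
        b = AttributionResult(values={"As": 3.0, "Hg": 0.5}, baseline={}, fx=0, f_baseline=0)
        assert rank_drivers([a, b]) == rank_drivers([b, a])
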