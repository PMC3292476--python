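"""Logistic fitting, selection, cross-validation and bootstrap machinery."""

import json

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from exocall.model import (
    DEFAULT_CUTOFF_GRID,
    LogisticModel,
    PerfectSeparationError,
    SingularDesignError,
    VariantLogit,
    bootstrap_ci,
    cross_validate,
    drop_nonsignificant,
    load_model,
    precision_sensitivity_curve,
    save_model,
    stepwise_select,
)
from exocall.simulate import simulate_training_table

BETA = (-2.0, 1.5, -0.8)
MODEL3 = LogisticModel(("x1", "x2", "x3"), 0.5, BETA)
SAMPLER3 = {"x1": ("normal", 0, 1), "x2": ("normal", 0, 1),
            "x3": ("uniform", -2, 2)}


def make_table(n, seed, model=MODEL3, sampler=SAMPLER3):
    return simulate_training_table(model, n, None, sampler, seed=seed,
                                   resample=False)


class TestScore:
    def test_zero_model_is_half(self):
        m = LogisticModel(("a", "b"), 0.0, (0.0, 0.0))
        assert m.score({"a": 123.0, "b": -4.0}) == 0.5

    def test_intercept_only_closed_form(self):
        m = LogisticModel((), 2.0, ())
        assert m.score({}) == pytest.approx(1 / (1 + np.exp(-2)), abs=1e-12)

    def test_missing_variable_named(self):
        with pytest.raises(KeyError, match="x2"):
            MODEL3.score({"x1": 1.0, "x3": 0.0})

    def test_matches_high_precision_oracle(self, rng):
        for _ in range(50):
            k = int(rng.integers(1, 6))
            beta = rng.normal(size=k)
            b0 = float(rng.normal())
            m = LogisticModel(tuple(f"v{i}" for i in range(k)), b0, tuple(beta))
            x = rng.normal(size=k)
            eta = b0 + float(np.dot(beta, x))
            expected = 1.0 / (1.0 + np.exp(-eta))
            got = m.score({f"v{i}": x[i] for i in range(k)})
            assert got == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_each_coordinate(self):
        feats = {"x1": 0.3, "x2": -1.0, "x3": 0.7}
        base = MODEL3.score(feats)
        for name, beta in zip(MODEL3.variable_names, MODEL3.coefficients):
            up = dict(feats)
            up[name] += 1.0
            assert (MODEL3.score(up) > base) == (beta > 0)


class TestFit:
    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        df = make_table(4000, seed=3)
        y = (df["label"] == "TP").astype(float)
        X = sm.add_constant(df[["x1", "x2", "x3"]].to_numpy())
        oracle = sm.Logit(y, X).fit(disp=0)
        res = VariantLogit.from_dataframe(df, ["x1", "x2", "x3"]).fit()
        np.testing.assert_allclose(res.params, oracle.params, rtol=1e-5)
        np.testing.assert_allclose(res.bse, oracle.bse, rtol=1e-4)

    def test_bruteforce_grid_mle_two_params(self):
        """IRLS lands on the grid-search maximum-likelihood point."""
        rng = np.random.default_rng(0)
        x = rng.normal(size=400)
        y = (rng.random(400) < expit(-0.5 + 1.2 * x)).astype(float)

        def llf(b0, b1):
            eta = b0 + b1 * x
            return np.sum(y * eta - np.logaddexp(0, eta))

        grid = np.linspace(-3, 3, 241)
        vals = np.array([[llf(a, b) for b in grid] for a in grid])
        i, j = np.unravel_index(vals.argmax(), vals.shape)
        res = VariantLogit(y, x[:, None], ["x"]).fit()
        # grid spacing is 0.025; refine with a local quadratic-free fine grid
        fine_a = np.linspace(grid[i] - 0.05, grid[i] + 0.05, 401)
        fine_b = np.linspace(grid[j] - 0.05, grid[j] + 0.05, 401)
        fvals = np.array([[llf(a, b) for b in fine_b] for a in fine_a])
        fi, fj = np.unravel_index(fvals.argmax(), fvals.shape)
        assert abs(res.params[0] - fine_a[fi]) < 1e-3
        assert abs(res.params[1] - fine_b[fj]) < 1e-3

    def test_duplicated_rows_leave_estimates_unchanged(self):
        df = make_table(800, seed=5)
        res1 = VariantLogit.from_dataframe(df, ["x1", "x2", "x3"]).fit()
        doubled = pd.concat([df, df], ignore_index=True)
        res2 = VariantLogit.from_dataframe(doubled, ["x1", "x2", "x3"]).fit()
        np.testing.assert_allclose(res1.params, res2.params, atol=1e-7)

    def test_perfect_separation_raises(self):
        x = np.concatenate([np.full(20, -1.0), np.full(20, 1.0)])
        y = (x > 0).astype(float)
        with pytest.raises(PerfectSeparationError):
            VariantLogit(y, x[:, None], ["x"]).fit()

    def test_singular_design_names_columns(self):
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=100)
        X = np.column_stack([x1, 2 * x1])
        y = (rng.random(100) < expit(x1)).astype(float)
        with pytest.raises(SingularDesignError):
            VariantLogit(y, X, ["a", "a_doubled"]).fit()
        with pytest.raises(SingularDesignError, match="const_col"):
            VariantLogit(
                y, np.column_stack([x1, np.ones(100)]), ["a", "const_col"]
            ).fit()

    def test_strong_separator_reports_extreme_significance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=20_000)
        y = (rng.random(20_000) < expit(4 * x)).astype(float)
        res = VariantLogit(y, x[:, None], ["x"]).fit()
        assert abs(res.zvalues[1]) > 8
        assert res.pvalues[1] < 2e-16
        assert "< 2e-16" in res.summary()

    def test_recovers_known_coefficients(self):
        df = make_table(50_000, seed=8)
        res = VariantLogit.from_dataframe(df, ["x1", "x2", "x3"]).fit()
        ci = bootstrap_ci(df, ["x1", "x2", "x3"], reps=200, seed=8)
        truth = {"const": 0.5, "x1": -2.0, "x2": 1.5, "x3": -0.8}
        for name, value in truth.items():
            assert ci.contains(name, value), (name, ci.to_frame())


class TestStepwise:
    def test_noise_variable_excluded(self):
        model = LogisticModel(("x1", "noise"), 0.0, (1.5, 0.0))
        sampler = {"x1": ("normal", 0, 1), "noise": ("normal", 0, 1)}
        df = simulate_training_table(model, 20_000, None, sampler, seed=5,
                                     resample=False)
        res = stepwise_select(df, ["x1", "noise"])
        assert tuple(res.model.variable_names) == ("x1",)

    def test_all_noise_reduces_to_intercept_only(self):
        model = LogisticModel(("a", "b"), -1.0, (0.0, 0.0))
        sampler = {"a": ("normal", 0, 1), "b": ("uniform", -1, 1)}
        df = simulate_training_table(model, 20_000, None, sampler, seed=1,
                                     resample=False)
        res = stepwise_select(df, ["a", "b"])
        assert res.model.variable_names == ()

    def test_true_generating_set_selected(self):
        model = LogisticModel(("x1", "x2", "x3", "junk"), 0.5,
                              (-2.0, 1.5, -0.8, 0.0))
        df = simulate_training_table(
            model, 30_000, None,
            {**SAMPLER3, "junk": ("normal", 0, 1)},
            seed=2, resample=False,
        )
        res = stepwise_select(df, ["x1", "x2", "x3", "junk"])
        assert set(res.model.variable_names) == {"x1", "x2", "x3"}


class TestDropNonsignificant:
    def test_fixed_point_when_all_significant(self):
        df = make_table(30_000, seed=9)
        res = drop_nonsignificant(df, ["x1", "x2", "x3"])
        assert set(res.model.variable_names) == {"x1", "x2", "x3"}

    def test_null_variable_removed_and_idempotent(self):
        model = LogisticModel(("x1", "x2", "null"), 0.0, (1.5, -0.8, 0.0))
        sampler = {"x1": ("normal", 0, 1), "x2": ("normal", 0, 1),
                   "null": ("normal", 0, 1)}
        df = simulate_training_table(model, 20_000, None, sampler, seed=3,
                                     resample=False)
        res = drop_nonsignificant(df, ["x1", "x2", "null"])
        assert set(res.model.variable_names) == {"x1", "x2"}
        res2 = drop_nonsignificant(df, list(res.model.variable_names))
        assert res2.model.variable_names == res.model.variable_names


class TestCrossValidate:
    def test_same_seed_identical(self):
        df = make_table(600, seed=11)
        a = cross_validate(df, ["x1", "x2", "x3"], reps=5, seed=3)
        b = cross_validate(df, ["x1", "x2", "x3"], reps=5, seed=3)
        np.testing.assert_array_equal(a.replicate_precision, b.replicate_precision)
        np.testing.assert_array_equal(a.replicate_sensitivity,
                                      b.replicate_sensitivity)

    def test_rejects_too_few_reps(self):
        df = make_table(100, seed=11)
        with pytest.raises(ValueError):
            cross_validate(df, ["x1"], reps=1, seed=0)

    def test_split_partitions_data(self, rng):
        """Train and test halves partition the rows in every replicate."""
        from exocall.model import draw_split

        y = (rng.random(201) < 0.2).astype(float)
        for _ in range(20):
            tr, te = draw_split(rng, y, 100)
            assert len(tr) == 100 and len(te) == 101
            assert set(tr) | set(te) == set(range(201))
            assert set(tr) & set(te) == set()
            assert 0 < y[tr].sum() < len(tr)
            assert 0 < y[te].sum() < len(te)

    def test_sensitivity_one_at_cutoff_zero(self):
        df = make_table(500, seed=13)
        res = cross_validate(df, ["x1", "x2", "x3"], reps=3, seed=2)
        assert np.all(res.replicate_sensitivity[:, 0] == 1.0)
        assert res.full_sensitivity[0] == 1.0

    def test_well_specified_mean_matches_full_curve(self):
        df = make_table(4000, seed=14)
        res = cross_validate(df, ["x1", "x2", "x3"], reps=40, seed=5)
        at = res.at_cutoff(0.5)
        assert abs(at["mean_precision"] - at["full_precision"]) < 0.02
        assert abs(at["mean_sensitivity"] - at["full_sensitivity"]) < 0.02

    def test_overfit_setting_disperses(self):
        """n=60 with 12 covariates: replicate curves spread far more."""
        k = 12
        names = tuple(f"v{i}" for i in range(k))
        sampler = {n: ("normal", 0, 1) for n in names}
        beta = tuple([1.0] + [0.0] * (k - 1))
        model = LogisticModel(names, 0.0, beta)
        small = simulate_training_table(model, 60, None, sampler, seed=15,
                                        resample=False)
        big = simulate_training_table(model, 4000, None, sampler, seed=15,
                                      resample=False)
        res_over = cross_validate(small, list(names), reps=30, seed=6)
        res_good = cross_validate(big, list(names), reps=30, seed=6)
        i = int(np.argmin(np.abs(res_over.cutoffs - 0.5)))
        std_over = np.nanstd(res_over.replicate_precision[:, i])
        std_good = np.nanstd(res_good.replicate_precision[:, i])
        assert std_over >= 3 * std_good


class TestPrecisionSensitivityCurve:
    def test_matches_naive_confusion_count(self, rng):
        y = rng.random(300) < 0.3
        s = rng.random(300)
        prec, sens = precision_sensitivity_curve(y, s, DEFAULT_CUTOFF_GRID)
        for ci, c in enumerate(DEFAULT_CUTOFF_GRID):
            called = s >= c
            tp = int((called & y).sum())
            fp = int((called & ~y).sum())
            fn = int((~called & y).sum())
            if tp + fp:
                assert prec[ci] == pytest.approx(tp / (tp + fp))
            else:
                assert np.isnan(prec[ci])
            assert sens[ci] == pytest.approx(tp / (tp + fn))


class TestModelIO:
    def test_roundtrip_identity_and_score_stability(self, tmp_path):
        path = tmp_path / "m.json"
        save_model(MODEL3, path)
        loaded = load_model(path)
        assert loaded.variable_names == MODEL3.variable_names
        assert loaded.intercept == MODEL3.intercept
        assert loaded.coefficients == MODEL3.coefficients
        feats = {"x1": 0.123456789, "x2": -3.4, "x3": 0.99}
        assert loaded.score(feats) == MODEL3.score(feats)

    def test_mismatched_lengths_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        payload = {"variables": ["a", "b"], "intercept": 0.0,
                   "coefficients": [1.0], "platform": "x", "provenance": ""}
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError):
            load_model(path)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            LogisticModel(("a",), float("nan"), (1.0,))


class TestBootstrap:
    def test_same_seed_identical(self):
        df = make_table(400, seed=16)
        a = bootstrap_ci(df, ["x1", "x2", "x3"], reps=100, seed=4)
        b = bootstrap_ci(df, ["x1", "x2", "x3"], reps=100, seed=4)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_interval_contains_point_estimate(self):
        df = make_table(2000, seed=17)
        ci = bootstrap_ci(df, ["x1", "x2", "x3"], reps=300, seed=5)
        assert ci.violations == []
        assert np.all(ci.lower <= ci.point) and np.all(ci.point <= ci.upper)

    def test_endpoint_stability_under_more_reps(self):
        df = make_table(2000, seed=18)
        small = bootstrap_ci(df, ["x1", "x2", "x3"], reps=1000, seed=6)
        big = bootstrap_ci(df, ["x1", "x2", "x3"], reps=4000, seed=6)
        width = small.width()
        assert np.all(np.abs(small.lower - big.lower) < 0.10 * width)
        assert np.all(np.abs(small.upper - big.upper) < 0.10 * width)
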