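"""Penalized-spline GAM machinery: basis, fitting, comparison, partials."""

import numpy as np
import pandas as pd
import pytest

from grc.gam import (
    CompressibilityGAM,
    GAMError,
    ModelSpec,
    RandomEffect,
    SmoothTerm,
    build_smooth_basis,
    compare_models,
    fit_difference_model,
    fit_gam,
    standard_specs,
)


@pytest.fixture(scope="module")
def linear_data():
    rng = np.random.default_rng(10)
    x = rng.uniform(0, 1, 500)
    return pd.DataFrame({"x": x, "y": 2 * x + rng.normal(0, 0.1, 500)})


@pytest.fixture(scope="module")
def sine_data():
    rng = np.random.default_rng(11)
    x = rng.uniform(0, 1, 500)
    return pd.DataFrame({"x": x, "y": np.sin(2 * np.pi * x) + rng.normal(0, 0.1, 500)})


class TestSplineBasis:
    def test_centering_leaves_dim_minus_one_columns(self, rng):
        x = rng.uniform(0, 1, 100)
        basis = build_smooth_basis(x, basis_dim=10)
        assert basis.design_train.shape == (100, 9)
        # sum-to-zero constraint holds at the training points
        assert abs(basis.design_train.sum(axis=0)).max() < 1e-10

    def test_straight_line_has_zero_penalty(self, rng):
        x = np.sort(rng.uniform(0, 1, 60))
        basis = build_smooth_basis(x, basis_dim=8)
        coef, *_ = np.linalg.lstsq(basis._raw_design(x), 1.5 + 0.7 * x, rcond=None)
        assert coef @ basis._penalty_raw @ coef < 1e-10

    def test_reproduces_cubic_exactly(self, rng):
        x = np.sort(rng.uniform(-1, 1, 80))
        y = 0.3 - 1.2 * x + 0.5 * x**2 + 2.0 * x**3
        basis = build_smooth_basis(x, basis_dim=10)
        coef, *_ = np.linalg.lstsq(basis._raw_design(x), y, rcond=None)
        assert np.abs(basis._raw_design(x) @ coef - y).max() < 1e-8

    def test_too_few_distinct_values(self):
        with pytest.raises(GAMError):
            build_smooth_basis(np.array([0.0, 1.0, 2.0] * 10), basis_dim=10)

    def test_basis_dim_floor(self):
        with pytest.raises(GAMError):
            SmoothTerm("x", basis_dim=3)


class TestFitRecovery:
    def test_linear_truth_edf_near_one_and_monotone(self, linear_data):
        res = fit_gam(linear_data, ModelSpec("y", (SmoothTerm("x"),)), "REML")
        assert 1.0 <= res.edf_by_term["x"] <= 1.3
        pe = res.partial_effect("x")
        assert np.all(np.diff(pe["effect"]) > 0)

    def test_sine_truth_detected_as_nonlinear(self, sine_data):
        res = fit_gam(sine_data, ModelSpec("y", (SmoothTerm("x"),)), "REML")
        assert res.edf_by_term["x"] > 3
        _, _, p = res.term_test("x")
        assert p < 1e-6

    def test_null_model_matches_closed_form_gaussian_aic(self, rng):
        y = 3.0 + rng.normal(0, 0.5, 400)
        res = fit_gam(pd.DataFrame({"y": y}), ModelSpec("y"), "ML")
        n = len(y)
        rss = float(np.sum((y - y.mean()) ** 2))
        closed = n * np.log(2 * np.pi * rss / n) + n + 2 * 2  # mean + variance
        assert res.aic == pytest.approx(closed, abs=2.0)

    def test_edf_bounds_respected(self, sine_data):
        res = fit_gam(sine_data, ModelSpec("y", (SmoothTerm("x", 10),)), "REML")
        assert 1.0 - 1e-6 <= res.edf_by_term["x"] <= 9.0 + 1e-6

    def test_partial_effect_matches_fitted_contribution(self, sine_data):
        model = CompressibilityGAM(sine_data, ModelSpec("y", (SmoothTerm("x"),)))
        res = model.fit("REML")
        block = [b for b in model.blocks if b.name == "x"][0]
        direct = model.X[:, block.sl] @ res.params[block.sl]
        via_api = res.partial_effect("x", grid=sine_data["x"].to_numpy())
        assert np.abs(via_api["effect"].to_numpy() - direct).max() < 1e-10

    def test_extrapolation_flagged(self, linear_data):
        res = fit_gam(linear_data, ModelSpec("y", (SmoothTerm("x"),)), "REML")
        pe = res.partial_effect("x", grid=np.array([-0.5, 0.5, 1.7]))
        assert list(pe["extrapolated"]) == [True, False, True]

    def test_summary_mentions_terms(self, linear_data):
        res = fit_gam(linear_data, ModelSpec("y", (SmoothTerm("x"),)), "REML")
        text = res.summary()
        assert "s(x)" in text and "AIC" in text and "REML" in text


class TestSpecValidation:
    def test_outcome_among_covariates(self):
        with pytest.raises(GAMError):
            ModelSpec("y", (SmoothTerm("y"),))

    def test_missing_column(self, linear_data):
        with pytest.raises(GAMError, match="missing"):
            fit_gam(linear_data, ModelSpec("y", (SmoothTerm("z"),)))

    def test_incomplete_cases_rejected(self, linear_data):
        data = linear_data.copy()
        data.loc[0, "x"] = np.nan
        with pytest.raises(GAMError, match="complete cases"):
            fit_gam(data, ModelSpec("y", (SmoothTerm("x"),)))

    def test_random_effect_needs_two_groups(self, linear_data):
        data = linear_data.assign(genus="only_one")
        spec = ModelSpec(
            "y", (SmoothTerm("x"),),
            random_effect=RandomEffect("genus", slope_covariate="x"),
        )
        with pytest.raises(GAMError, match="2 groups"):
            fit_gam(data, spec)

    def test_random_effect_needs_some_structure(self):
        with pytest.raises(GAMError):
            RandomEffect("genus")


@pytest.fixture(scope="module")
def grouped_data():
    rng = np.random.default_rng(21)
    G, per = 15, 12
    genus = np.repeat([f"g{i:02d}" for i in range(G)], per)
    size = rng.uniform(4.3, 6.0, G * per)
    z = (size - size.mean()) / size.std()
    slopes = rng.normal(0.5, 0.4, G)
    y = 4 + 0.8 * z + slopes[np.repeat(np.arange(G), per)] * z
    y += rng.normal(0, 0.15, G * per)
    return pd.DataFrame(
        {
            "genus": genus,
            "log10_size": size,
            "at": rng.uniform(0.25, 0.85, G * per),
            "ouv": rng.uniform(0, 2e-5, G * per),
            "ratio": y,
        }
    )


class TestMixedModel:

    def test_planted_genus_slopes_favor_full_model(self, grouped_data):
        comparison = compare_models(grouped_data, standard_specs("ratio"))
        assert comparison.best == "full"
        assert (
            comparison.aic["full"]
            < comparison.aic["no_random_effects"]
            < comparison.aic["null"]
        )

    def test_random_slope_variance_reported(self, grouped_data):
        res = fit_gam(grouped_data, standard_specs("ratio")["full"], "REML")
        key = "genus x log10_size"
        assert key in res.random_variances and res.random_variances[key] > 0

    def test_random_intercept_variant_fits(self, grouped_data):
        spec = ModelSpec(
            "ratio",
            (SmoothTerm("log10_size"),),
            random_effect=RandomEffect(
                "genus", slope_covariate="log10_size", include_intercept=True
            ),
        )
        res = fit_gam(grouped_data, spec, "REML")
        assert "genus (intercept)" in res.random_variances

    def test_adding_terms_never_raises_ml_deviance(self, grouped_data):
        null = fit_gam(grouped_data, ModelSpec("ratio"), "ML")
        one = fit_gam(grouped_data, ModelSpec("ratio", (SmoothTerm("log10_size"),)), "ML")
        two = fit_gam(
            grouped_data,
            ModelSpec("ratio", (SmoothTerm("log10_size"), SmoothTerm("at"))),
            "ML",
        )
        assert two.deviance <= one.deviance <= null.deviance

    def test_single_spec_comparison_is_itself(self, grouped_data):
        comparison = compare_models(grouped_data, {"null": ModelSpec("ratio")})
        assert comparison.best == "null"
        assert list(comparison.table()["model"]) == ["null"]


class TestDifferenceModel:
    def test_self_regression_recovers_identity(self, rng):
        m = 120
        df = pd.DataFrame(
            {
                "at": rng.uniform(0.3, 0.8, m),
                "log10_size": rng.uniform(4.5, 6.5, m),
                "ouv": rng.uniform(0, 1e-5, m),
            }
        )
        df["ratio_ctx"] = 4 + 0.3 * df.log10_size + rng.normal(0, 0.4, m)
        df["ratio_ctx_rc"] = df["ratio_ctx"]
        res = fit_difference_model(df, group=None)
        assert res.coefficient("ratio_ctx") == pytest.approx(1.0, abs=1e-6)
        assert res.coefficient("intercept") == pytest.approx(0.0, abs=1e-6)

    def test_missing_ratio_column(self, rng):
        with pytest.raises(GAMError, match="ratio"):
            fit_difference_model(pd.DataFrame({"ratio_ctx": [1.0]}))


@pytest.mark.skipif(
    __import__("shutil").which("Rscript") is None,
    reason="R/mgcv oracle not on PATH",
)
def test_agrees_with_mgcv_oracle(tmp_path, sine_data):
    """Independent oracle: mgcv's REML cubic-regression-spline fit on the
    same data gives closely matching fitted values and a similar edf."""
    import subprocess

    csv = tmp_path / "d.csv"
    sine_data.to_csv(csv, index=False)
    out = tmp_path / "fit.csv"
    script = (
        "suppressMessages(library(mgcv));"
        f"d <- read.csv('{csv}');"
        "f <- gam(y ~ s(x, k=10, bs='cr'), data=d, method='REML');"
        f"write.csv(data.frame(fit=fitted(f), edf=sum(f$edf)), '{out}', row.names=FALSE)"
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    oracle = pd.read_csv(out)
    res = fit_gam(sine_data, ModelSpec("y", (SmoothTerm("x"),)), "REML")
    fitted = res.fitted_values
    rms = float(np.sqrt(np.mean((fitted - oracle["fit"].to_numpy()) ** 2)))
    assert rms < 0.02  # noise sd is 0.1; the two fits agree far below it
    assert abs(res.edf_total - oracle["edf"].iloc[0]) < 1.5


def test_sign_recovery_on_measured_cohort(measured_cohort):
    """Planted positive size->ratio and OUV->ratio couplings are recovered as
    increasing partial effects over the central 80% of each covariate."""
    _, _, table = measured_cohort
    res = fit_gam(table, standard_specs("ratio_ctx")["full"], "REML")
    for term in ("log10_size", "ouv"):
        pe = res.partial_effect(term)
        lo, hi = pe["x"].quantile([0.1, 0.9])
        central = pe[(pe["x"] >= lo) & (pe["x"] <= hi)]
        assert np.all(np.diff(central["effect"]) > 0), term
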