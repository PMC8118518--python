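"""Correlation, regression-family selection and treatment-vs-control tests."""

import numpy as np
import pandas as pd
import pytest

from leafgm import compare_to_control, correlation_matrix, fit_best_relationship
from leafgm.stats import (FLAG_INSUFFICIENT, FLAG_NS, FLAG_P01,
                          FLAG_UNDEFINED, correlation_matrix_csv)


class TestCorrelationMatrix:
    def test_perfect_linear_and_antilinear(self):
        x = np.arange(10.0)
        table = pd.DataFrame({"a": x, "b": 2 * x + 3, "c": -x})
        m = correlation_matrix(table, variables=("a", "b", "c"))
        assert m.r.loc["a", "b"] == pytest.approx(1.0)
        assert m.r.loc["a", "c"] == pytest.approx(-1.0)
        assert (np.diag(m.r) == 1.0).all()

    def test_symmetric_and_bounded(self, rng):
        table = pd.DataFrame(rng.normal(size=(40, 4)), columns=list("abcd"))
        m = correlation_matrix(table, variables=list("abcd"))
        assert np.allclose(m.r, m.r.T)
        assert (m.r.abs() <= 1.0).all().all()

    def test_monte_carlo_bivariate_rho(self, rng):
        rho, n = 0.8, 500
        x = rng.normal(size=n)
        y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=n)
        m = correlation_matrix(pd.DataFrame({"x": x, "y": y}),
                               variables=("x", "y"))
        assert m.r.loc["x", "y"] == pytest.approx(rho, abs=0.05)
        assert m.flags.loc["x", "y"] == FLAG_P01

    def test_constant_column_flagged_undefined(self):
        table = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [5.0, 5, 5, 5]})
        m = correlation_matrix(table, variables=("a", "b"))
        assert np.isnan(m.r.loc["a", "b"])
        assert m.flags.loc["a", "b"] == FLAG_UNDEFINED

    def test_affine_invariance(self, rng):
        x = rng.normal(size=60)
        y = rng.normal(size=60)
        t1 = pd.DataFrame({"x": x, "y": y})
        t2 = pd.DataFrame({"x": 3.5 * x - 11.0, "y": 0.2 * y + 7.0})
        r1 = correlation_matrix(t1, variables=("x", "y")).r.loc["x", "y"]
        r2 = correlation_matrix(t2, variables=("x", "y")).r.loc["x", "y"]
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_csv_layout_stars(self):
        x = np.arange(20.0)
        table = pd.DataFrame({"a": x, "b": 2 * x})
        cells = correlation_matrix_csv(correlation_matrix(table, ("a", "b")))
        assert cells.loc["a", "b"].endswith("**")


class TestBestRelationship:
    def test_linear_exact(self):
        x = np.linspace(0, 5, 12)
        fit = fit_best_relationship(x, 3 * x - 1)
        assert fit.family == "linear"
        assert fit.r2 == pytest.approx(1.0)
        assert fit.coefficients[1] == pytest.approx(3.0)

    def test_exponential_closure(self):
        x = np.linspace(0, 2, 15)
        fit = fit_best_relationship(x, 2.0 * np.exp(1.5 * x))
        assert fit.family == "exponential"
        assert fit.coefficients == (pytest.approx(2.0), pytest.approx(1.5))
        assert fit.r2 == pytest.approx(1.0)

    def test_logarithmic_closure(self):
        x = np.linspace(0.5, 8, 15)
        fit = fit_best_relationship(x, 4.0 * np.log(x) + 1.0)
        assert fit.family == "logarithmic"
        assert fit.r2 == pytest.approx(1.0)

    def test_prediction_roundtrip(self):
        x = np.linspace(0.5, 4, 10)
        y = 2.0 * np.exp(0.7 * x)
        fit = fit_best_relationship(x, y)
        assert np.allclose(fit.predict(x), y, rtol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_best_relationship([1, 2, 3], [1, 2, 3])

    def test_negative_y_excludes_exponential_family(self):
        x = np.linspace(0, 5, 10)
        y = -2.0 + 0.5 * x  # crosses zero: exponential inadmissible
        fit = fit_best_relationship(x, y, candidates=("linear", "exponential"))
        assert fit.family == "linear"

    def test_insignificant_fit_flagged(self, rng):
        x = np.arange(8.0)
        y = rng.normal(size=8)
        fit = fit_best_relationship(x, y, candidates=("linear",))
        assert fit.significant == (fit.p_value < 0.05)


class TestCompareToControl:
    def _frame(self, ctrl_vals, trt_vals, days=None):
        rows = []
        days = days or [1]
        for d in days:
            rows += [{"day": d, "treatment": "control", "y": v} for v in ctrl_vals]
            rows += [{"day": d, "treatment": "drought", "y": v} for v in trt_vals]
        return pd.DataFrame(rows)

    def test_identical_arms_ns(self):
        out = compare_to_control(self._frame([5.0, 5.0], [5.0, 5.0]), "y")
        assert out["flag"].iloc[0] == FLAG_NS

    def test_large_separation_strongly_significant(self, rng):
        ctrl = rng.normal(10.0, 0.5, 2)
        trt = rng.normal(5.0, 0.5, 6)  # 10 pooled sd away
        out = compare_to_control(self._frame(ctrl, trt), "y", adjust=False)
        assert out["flag"].iloc[0] == FLAG_P01

    def test_single_value_arm_flagged(self):
        out = compare_to_control(self._frame([5.0], [4.0, 4.1, 3.9]), "y")
        assert out["flag"].iloc[0] == FLAG_INSUFFICIENT

    def test_one_row_per_day_with_holm_adjustment(self, rng):
        df = pd.concat([
            self._frame(rng.normal(10, 0.5, 3), rng.normal(10, 0.5, 6), [d])
            for d in range(1, 6)
        ])
        out = compare_to_control(df, "y")
        assert len(out) == 5
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()


class TestDrydownCorrelationSigns:
    def test_sign_pattern_over_seeds(self):
        """Pooled drought+control tables reproduce the expected sign
        pattern: r(An,gs)>0, r(gm,gs)>0, r(ABA,gm)<0, r(psi_leaf,gs)>0."""
        from leafgm import DrydownScenario, generate_observations
        from leafgm.pipeline import estimate_gm_table
        from leafgm.stats import derive_analysis_table

        for seed in range(10):
            tables = generate_observations(DrydownScenario(seed=seed),
                                           include_aci=False)
            est = estimate_gm_table(tables["observations"])
            analysis = derive_analysis_table(est).merge(
                tables["water_status"][["plant_id", "day", "treatment",
                                        "psi_leaf", "ABA"]],
                on=["plant_id", "day", "treatment"])
            m = correlation_matrix(analysis).r
            assert m.loc["An", "gs"] > 0
            assert m.loc["gm", "gs"] > 0
            assert m.loc["ABA", "gm"] < 0
            assert m.loc["psi_leaf", "gs"] > 0
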