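"""Per-age OLS refitting, best-subset screening, spline gap-filling."""

import numpy as np
import pandas as pd
import pytest

from yldhale import (
    ReferencePanel,
    SyntheticConfig,
    fill_gaps_spline,
    fit_age_models,
    generate_reference_panel,
    inverse_logit,
    predict_panel,
    screen_predictors,
)
from yldhale.ages import AGE_LABELS, N_AGES


def test_noiseless_panel_recovers_generating_coefficients():
    config = SyntheticConfig(seed=5, sigma=0.0)
    panel = generate_reference_panel(config)
    result = fit_age_models(panel, "both")
    got = result.table.for_sex("both")
    truth = panel.true_coefficients.for_sex("both")
    assert np.max(np.abs(got - truth)) < 1e-9
    assert np.allclose(result.diagnostics["r2"], 1.0)


def test_residuals_orthogonal_to_design(synthetic_panel):
    result = fit_age_models(synthetic_panel, "both")
    X = synthetic_panel.design_matrix("both")
    cross = X.T @ result.residuals  # (4, 21)
    scale = np.linalg.norm(X, axis=0)[:, None] * np.linalg.norm(
        result.residuals, axis=0
    )
    assert np.max(np.abs(cross) / np.maximum(scale, 1e-30)) < 1e-8


def test_fitted_value_identity(synthetic_panel):
    """Predicting at the training predictors reproduces the OLS fitted
    half-logit values before any rounding."""
    result = fit_age_models(synthetic_panel, "both")
    fitted = predict_panel(result.table, synthetic_panel, sexes=["both"])
    gamma_pred = fitted.gamma_matrix("both")
    X = synthetic_panel.design_matrix("both")
    gamma_ols = X @ result.table.for_sex("both").T
    assert np.max(np.abs(gamma_pred - gamma_ols)) < 1e-9


def test_stochastic_recovery_is_unbiased():
    """Replicate fits on noisy panels: the mean coefficient estimate sits
    within sampling error of the generating coefficients (OLS is unbiased
    under the additive half-logit noise model)."""
    n_rep = 60
    sigma = 0.05
    estimates = []
    variances = []
    for rep in range(n_rep):
        config = SyntheticConfig(seed=1000 + rep, sigma=sigma, n_years=30)
        panel = generate_reference_panel(config)
        result = fit_age_models(panel, "both")
        estimates.append(result.table.for_sex("both"))
        X = panel.design_matrix("both")
        xtx_inv_diag = np.diag(np.linalg.inv(X.T @ X))
        variances.append(sigma**2 * xtx_inv_diag)  # per-coefficient
        truth = panel.true_coefficients.for_sex("both")
    mean_est = np.mean(estimates, axis=0)  # (21, 4)
    se_mean = np.sqrt(np.mean(variances, axis=0) / n_rep)  # (4,)
    z = np.abs(mean_est - truth) / se_mean[None, :]
    assert np.max(z) < 4.5  # 84 coefficients, fixed seeds


def _panel_from_gamma(X_named: pd.DataFrame, gamma: np.ndarray) -> ReferencePanel:
    years = X_named.index.to_numpy()
    predictors = pd.DataFrame(
        {
            "year": years,
            "sex": "both",
            "iid": X_named.iloc[:, 0],
            "pcdpf": X_named.iloc[:, 1] if X_named.shape[1] > 1 else 0.2,
            "u5mr": X_named.iloc[:, 2] if X_named.shape[1] > 2 else 0.03,
        }
    )
    yld = pd.DataFrame(
        {
            "year": np.repeat(years, N_AGES),
            "sex": "both",
            "age_group": np.tile(AGE_LABELS, len(years)),
            "yld": inverse_logit(gamma).ravel(),
        }
    )
    return ReferencePanel(predictors=predictors, yld=yld)


def test_duplicate_predictor_columns_raise_collinearity_error():
    rng = np.random.default_rng(0)
    years = np.arange(1990, 2000)
    x = rng.uniform(0.001, 0.003, size=len(years))
    predictors = pd.DataFrame(
        {"year": years, "sex": "both", "iid": x, "pcdpf": x, "u5mr": x}
    )
    gamma = rng.normal(1.0, 0.1, size=(len(years), N_AGES))
    yld = pd.DataFrame(
        {
            "year": np.repeat(years, N_AGES),
            "sex": "both",
            "age_group": np.tile(AGE_LABELS, len(years)),
            "yld": inverse_logit(gamma).ravel(),
        }
    )
    panel = ReferencePanel(predictors=predictors, yld=yld)
    with pytest.raises(np.linalg.LinAlgError, match="rank deficient"):
        fit_age_models(panel, "both")


def test_panel_rejects_out_of_range_yld():
    years = np.arange(1990, 1996)
    predictors = pd.DataFrame(
        {"year": years, "sex": "both", "iid": 0.002, "pcdpf": 0.2, "u5mr": 0.03}
    )
    yld = pd.DataFrame(
        {
            "year": np.repeat(years, N_AGES),
            "sex": "both",
            "age_group": np.tile(AGE_LABELS, len(years)),
            "yld": 0.02,
        }
    )
    yld.loc[5, "yld"] = 1.2
    with pytest.raises(ValueError, match=r"outside \(0, 1\)"):
        ReferencePanel(predictors=predictors, yld=yld)


def test_panel_requires_five_years():
    years = np.arange(1990, 1993)
    predictors = pd.DataFrame(
        {"year": years, "sex": "both", "iid": 0.002, "pcdpf": 0.2, "u5mr": 0.03}
    )
    yld = pd.DataFrame(
        {
            "year": np.repeat(years, N_AGES),
            "sex": "both",
            "age_group": np.tile(AGE_LABELS, len(years)),
            "yld": 0.02,
        }
    )
    with pytest.raises(ValueError, match="at least 5"):
        ReferencePanel(predictors=predictors, yld=yld)


class TestScreening:
    @staticmethod
    def _setup(seed=1):
        rng = np.random.default_rng(seed)
        years = np.arange(1990, 2020)
        cand = pd.DataFrame(
            {
                "A": rng.uniform(0.1, 0.9, 30),
                "B": rng.uniform(0.1, 0.9, 30),
                "C": rng.uniform(0.1, 0.9, 30),
            },
            index=years,
        )
        # gamma generated exactly from A and B, no noise
        w = rng.normal(size=(N_AGES, 3))
        gamma = (
            w[:, 0][None, :]
            + cand["A"].to_numpy()[:, None] * w[:, 1][None, :]
            + cand["B"].to_numpy()[:, None] * w[:, 2][None, :]
        )
        X_named = pd.DataFrame(
            {"iid": np.clip(cand["A"] / 300, 0.0017, 0.003)}, index=years
        )
        panel = _panel_from_gamma(X_named, gamma)
        return cand, panel

    def test_exhaustive_search_finds_the_generating_pair(self):
        cand, panel = self._setup()
        report = screen_predictors(cand, panel, max_subset_size=3)
        best2 = report.best_by_size.set_index("size").loc[2, "subset"]
        assert set(best2) == {"A", "B"}
        assert set(report.chosen) >= {"A", "B"}

    def test_single_true_generator_chosen_at_size_one(self):
        rng = np.random.default_rng(9)
        years = np.arange(1990, 2020)
        cand = pd.DataFrame(
            {"A": rng.uniform(0.1, 0.9, 30), "B": rng.uniform(0.1, 0.9, 30)},
            index=years,
        )
        gamma = 1.0 + cand["A"].to_numpy()[:, None] * np.ones((1, N_AGES))
        panel = _panel_from_gamma(
            pd.DataFrame({"iid": np.full(30, 0.002) + rng.normal(0, 1e-5, 30)},
                         index=years),
            gamma,
        )
        report = screen_predictors(cand, panel, max_subset_size=1)
        assert report.chosen == ("A",)

    def test_duplicate_candidate_flagged(self):
        cand, panel = self._setup()
        cand = cand.assign(A2=cand["A"])
        report = screen_predictors(cand, panel, max_subset_size=2)
        assert report.correlations.loc["A", "A2"] == pytest.approx(1.0)
        assert np.isinf(report.vif["A"]) or report.vif["A"] > 1e6
        assert np.all(report.correlations.to_numpy().diagonal() == 1.0)
        assert np.allclose(
            report.correlations.to_numpy(), report.correlations.to_numpy().T
        )

    def test_enumeration_cap(self):
        cand, panel = self._setup()
        big = pd.concat(
            [cand.rename(columns=lambda c, k=k: f"{c}{k}") for k in range(8)], axis=1
        )
        with pytest.raises(ValueError, match="cap"):
            screen_predictors(big, panel, max_subset_size=2)


class TestSplineGapFill:
    def test_linear_series_filled_on_the_line(self):
        s = pd.Series(
            [1.0, 2.0, np.nan, 4.0, 5.0, 6.0], index=[2000, 2001, 2002, 2003, 2004, 2005]
        )
        out = fill_gaps_spline(s)
        assert out.loc[2002] == pytest.approx(3.0, abs=1e-10)
        assert out.drop(2002).equals(s.drop(2002))

    def test_complete_series_is_identity(self):
        s = pd.Series([1.0, 4.0, 9.0, 16.0], index=[1, 2, 3, 4])
        assert fill_gaps_spline(s).equals(s)

    def test_quadratic_gap_matches_tridiagonal_oracle(self):
        """Natural-spline fill of t**2 at t=3 from knots 0,1,2,4,5, checked
        against a direct solve of the textbook tridiagonal moment system."""
        x = np.array([0.0, 1.0, 2.0, 4.0, 5.0])
        y = x**2
        # second-derivative (moment) system for a natural cubic spline
        h = np.diff(x)
        n = len(x)
        A = np.zeros((n, n))
        rhs = np.zeros(n)
        A[0, 0] = A[-1, -1] = 1.0  # natural: M0 = Mn = 0
        for i in range(1, n - 1):
            A[i, i - 1] = h[i - 1]
            A[i, i] = 2.0 * (h[i - 1] + h[i])
            A[i, i + 1] = h[i]
            rhs[i] = 6.0 * ((y[i + 1] - y[i]) / h[i] - (y[i] - y[i - 1]) / h[i - 1])
        M = np.linalg.solve(A, rhs)
        i = 2  # interval [2, 4] contains t = 3
        t = 3.0
        dx = x[i + 1] - t
        dx0 = t - x[i]
        expected = (
            M[i] * dx**3 / (6 * h[i])
            + M[i + 1] * dx0**3 / (6 * h[i])
            + (y[i] / h[i] - M[i] * h[i] / 6) * dx
            + (y[i + 1] / h[i] - M[i + 1] * h[i] / 6) * dx0
        )
        s = pd.Series([0.0, 1.0, 4.0, np.nan, 16.0, 25.0], index=[0, 1, 2, 3, 4, 5])
        assert fill_gaps_spline(s).loc[3] == pytest.approx(expected, abs=1e-10)

    def test_gap_outside_range_is_an_error(self):
        s = pd.Series([np.nan, 1.0, 2.0, 3.0, 4.0], index=[0, 1, 2, 3, 4])
        with pytest.raises(ValueError, match="interpolation only"):
            fill_gaps_spline(s)

    def test_too_few_points_is_an_error(self):
        s = pd.Series([1.0, np.nan, 3.0, 4.0], index=[0, 1, 2, 3])
        with pytest.raises(ValueError, match="at least 4"):
            fill_gaps_spline(s)
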