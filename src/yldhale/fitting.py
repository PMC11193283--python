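"""Re-estimating the transfer model from a reference panel.

Each of the 21 age groups gets its own ordinary-least-squares fit of the
half-logit YLD rate on an intercept plus the predictors, over the panel
years — no pooling or smoothing across ages.  Candidate predictors can be
screened by exhaustive best-subset search ("global optimum"), and gappy
predictor time series are completed by natural cubic spline interpolation
(interior gaps only; no extrapolation).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.interpolate import CubicSpline
from statsmodels.stats.outliers_influence import variance_inflation_factor

from .ages import AGE_LABELS, N_AGES
from .core_model import (
    COEF_NAMES,
    CoefficientTable,
    _check_sex,
    logit_transform,
)

__all__ = [
    "ReferencePanel",
    "FitResult",
    "ScreeningReport",
    "fit_age_models",
    "predict_panel",
    "screen_predictors",
    "fill_gaps_spline",
]

PREDICTOR_COLS = ("iid", "pcdpf", "u5mr")

MIN_YEARS = 5  # more observations than the 4 parameters


@dataclass
class ReferencePanel:
    """A reference panel of predictors and YLD rates over years.

    ``predictors`` is long with columns year, sex, iid, pcdpf, u5mr;
    ``yld`` is long with columns year, sex, age_group, yld and optional
    yld_lo / yld_hi 95% bounds.  Every (year, sex) in the predictors must
    carry all 21 age groups in the YLD frame.  A synthetic panel may carry
    its generating coefficients in ``true_coefficients``.
    """

    predictors: pd.DataFrame
    yld: pd.DataFrame
    true_coefficients: Optional[CoefficientTable] = None

    def __post_init__(self) -> None:
        for col in ("year", "sex", *PREDICTOR_COLS):
            if col not in self.predictors.columns:
                raise ValueError(f"predictor frame missing column {col!r}")
        for col in ("year", "sex", "age_group", "yld"):
            if col not in self.yld.columns:
                raise ValueError(f"yld frame missing column {col!r}")
        for sex in self.sexes:
            years = self.years(sex)
            if len(years) < MIN_YEARS:
                raise ValueError(
                    f"panel for sex {sex!r} has {len(years)} years; "
                    f"at least {MIN_YEARS} required"
                )
            block = self.yld[self.yld["sex"] == sex]
            counts = block.groupby("year")["age_group"].nunique()
            missing = [y for y in years if counts.get(y, 0) != N_AGES]
            if missing:
                raise ValueError(
                    f"yld frame for sex {sex!r} lacks full 21-group coverage "
                    f"for years {missing}"
                )
        bad = (self.yld["yld"] <= 0.0) | (self.yld["yld"] >= 1.0)
        if bad.any():
            row = self.yld.loc[bad].iloc[0]
            raise ValueError(
                f"YLD rate outside (0, 1) at year={row['year']}, "
                f"sex={row['sex']!r}, age_group={row['age_group']!r}: {row['yld']}"
            )

    @property
    def sexes(self) -> tuple[str, ...]:
        present = set(self.predictors["sex"])
        return tuple(s for s in ("male", "female", "both") if s in present)

    def years(self, sex: str) -> np.ndarray:
        block = self.predictors[self.predictors["sex"] == sex]
        return np.sort(block["year"].unique())

    def has_bounds(self) -> bool:
        return {"yld_lo", "yld_hi"}.issubset(self.yld.columns)

    def design_matrix(self, sex: str) -> np.ndarray:
        """(n_years, 4) matrix [1, IID, PCDPF, U5MR] in year order."""
        _check_sex(sex)
        block = (
            self.predictors[self.predictors["sex"] == sex]
            .set_index("year")
            .loc[self.years(sex)]
        )
        X = block[list(PREDICTOR_COLS)].to_numpy(dtype=float)
        return np.column_stack([np.ones(len(X)), X])

    def _pivot(self, col: str, sex: str) -> np.ndarray:
        block = self.yld[self.yld["sex"] == sex]
        wide = block.pivot(index="year", columns="age_group", values=col)
        wide = wide.loc[self.years(sex), list(AGE_LABELS)]
        return wide.to_numpy(dtype=float)

    def yld_matrix(self, sex: str) -> np.ndarray:
        """(n_years, 21) YLD rates in year x canonical-age order."""
        return self._pivot("yld", sex)

    def gamma_matrix(self, sex: str) -> np.ndarray:
        """Half-logit transform of the YLD matrix."""
        return logit_transform(self.yld_matrix(sex))

    def bound_matrices(self, sex: str) -> tuple[np.ndarray, np.ndarray]:
        if not self.has_bounds():
            raise ValueError("panel carries no yld_lo / yld_hi bounds")
        return self._pivot("yld_lo", sex), self._pivot("yld_hi", sex)


@dataclass
class FitResult:
    """A fitted coefficient table with per-age OLS diagnostics."""

    table: CoefficientTable
    diagnostics: pd.DataFrame  # age_group, sex, r2, resid_se
    residuals: np.ndarray  # (n_years, 21) on the half-logit scale
    sex: str


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the culprit pairs when the deficiency is a duplicated column
        dep = []
        cols = X[:, 1:]
        k = cols.shape[1]
        for i, j in itertools.combinations(range(k), 2):
            r = np.corrcoef(cols[:, i], cols[:, j])[0, 1]
            if abs(r) > 1.0 - 1e-10:
                dep.append((names[i], names[j]))
        detail = f"; linearly dependent pairs: {dep}" if dep else ""
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]})"
            + detail
        )


def fit_age_models(panel: ReferencePanel, sex: str) -> FitResult:
    """OLS of the half-logit YLD rate on [1, IID, PCDPF, U5MR], one model
    per age group, over the panel years.

    Returns full-precision coefficients; round only on export.
    """
    _check_sex(sex)
    X = panel.design_matrix(sex)
    _check_full_rank(X, list(PREDICTOR_COLS))
    gamma = panel.gamma_matrix(sex)

    coefs = np.empty((N_AGES, 4))
    r2 = np.empty(N_AGES)
    resid_se = np.empty(N_AGES)
    resid = np.empty_like(gamma)
    for i in range(N_AGES):
        fit = sm.OLS(gamma[:, i], X).fit()
        coefs[i] = fit.params
        r2[i] = fit.rsquared
        resid_se[i] = np.sqrt(fit.ssr / fit.df_resid)
        resid[:, i] = fit.resid

    diagnostics = pd.DataFrame(
        {"age_group": list(AGE_LABELS), "sex": sex, "r2": r2, "resid_se": resid_se}
    )
    table = CoefficientTable.from_arrays(sex, coefs)
    return FitResult(table=table, diagnostics=diagnostics, residuals=resid, sex=sex)


def predict_panel(
    table: CoefficientTable, panel: ReferencePanel, sexes=None
) -> ReferencePanel:
    """Model-fitted panel: predict every panel year's YLD series from its
    predictors with ``table``, keeping the panel's year/sex structure.

    The result is shaped like a reference panel, ready for error
    assessment against the original.
    """
    from .core_model import inverse_logit

    sexes = tuple(sexes) if sexes is not None else panel.sexes
    frames = []
    for sex in sexes:
        X = panel.design_matrix(sex)
        gamma = X @ table.for_sex(sex).T  # (n_years, 21)
        y = inverse_logit(gamma)
        years = panel.years(sex)
        frames.append(
            pd.DataFrame(
                {
                    "year": np.repeat(years, N_AGES),
                    "sex": sex,
                    "age_group": np.tile(AGE_LABELS, len(years)),
                    "yld": y.ravel(),
                }
            )
        )
    return ReferencePanel(
        predictors=panel.predictors[panel.predictors["sex"].isin(sexes)].copy(),
        yld=pd.concat(frames, ignore_index=True),
    )


@dataclass
class ScreeningReport:
    """Outcome of exhaustive best-subset predictor screening."""

    candidates: list[str]
    correlations: pd.DataFrame  # candidate x candidate Pearson r
    gamma_correlations: pd.DataFrame  # age_group x candidate Pearson r
    vif: pd.Series  # candidate -> variance inflation factor
    best_by_size: pd.DataFrame  # size, subset, criterion value
    chosen: tuple[str, ...]
    criterion: str


def _subset_score(
    X: np.ndarray, gamma: np.ndarray, criterion: str
) -> float:
    """Selection criterion averaged over the 21 per-age OLS fits."""
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, gamma, rcond=None)
    resid = gamma - X @ beta
    ssr = np.sum(resid**2, axis=0)
    sst = np.sum((gamma - gamma.mean(axis=0)) ** 2, axis=0)
    if criterion == "adj_r2":
        with np.errstate(divide="ignore", invalid="ignore"):
            adj = 1.0 - (ssr / max(n - p, 1)) / (sst / (n - 1))
        return float(np.mean(adj))
    if criterion == "aic":
        sigma2 = np.maximum(ssr / n, np.finfo(float).tiny)
        aic = n * np.log(sigma2) + 2 * p
        return float(np.mean(aic))
    raise ValueError(f"unknown criterion {criterion!r}; use 'adj_r2' or 'aic'")


def screen_predictors(
    candidates: pd.DataFrame,
    panel: ReferencePanel,
    max_subset_size: int,
    sex: str = "both",
    criterion: str = "adj_r2",
    enumeration_cap: int = 20,
) -> ScreeningReport:
    """Exhaustive best-subset search for the YLD-rate predictors.

    ``candidates`` is a year-indexed frame of candidate series aligned to
    the panel years.  Every subset up to ``max_subset_size`` is fitted
    (21 per-age OLS models each) and subsets are ranked by the criterion
    averaged over age groups: adjusted R-squared (higher is better, the
    default) or AIC (lower is better).
    """
    names = list(candidates.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 candidate series to screen")
    if len(names) > enumeration_cap:
        raise ValueError(
            f"{len(names)} candidates exceed the enumeration cap "
            f"({enumeration_cap}); pre-filter the candidate set"
        )
    years = panel.years(sex)
    try:
        cand = candidates.loc[years]
    except KeyError as exc:
        raise ValueError(f"candidate series not aligned to panel years: {exc}")
    C = cand.to_numpy(dtype=float)
    gamma = panel.gamma_matrix(sex)

    correlations = cand.corr(method="pearson")
    gcorr = pd.DataFrame(
        {
            name: [np.corrcoef(C[:, j], gamma[:, i])[0, 1] for i in range(N_AGES)]
            for j, name in enumerate(names)
        },
        index=list(AGE_LABELS),
    )

    design_all = np.column_stack([np.ones(len(C)), C])
    vif_vals = []
    for j in range(len(names)):
        try:
            with np.errstate(divide="ignore"):
                v = variance_inflation_factor(design_all, j + 1)
        except Exception:
            v = np.inf
        vif_vals.append(v if np.isfinite(v) else np.inf)
    vif = pd.Series(vif_vals, index=names, name="vif")

    better = max if criterion == "adj_r2" else min
    rows = []
    for size in range(1, min(max_subset_size, len(names)) + 1):
        scored = []
        for subset in itertools.combinations(range(len(names)), size):
            X = np.column_stack([np.ones(len(C)), C[:, list(subset)]])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                continue
            scored.append(
                (tuple(names[j] for j in subset), _subset_score(X, gamma, criterion))
            )
        if scored:
            best = better(scored, key=lambda t: t[1])
            rows.append({"size": size, "subset": best[0], "criterion": best[1]})
    best_by_size = pd.DataFrame(rows)
    chosen = better(rows, key=lambda r: r["criterion"])["subset"]
    return ScreeningReport(
        candidates=names,
        correlations=correlations,
        gamma_correlations=gcorr,
        vif=vif,
        best_by_size=best_by_size,
        chosen=chosen,
        criterion=criterion,
    )


def fill_gaps_spline(series: pd.Series) -> pd.Series:
    """Complete a year-indexed series by natural cubic spline interpolation.

    Only strictly interior gaps are filled — the published procedure
    interpolates, never extrapolates.  Observed values pass through
    unchanged.  Requires at least 4 observed points.
    """
    obs = series.dropna()
    if len(obs) == len(series):
        return series.copy()
    if len(obs) < 4:
        raise ValueError(
            f"spline gap-filling needs at least 4 observed points, got {len(obs)}"
        )
    x_obs = obs.index.to_numpy(dtype=float)
    gaps = series.index[series.isna()].to_numpy(dtype=float)
    if np.any(gaps < x_obs.min()) or np.any(gaps > x_obs.max()):
        outside = [g for g in gaps if g < x_obs.min() or g > x_obs.max()]
        raise ValueError(
            f"gaps at {outside} lie at or beyond the observed range "
            f"[{x_obs.min()}, {x_obs.max()}]; interpolation only"
        )
    spline = CubicSpline(x_obs, obs.to_numpy(dtype=float), bc_type="natural")
    out = series.copy()
    out.loc[series.isna()] = spline(gaps)
    return out
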