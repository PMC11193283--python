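"""Monte-Carlo 95% uncertainty intervals for coefficients, YLD and HALE.

The reference YLD rates are treated, after the half-logit transform, as
normally distributed around their reported point values, with the spread
recovered from the reported 95% bounds (symmetric normal-theory formula,
half-width / 1.96).  One multivariate normal per panel year — diagonal
across the 21 age groups, since no correlation structure is reported —
is sampled ``n_draws`` times; each draw re-fits all 21 age models,
re-predicts YLD at the target predictors and re-computes HALE.  Reported
intervals are the 2.5th and 97.5th percentiles across draws (linear
interpolation on order statistics); the point estimate always comes from
the unperturbed fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ages import N_AGES
from .core_model import (
    CoefficientTable,
    PredictorSet,
    YLDSeries,
    inverse_logit,
    logit_transform,
)
from .fitting import FitResult, ReferencePanel, _check_full_rank, fit_age_models
from .life_table import AbridgedLifeTable, HALESeries

__all__ = ["logit_sd_from_ui", "propagate_uncertainty", "UncertaintyResult"]

#: total width of a symmetric 95% normal interval, in standard deviations
_Z95_WIDTH = 2.0 * 1.96


def logit_sd_from_ui(point, lower, upper):
    """Half-logit-scale standard deviation implied by a 95% UI.

    sd = |gamma(lower) - gamma(upper)| / (2 * 1.96); the absolute value
    absorbs the transform's reversed orientation (higher Y, lower gamma).
    Accepts scalars or arrays.
    """
    point = np.asarray(point, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    ok = (lower <= point) & (point <= upper)
    if not np.all(ok):
        bad = np.argwhere(~np.atleast_1d(ok))[0]
        raise ValueError(
            f"UI ordering violated (need lower <= point <= upper) at index "
            f"{tuple(bad)}"
        )
    sd = np.abs(logit_transform(lower) - logit_transform(upper)) / _Z95_WIDTH
    return sd if point.ndim else float(sd)


@dataclass
class UncertaintyResult:
    """Point estimates with Monte-Carlo 95% uncertainty intervals."""

    fit: FitResult  # unperturbed point fit
    coefficients: CoefficientTable  # point values with lo/hi bounds
    yld: YLDSeries  # at the target predictors, with bounds
    hale: HALESeries  # with bounds
    n_draws: int
    seed: int


def propagate_uncertainty(
    panel: ReferencePanel,
    lt: AbridgedLifeTable,
    target_predictors: PredictorSet,
    n_draws: int = 1000,
    seed: int = 0,
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> UncertaintyResult:
    """Refit-per-draw propagation of reference-panel uncertainty.

    For each draw, every panel year's 21 half-logit YLD values are
    perturbed by independent normals with the UI-implied standard
    deviations, all 21 age models are refit, YLD at ``target_predictors``
    is re-predicted and HALE re-computed against the fixed life table.
    The life table itself carries no uncertainty here.
    """
    if n_draws < 2:
        raise ValueError(f"n_draws must be at least 2, got {n_draws}")
    sex = target_predictors.sex
    if not panel.has_bounds():
        raise ValueError(
            "uncertainty propagation needs yld_lo / yld_hi bounds on the panel"
        )

    gamma_obs = panel.gamma_matrix(sex)  # (n_years, 21)
    lo, hi = panel.bound_matrices(sex)
    sd = logit_sd_from_ui(panel.yld_matrix(sex), lo, hi)

    X = panel.design_matrix(sex)
    _check_full_rank(X, ["iid", "pcdpf", "u5mr"])
    pinv = np.linalg.pinv(X)  # (4, n_years)

    rng = np.random.default_rng(seed)
    # one diagonal 21-dim normal per year, n_draws samples each; slot 0 is
    # the zero-noise point estimate run through the identical pipeline so
    # degenerate (zero-sd) inputs yield bit-identical point and bounds
    noise = np.concatenate(
        [
            np.zeros((1, *gamma_obs.shape)),
            rng.standard_normal((n_draws, *gamma_obs.shape)),
        ]
    )
    gamma_draws = gamma_obs[None, :, :] + sd[None, :, :] * noise

    # refit all 21 models for every draw in one tensor contraction:
    # (4, n_years) x (1+n_draws, n_years, 21) -> (1+n_draws, 4, 21)
    coef_all = np.einsum("py,dya->dpa", pinv, gamma_draws)

    x_target = target_predictors.as_array()  # (4,)
    gamma_target = np.einsum("p,dpa->da", x_target, coef_all)
    yld_all = inverse_logit(gamma_target)

    # vectorised Sullivan sum over draws
    healthy = lt.L[None, :] * (1.0 - yld_all)
    hale_all = np.cumsum(healthy[:, ::-1], axis=1)[:, ::-1] / lt.l[None, :]

    point_coefs, coef_draws = coef_all[0].T, coef_all[1:]  # point: (21, 4)
    point_yld, yld_draws = yld_all[0], yld_all[1:]
    point_hale, hale_draws = hale_all[0], hale_all[1:]

    p_lo, p_hi = percentiles
    coef_lo = np.percentile(coef_draws, p_lo, axis=0).T  # (21, 4)
    coef_hi = np.percentile(coef_draws, p_hi, axis=0).T
    # the finite-draw percentile interval may not bracket the point fit;
    # clamp so reported intervals always contain the point estimate
    coef_lo = np.minimum(coef_lo, point_coefs)
    coef_hi = np.maximum(coef_hi, point_coefs)
    coefficients = CoefficientTable.from_arrays(sex, point_coefs, coef_lo, coef_hi)

    yld = YLDSeries(
        sex=sex,
        values=point_yld,
        lower=np.minimum(np.percentile(yld_draws, p_lo, axis=0), point_yld),
        upper=np.maximum(np.percentile(yld_draws, p_hi, axis=0), point_yld),
    )
    hale = HALESeries(
        sex=sex,
        values=point_hale,
        lower=np.minimum(np.percentile(hale_draws, p_lo, axis=0), point_hale),
        upper=np.maximum(np.percentile(hale_draws, p_hi, axis=0), point_hale),
    )
    fit = fit_age_models(panel, sex)
    return UncertaintyResult(
        fit=fit,
        coefficients=coefficients,
        yld=yld,
        hale=hale,
        n_draws=n_draws,
        seed=seed,
    )
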