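"""Seeded synthetic data with the statistical structure the method assumes.

The generator manufactures everything the pipeline consumes, so every
stage is testable without any download: smooth trended predictor series
inside the observed Chinese 1990-2019 ranges, reference YLD panels built
by inverting the transfer model from known coefficients plus half-logit
Gaussian noise, and abridged life tables from a Gompertz-Makeham hazard.

All randomness flows from one seed through a single generator, consumed
in a fixed order: predictor noise first (iid, pcdpf, u5mr, year-major),
then the half-logit YLD noise sex by sex.  Regenerating with the same
config is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .ages import AGE_STARTS, AGE_WIDTHS, AGE_LABELS, N_AGES
from .core_model import CoefficientTable, inverse_logit
from .fitting import ReferencePanel
from .life_table import AbridgedLifeTable, build_life_table

__all__ = [
    "PredictorProcess",
    "SyntheticConfig",
    "generate_predictor_panel",
    "generate_reference_panel",
    "generate_life_table",
]

_Z95 = 1.96

#: PCDPF mean ratios of the sex-specific to the combined series, used to
#: derive male/female chronic-disease trajectories from the combined one
_PCDPF_SEX_RATIO = {"both": 1.0, "male": 0.2463 / 0.2656, "female": 0.2846 / 0.2656}


@dataclass(frozen=True)
class PredictorProcess:
    """Linear-trend-plus-noise process for one predictor, clipped to the
    observed range of the corresponding Chinese indicator."""

    start: float
    trend: float  # per year
    noise_sd: float
    bounds: tuple[float, float]

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        lo, hi = self.bounds
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"bounds must satisfy 0 <= lo < hi <= 1, got {self.bounds}")

    def path(self, n_years: int) -> np.ndarray:
        t = np.arange(n_years)
        drift = self.start + self.trend * t
        lo, hi = self.bounds
        if np.any(drift < lo) or np.any(drift > hi):
            raise ValueError(
                f"trend drives the series outside its bounds {self.bounds} "
                f"within {n_years} years"
            )
        return drift


def _default_coefficients() -> CoefficientTable:
    from .io import load_coefficient_table

    return load_coefficient_table("gbd2019_china_3param")


@dataclass
class SyntheticConfig:
    """Study-shaped defaults: a 30-year panel (one GBD-style revision
    span), predictor trajectories spanning the observed 1990-2019 ranges
    of the three Chinese indicators, half-logit noise and UI half-width
    of 0.05, and a Gompertz-Makeham mortality schedule with a
    life expectancy at birth near 74 years."""

    n_years: int = 30
    seed: int = 0
    start_year: int = 1990
    sexes: tuple[str, ...] = ("both",)
    coefficients: Optional[CoefficientTable] = None  # defaults to the bundled asset
    iid: PredictorProcess = PredictorProcess(
        start=0.0030, trend=-4.2e-5, noise_sd=5e-5, bounds=(0.0017, 0.0030)
    )
    pcdpf: PredictorProcess = PredictorProcess(
        start=0.1900, trend=0.0115, noise_sd=0.008, bounds=(0.16, 0.55)
    )
    u5mr: PredictorProcess = PredictorProcess(
        start=0.0600, trend=-0.00178, noise_sd=5e-4, bounds=(0.0078, 0.0610)
    )
    sigma: float = 0.05  # half-logit YLD noise sd
    ui_half_width: float = 0.05  # half-logit UI half-width (one sd)
    gompertz_alpha: float = 3e-5
    gompertz_beta: float = 0.1
    makeham_c: float = 5e-4
    radix: float = 100_000.0
    a0: float = 0.3

    def __post_init__(self) -> None:
        if self.n_years < 5:
            raise ValueError("n_years must be at least 5")
        if self.sigma < 0 or self.ui_half_width < 0:
            raise ValueError("sigma and ui_half_width must be non-negative")

    def coefficient_table(self) -> CoefficientTable:
        return self.coefficients or _default_coefficients()

    @property
    def years(self) -> np.ndarray:
        return self.start_year + np.arange(self.n_years)


def _predictor_paths(
    config: SyntheticConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Noisy bounded paths; pcdpf key is the combined series."""
    out = {}
    for name in ("iid", "pcdpf", "u5mr"):
        proc: PredictorProcess = getattr(config, name)
        drift = proc.path(config.n_years)
        noisy = drift + proc.noise_sd * rng.standard_normal(config.n_years)
        out[name] = np.clip(noisy, *proc.bounds)
    return out


def generate_predictor_panel(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> pd.DataFrame:
    """Long predictor frame (year, sex, iid, pcdpf, u5mr).

    IID and U5MR are combined-population rates shared across sexes; the
    sex-specific PCDPF is the combined path rescaled by the observed
    male/female-to-combined mean ratio, clipped back into its bounds.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    paths = _predictor_paths(config, rng)
    frames = []
    for sex in config.sexes:
        pcdpf = np.clip(
            paths["pcdpf"] * _PCDPF_SEX_RATIO[sex], *config.pcdpf.bounds
        )
        frames.append(
            pd.DataFrame(
                {
                    "year": config.years,
                    "sex": sex,
                    "iid": paths["iid"],
                    "pcdpf": pcdpf,
                    "u5mr": paths["u5mr"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_reference_panel(config: SyntheticConfig) -> ReferencePanel:
    """Reference panel whose YLD rates are the transfer model inverted.

    For each sex, gamma = true linear predictor + N(0, sigma) on the
    half-logit scale; Y = inverse transform; 95% bounds are the inverse
    transform of gamma -/+ 1.96 * ui_half_width (orientation flipped so
    lower < upper on the Y scale).  The generating coefficients travel
    with the panel as retrievable ground truth.
    """
    rng = np.random.default_rng(config.seed)
    predictors = generate_predictor_panel(config, rng)
    table = config.coefficient_table()

    yld_frames = []
    for sex in config.sexes:
        block = predictors[predictors["sex"] == sex].set_index("year")
        X = np.column_stack(
            [
                np.ones(config.n_years),
                block.loc[config.years, ["iid", "pcdpf", "u5mr"]].to_numpy(),
            ]
        )
        coefs = table.for_sex(sex)  # (21, 4)
        gamma_true = X @ coefs.T  # (n_years, 21)
        gamma = gamma_true + config.sigma * rng.standard_normal(gamma_true.shape)
        y = inverse_logit(gamma)
        # higher gamma means lower Y, so the +h image is the lower bound
        half = _Z95 * config.ui_half_width
        y_lo = inverse_logit(gamma + half)
        y_hi = inverse_logit(gamma - half)
        yld_frames.append(
            pd.DataFrame(
                {
                    "year": np.repeat(config.years, N_AGES),
                    "sex": sex,
                    "age_group": np.tile(AGE_LABELS, config.n_years),
                    "yld": y.ravel(),
                    "yld_lo": y_lo.ravel(),
                    "yld_hi": y_hi.ravel(),
                }
            )
        )
    return ReferencePanel(
        predictors=predictors,
        yld=pd.concat(yld_frames, ignore_index=True),
        true_coefficients=table,
    )


def gompertz_makeham_hazard(
    age, alpha: float, beta: float, c: float
) -> np.ndarray:
    """m(x) = c + alpha * exp(beta * x)."""
    return c + alpha * np.exp(beta * np.asarray(age, dtype=float))


def generate_life_table(config: SyntheticConfig) -> AbridgedLifeTable:
    """Abridged life table from the Gompertz-Makeham hazard evaluated at
    group midpoints (the open 95+ group uses a representative age of
    97.5 years)."""
    starts = np.array(AGE_STARTS)
    widths = np.array(AGE_WIDTHS)
    mid = starts + np.where(np.isfinite(widths), widths, 5.0) / 2.0
    m = gompertz_makeham_hazard(
        mid, config.gompertz_alpha, config.gompertz_beta, config.makeham_c
    )
    if np.any(m <= 0.0):
        raise ValueError("hazard parameters produce non-positive death rates")
    return build_life_table(m, radix=config.radix, a0=config.a0)
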