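"""The YLD-rate transfer model.

Twenty-one age-specific linear models map three routinely monitored
indicators — the incidence of class A/B notifiable infectious diseases
(IID), the prevalence/incidence of chronic disease among persons aged 15+
(PCDPF), and the under-five mortality rate (U5MR), all proportions — to
the all-cause years-lived-with-disability (YLD) rate of each age group.

The models act on a half-logit scale with reversed orientation,

    gamma(Y) = 0.5 * ln((1 - Y) / Y),

so gamma is *decreasing* in Y and the back-transform is
Y = 1 / (1 + exp(2 * gamma)).  Published coefficient tables are only valid
under this exact transform; a standard logit must not be substituted.

For sex-specific predictions only PCDPF is sex-specific; IID and U5MR are
always the combined-population rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .ages import AGE_LABELS, N_AGES

SEXES = ("male", "female", "both")

COEF_NAMES = ("beta", "a", "b", "c")

__all__ = [
    "SEXES",
    "COEF_NAMES",
    "PredictorSet",
    "CoefficientTable",
    "YLDSeries",
    "logit_transform",
    "inverse_logit",
    "predict_yld_rates",
]


def _check_sex(sex: str) -> str:
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    return sex


def logit_transform(y):
    """Half-logit transform gamma(y) = 0.5*ln((1-y)/y), decreasing in y.

    Accepts a scalar or array of proportions strictly inside (0, 1).
    """
    arr = np.asarray(y, dtype=float)
    bad = ~np.isfinite(arr) | (arr <= 0.0) | (arr >= 1.0)
    if np.any(bad):
        offending = arr[bad].ravel()[0] if arr.ndim else float(arr)
        raise ValueError(
            f"logit_transform requires 0 < y < 1; got {offending!r}"
        )
    out = 0.5 * np.log((1.0 - arr) / arr)
    return out if arr.ndim else float(out)


def inverse_logit(gamma):
    """Back-transform Y = 1/(1 + exp(2*gamma)); always strictly in (0, 1)."""
    arr = np.asarray(gamma, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("inverse_logit requires finite gamma")
    # exp overflow is harmless here: 1/(1+inf) -> 0.0, clip keeps it open
    with np.errstate(over="ignore"):
        out = 1.0 / (1.0 + np.exp(2.0 * arr))
    tiny = np.finfo(float).tiny
    out = np.clip(out, tiny, 1.0 - np.finfo(float).epsneg)
    return out if arr.ndim else float(out)


@dataclass(frozen=True)
class PredictorSet:
    """One (IID, PCDPF, U5MR) triple of proportions, with the sex the
    PCDPF value refers to.  IID and U5MR are combined-population rates
    regardless of sex."""

    iid: float
    pcdpf: float
    u5mr: float
    sex: str = "both"

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        for name in ("iid", "pcdpf", "u5mr"):
            v = getattr(self, name)
            if not np.isfinite(v) or not (0.0 <= v <= 1.0):
                raise ValueError(
                    f"{name} must be a proportion in [0, 1], got {v!r}; "
                    "rates per 100 000 must be divided by 100 000 first"
                )

    def as_array(self) -> np.ndarray:
        """Design row [1, IID, PCDPF, U5MR]."""
        return np.array([1.0, self.iid, self.pcdpf, self.u5mr])


class CoefficientTable:
    """Per-age, per-sex coefficients (beta, a, b, c) of the transfer model,
    optionally with 95% uncertainty bounds per coefficient.

    Backed by a DataFrame with columns age_group, sex, beta, a, b, c and
    optional ``<coef>_lo`` / ``<coef>_hi`` columns.  Each sex present must
    carry all 21 age groups exactly once.
    """

    def __init__(self, frame: pd.DataFrame):
        required = ["age_group", "sex", *COEF_NAMES]
        missing = [c for c in required if c not in frame.columns]
        if missing:
            raise ValueError(f"coefficient table missing columns {missing}")
        frame = frame.copy()
        for sex in frame["sex"].unique():
            _check_sex(sex)
        for sex, block in frame.groupby("sex"):
            labels = list(block["age_group"])
            if sorted(labels) != sorted(AGE_LABELS):
                missing_ages = [l for l in AGE_LABELS if l not in labels]
                dup = [l for l in set(labels) if labels.count(l) > 1]
                raise ValueError(
                    f"coefficient table for sex {sex!r} must have each of the "
                    f"21 age groups exactly once; missing {missing_ages}, "
                    f"duplicated {dup}"
                )
        for name in COEF_NAMES:
            lo, hi = f"{name}_lo", f"{name}_hi"
            if lo in frame.columns and hi in frame.columns:
                ok = (frame[lo] <= frame[name]) & (frame[name] <= frame[hi])
                if not ok.all():
                    bad = frame.loc[~ok, ["age_group", "sex"]].iloc[0]
                    raise ValueError(
                        f"UI bounds violated for {name} at age_group="
                        f"{bad['age_group']!r}, sex={bad['sex']!r}"
                    )
        self.frame = frame.reset_index(drop=True)

    @property
    def sexes(self) -> tuple[str, ...]:
        return tuple(s for s in SEXES if s in set(self.frame["sex"]))

    def has_bounds(self) -> bool:
        return all(
            f"{n}_lo" in self.frame.columns and f"{n}_hi" in self.frame.columns
            for n in COEF_NAMES
        )

    def for_sex(self, sex: str) -> np.ndarray:
        """(21, 4) array of [beta, a, b, c] rows in canonical age order."""
        _check_sex(sex)
        block = self.frame[self.frame["sex"] == sex]
        if block.empty:
            raise KeyError(
                f"coefficient table has no rows for sex {sex!r}; "
                f"available: {list(self.sexes)}"
            )
        block = block.set_index("age_group").loc[list(AGE_LABELS)]
        return block[list(COEF_NAMES)].to_numpy(dtype=float)

    @classmethod
    def from_arrays(
        cls,
        sex: str,
        coefs: np.ndarray,
        lower: Optional[np.ndarray] = None,
        upper: Optional[np.ndarray] = None,
    ) -> "CoefficientTable":
        """Build a single-sex table from a (21, 4) coefficient array."""
        coefs = np.asarray(coefs, dtype=float)
        if coefs.shape != (N_AGES, 4):
            raise ValueError(f"expected a (21, 4) array, got {coefs.shape}")
        data = {"age_group": list(AGE_LABELS), "sex": sex}
        for j, name in enumerate(COEF_NAMES):
            data[name] = coefs[:, j]
        if lower is not None and upper is not None:
            for j, name in enumerate(COEF_NAMES):
                data[f"{name}_lo"] = np.asarray(lower, dtype=float)[:, j]
                data[f"{name}_hi"] = np.asarray(upper, dtype=float)[:, j]
        return cls(pd.DataFrame(data))

    def rounded(self, decimals: int = 4) -> "CoefficientTable":
        """Copy with all coefficient (and bound) columns rounded, the
        precision used for published tables."""
        frame = self.frame.copy()
        cols = [c for c in frame.columns if c not in ("age_group", "sex")]
        frame[cols] = frame[cols].round(decimals)
        return CoefficientTable(frame)

    def __eq__(self, other) -> bool:
        return isinstance(other, CoefficientTable) and self.frame.equals(other.frame)


@dataclass
class YLDSeries:
    """21 age-specific YLD rates for one sex, each strictly in (0, 1),
    with optional lower/upper uncertainty bounds."""

    sex: str
    values: np.ndarray
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_AGES,):
            raise ValueError(
                f"YLD series must have {N_AGES} values, got shape {self.values.shape}"
            )
        if np.any(self.values <= 0.0) or np.any(self.values >= 1.0):
            raise ValueError("YLD rates must lie strictly in (0, 1)")
        if (self.lower is None) != (self.upper is None):
            raise ValueError("provide both lower and upper bounds or neither")
        if self.lower is not None:
            self.lower = np.asarray(self.lower, dtype=float)
            self.upper = np.asarray(self.upper, dtype=float)
            ok = (
                (self.lower > 0.0)
                & (self.lower <= self.values)
                & (self.values <= self.upper)
                & (self.upper < 1.0)
            )
            if not ok.all():
                i = int(np.flatnonzero(~ok)[0])
                raise ValueError(
                    f"YLD bounds violated at age group {AGE_LABELS[i]!r}: "
                    f"lower={self.lower[i]}, value={self.values[i]}, "
                    f"upper={self.upper[i]}"
                )

    def to_frame(self) -> pd.DataFrame:
        data = {"age_group": list(AGE_LABELS), "sex": self.sex, "yld": self.values}
        if self.lower is not None:
            data["yld_lo"] = self.lower
            data["yld_hi"] = self.upper
        return pd.DataFrame(data)


def linear_predictor(table: CoefficientTable, predictors: PredictorSet) -> np.ndarray:
    """gamma_i = beta_i + a_i*IID + b_i*PCDPF + c_i*U5MR for all 21 groups."""
    coefs = table.for_sex(predictors.sex)
    return coefs @ predictors.as_array()


def predict_yld_rates(table: CoefficientTable, predictors: PredictorSet) -> YLDSeries:
    """Point prediction of the 21 age-specific YLD rates.

    Evaluates each age group's linear predictor on the half-logit scale and
    back-transforms, so results are in (0, 1) by construction.
    """
    gamma = linear_predictor(table, predictors)
    return YLDSeries(sex=predictors.sex, values=inverse_logit(gamma))
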