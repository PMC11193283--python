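"""Error assessment of model-fitted YLD rates and HALE against a reference.

Accuracy is summarised by the mean absolute error, in the units of the
quantity itself, and the mean absolute percentage error, in percent:

    MAE  = (1/n) * sum |yhat_i - y_i|
    MAPE = (100/n) * sum |yhat_i - y_i| / |y_i|

reported per age group and in total.  "Total" pools every (year, age)
record rather than averaging the per-age statistics; a per-age mean is
available as a sensitivity option.  HALE errors compare Sullivan
conversions of the fitted and reference YLD series against the same fixed
life table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .ages import AGE_LABELS
from .core_model import YLDSeries
from .fitting import ReferencePanel
from .life_table import AbridgedLifeTable, sullivan_hale

__all__ = [
    "mean_absolute_error",
    "mean_absolute_percentage_error",
    "evaluate_panel",
    "EvaluationReport",
]


def _as_aligned(fitted, reference) -> tuple[np.ndarray, np.ndarray]:
    f = np.asarray(fitted, dtype=float)
    r = np.asarray(reference, dtype=float)
    if f.shape != r.shape or f.size == 0:
        raise ValueError(
            f"fitted and reference must have equal nonzero length; "
            f"got shapes {f.shape} and {r.shape}"
        )
    if not (np.all(np.isfinite(f)) and np.all(np.isfinite(r))):
        raise ValueError("fitted and reference values must be finite")
    return f, r


def mean_absolute_error(fitted, reference) -> float:
    """MAE = (1/n) * sum |yhat_i - y_i|, in the quantity's own units."""
    f, r = _as_aligned(fitted, reference)
    return float(np.mean(np.abs(f - r)))


def mean_absolute_percentage_error(fitted, reference) -> float:
    """MAPE = (100/n) * sum |yhat_i - y_i| / |y_i|, in percent."""
    f, r = _as_aligned(fitted, reference)
    zero = r == 0.0
    if np.any(zero):
        idx = int(np.flatnonzero(zero)[0])
        raise ZeroDivisionError(
            f"MAPE undefined: reference value is 0 at index {idx}"
        )
    return float(100.0 * np.mean(np.abs((f - r) / r)))


@dataclass
class EvaluationReport:
    """Per-age and total MAE/MAPE for YLD rates and (optionally) HALE."""

    sex: str
    yld_errors: pd.DataFrame  # age_group (incl. "Total"), mae, mape
    residuals: pd.DataFrame  # year, sex, age_group, fitted, reference, residual
    hale_errors: Optional[pd.DataFrame] = None
    total_mode: str = "pooled"

    @property
    def total_yld_mae(self) -> float:
        return float(self.yld_errors.set_index("age_group").loc["Total", "mae"])

    @property
    def total_yld_mape(self) -> float:
        return float(self.yld_errors.set_index("age_group").loc["Total", "mape"])


def _error_table(
    fitted: np.ndarray, reference: np.ndarray, total_mode: str
) -> pd.DataFrame:
    """Per-age rows plus a Total row from (n_years, 21) matrices."""
    rows = []
    for i, label in enumerate(AGE_LABELS):
        rows.append(
            {
                "age_group": label,
                "mae": mean_absolute_error(fitted[:, i], reference[:, i]),
                "mape": mean_absolute_percentage_error(fitted[:, i], reference[:, i]),
            }
        )
    if total_mode == "pooled":
        total_mae = mean_absolute_error(fitted.ravel(), reference.ravel())
        total_mape = mean_absolute_percentage_error(fitted.ravel(), reference.ravel())
    elif total_mode == "per_age_mean":
        total_mae = float(np.mean([r["mae"] for r in rows]))
        total_mape = float(np.mean([r["mape"] for r in rows]))
    else:
        raise ValueError(
            f"total_mode must be 'pooled' or 'per_age_mean', got {total_mode!r}"
        )
    rows.append({"age_group": "Total", "mae": total_mae, "mape": total_mape})
    return pd.DataFrame(rows)


def evaluate_panel(
    fitted: ReferencePanel,
    reference: ReferencePanel,
    sex: str = "both",
    lt: Optional[AbridgedLifeTable] = None,
    total_mode: str = "pooled",
) -> EvaluationReport:
    """Compare a model-fitted panel with a reference panel year by year.

    Both panels must cover the same years for ``sex``.  YLD errors are
    always computed; HALE errors are added when a life table is supplied,
    converting each year's fitted and reference YLD series with the same
    table, so HALE differences reflect the YLD model alone.
    """
    years_f = fitted.years(sex)
    years_r = reference.years(sex)
    if not np.array_equal(years_f, years_r):
        raise ValueError(
            f"panels not aligned for sex {sex!r}: fitted years "
            f"{list(years_f)} vs reference years {list(years_r)}"
        )
    F = fitted.yld_matrix(sex)
    R = reference.yld_matrix(sex)

    yld_errors = _error_table(F, R, total_mode)

    records = []
    for t, year in enumerate(years_f):
        for i, label in enumerate(AGE_LABELS):
            records.append(
                {
                    "year": year,
                    "sex": sex,
                    "age_group": label,
                    "fitted": F[t, i],
                    "reference": R[t, i],
                    "residual": F[t, i] - R[t, i],
                }
            )
    residuals = pd.DataFrame(records)

    hale_errors = None
    if lt is not None:
        hale_f = np.empty_like(F)
        hale_r = np.empty_like(R)
        for t in range(len(years_f)):
            hale_f[t] = sullivan_hale(lt, YLDSeries(sex=sex, values=F[t])).values
            hale_r[t] = sullivan_hale(lt, YLDSeries(sex=sex, values=R[t])).values
        hale_errors = _error_table(hale_f, hale_r, total_mode)

    return EvaluationReport(
        sex=sex,
        yld_errors=yld_errors,
        residuals=residuals,
        hale_errors=hale_errors,
        total_mode=total_mode,
    )
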