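"""Abridged life tables and the Sullivan conversion of YLD rates to HALE.

The Sullivan method discounts the person-years lived in each age group by
the proportion of the year lived in less-than-full health (the YLD rate):

    HALE_x = sum_{j >= x} L_j * (1 - Y_j) / l_x

where l_x are survivors at the start of group x and L_j the person-years
lived within group j.  The life table is held fixed; only the YLD rates
carry uncertainty elsewhere in this package.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .ages import AGE_LABELS, AGE_WIDTHS, N_AGES
from .core_model import YLDSeries, _check_sex

__all__ = ["AbridgedLifeTable", "HALESeries", "build_life_table", "sullivan_hale"]


@dataclass
class AbridgedLifeTable:
    """Survivors ``l`` and person-years ``L`` over the canonical 21 groups.

    ``l`` is radix-scaled (l[0] == radix) and non-increasing; every ``L`` is
    positive and, for closed groups, at most width * l at the group start.
    Death rates ``m`` are optional (kept when the table was built from
    rates).  Remaining life expectancy ``e`` is derived.
    """

    l: np.ndarray
    L: np.ndarray
    m: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=float)
        self.L = np.asarray(self.L, dtype=float)
        if self.l.shape != (N_AGES,) or self.L.shape != (N_AGES,):
            raise ValueError(
                f"life table needs {N_AGES} rows; got l{self.l.shape}, L{self.L.shape}"
            )
        if np.any(self.l <= 0.0):
            raise ValueError("survivors l must be strictly positive")
        if np.any(np.diff(self.l) > 0.0):
            raise ValueError("survivors l must be non-increasing with age")
        if np.any(self.L <= 0.0):
            raise ValueError("person-years L must be strictly positive")
        widths = np.array(AGE_WIDTHS[:-1])
        if np.any(self.L[:-1] > widths * self.l[:-1] * (1.0 + 1e-12)):
            raise ValueError("closed-group L cannot exceed width * l")
        if self.m is not None:
            self.m = np.asarray(self.m, dtype=float)

    @property
    def e(self) -> np.ndarray:
        """Remaining life expectancy at the start of each group."""
        return np.cumsum(self.L[::-1])[::-1] / self.l

    def to_frame(self) -> pd.DataFrame:
        data = {"age_group": list(AGE_LABELS), "l": self.l, "L": self.L}
        if self.m is not None:
            data["m"] = self.m
        data["e"] = self.e
        return pd.DataFrame(data)


@dataclass
class HALESeries:
    """Healthy years of life remaining at the start of each age group."""

    sex: str
    values: np.ndarray
    lower: Optional[np.ndarray] = None
    upper: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        _check_sex(self.sex)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_AGES,):
            raise ValueError(f"HALE series must have {N_AGES} values")
        if np.any(self.values <= 0.0):
            raise ValueError("HALE values must be positive")
        if (self.lower is None) != (self.upper is None):
            raise ValueError("provide both lower and upper bounds or neither")
        if self.lower is not None:
            self.lower = np.asarray(self.lower, dtype=float)
            self.upper = np.asarray(self.upper, dtype=float)
            if np.any(self.lower > self.values) or np.any(self.values > self.upper):
                raise ValueError("HALE bounds must bracket the point values")

    def to_frame(self) -> pd.DataFrame:
        data = {"age_group": list(AGE_LABELS), "sex": self.sex, "hale": self.values}
        if self.lower is not None:
            data["hale_lo"] = self.lower
            data["hale_hi"] = self.upper
        return pd.DataFrame(data)


def build_life_table(
    m: np.ndarray, radix: float = 100_000.0, a0: float = 0.3
) -> AbridgedLifeTable:
    """Standard abridged life table from age-specific death rates.

    Probabilities of death use the constant average-years-lived
    approximation q = n*m / (1 + (n - a)*m), with a = a0*n in the infant
    group (deaths concentrated early in the first year) and a = n/2 in the
    other closed groups.  The open group has q = 1 and L = l / m.

    Parameters
    ----------
    m : 21 death rates, all positive.
    radix : initial cohort size l0.
    a0 : fraction of the first year lived by those dying in it, in (0, 1).
    """
    m = np.asarray(m, dtype=float)
    if m.shape != (N_AGES,):
        raise ValueError(f"expected {N_AGES} death rates, got shape {m.shape}")
    if np.any(m <= 0.0) or not np.all(np.isfinite(m)):
        raise ValueError("all death rates must be positive and finite")
    if not (radix > 0.0):
        raise ValueError("radix must be positive")
    if not (0.0 < a0 < 1.0):
        raise ValueError("a0 must lie in (0, 1)")

    widths = np.array(AGE_WIDTHS[:-1])
    avg_years = widths / 2.0
    avg_years[0] = a0 * widths[0]

    q = widths * m[:-1] / (1.0 + (widths - avg_years) * m[:-1])
    if np.any(q >= 1.0):
        i = int(np.flatnonzero(q >= 1.0)[0])
        raise ValueError(
            f"death rate m={m[i]} in closed group {AGE_LABELS[i]!r} implies "
            "q >= 1 (cohort exhausted before the open group)"
        )

    l = np.empty(N_AGES)
    L = np.empty(N_AGES)
    l[0] = radix
    for i in range(N_AGES - 1):
        d = l[i] * q[i]
        l[i + 1] = l[i] - d
        L[i] = widths[i] * l[i + 1] + avg_years[i] * d
    L[N_AGES - 1] = l[N_AGES - 1] / m[N_AGES - 1]
    return AbridgedLifeTable(l=l, L=L, m=m)


def sullivan_hale(lt: AbridgedLifeTable, yld) -> HALESeries:
    """Health-adjusted life expectancy at every age-group start.

    HALE_x = sum over remaining groups of L * (1 - Y), divided by survivors
    at x.  ``yld`` is a :class:`YLDSeries` or a bare 21-vector; the bare
    form additionally admits exact zeros so the disability-free limit
    (HALE identical to life expectancy) can be evaluated exactly.
    """
    if isinstance(yld, YLDSeries):
        values, sex = yld.values, yld.sex
    else:
        values = np.asarray(yld, dtype=float)
        sex = "both"
        if values.shape != (N_AGES,):
            raise ValueError(f"YLD vector must have {N_AGES} values")
        if np.any(values < 0.0) or np.any(values >= 1.0):
            raise ValueError("YLD values must lie in [0, 1)")
    healthy_py = lt.L * (1.0 - values)
    hale = np.cumsum(healthy_py[::-1])[::-1] / lt.l
    return HALESeries(sex=sex, values=hale)
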