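"""CSV readers and writers for every table dialect the tool exchanges.

All files share one age-group label dialect ("0", "1-4", ..., "95+");
loaders reject other spellings outright so rows can never be silently
misaligned.  Proportions are validated to [0, 1] at the boundary — inputs
on a per-100 000 scale fail fast with a conversion hint, and the predictor
loader can divide by 100 000 on request.  Writers prefix a deterministic
metadata header as '#' comment lines; readers skip such lines.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .ages import AGE_LABELS
from .core_model import COEF_NAMES, SEXES, CoefficientTable, PredictorSet, YLDSeries
from .fitting import ReferencePanel
from .life_table import AbridgedLifeTable

__all__ = [
    "load_coefficient_table",
    "write_coefficient_table",
    "read_life_table",
    "write_life_table",
    "read_predictors",
    "read_panel",
    "write_panel",
    "read_yld_series",
    "write_frame",
]

BUNDLED_ASSETS = ("gbd2019_china_3param",)


class ParseError(ValueError):
    """A CSV cell or label that the dialect does not admit."""


def _read_csv(path: Union[str, Path]) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", skip_blank_lines=True)


def _check_labels(frame: pd.DataFrame, path: str) -> None:
    bad = sorted(set(frame["age_group"].astype(str)) - set(AGE_LABELS) - {"Total"})
    if bad:
        raise ParseError(
            f"{path}: invalid age-group label(s) {bad}; the dialect is "
            f"'0', '1-4', '5-9', ..., '90-94', '95+'"
        )


def _check_numeric(frame: pd.DataFrame, cols, path: str) -> pd.DataFrame:
    out = frame.copy()
    for col in cols:
        if col not in out.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
        parsed = pd.to_numeric(out[col], errors="coerce")
        bad = parsed.isna() & out[col].notna()
        if bad.any() or parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna())[0])
            raise ParseError(
                f"{path}: non-numeric or missing value in column {col!r}, "
                f"data row {row}"
            )
        out[col] = parsed
    return out


def _check_proportions(frame: pd.DataFrame, cols, path: str) -> None:
    for col in cols:
        outside = (frame[col] < 0.0) | (frame[col] > 1.0)
        if outside.any():
            row = int(np.flatnonzero(outside)[0])
            raise ParseError(
                f"{path}: column {col!r} has value {frame[col].iloc[row]} "
                f"outside [0, 1] at data row {row}; rates per 100 000 must "
                f"be divided by 100 000 (see the per_100k loader option)"
            )


def load_coefficient_table(source: Union[str, Path]) -> CoefficientTable:
    """Load a coefficient table from a bundled asset name or a CSV path.

    The bundled ``"gbd2019_china_3param"`` asset carries the published
    male/female/combined three-predictor coefficients with their 95%
    uncertainty bounds, at the 4-decimal precision of the published table.
    """
    if isinstance(source, str) and source in BUNDLED_ASSETS:
        resource = importlib.resources.files("yldhale").joinpath(
            f"data/{source}.csv"
        )
        with importlib.resources.as_file(resource) as path:
            frame = _read_csv(path)
        label = f"asset {source!r}"
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"{source!r} is neither a bundled asset "
                f"({', '.join(BUNDLED_ASSETS)}) nor an existing file"
            )
        frame = _read_csv(path)
        label = str(path)

    for col in ("age_group", "sex"):
        if col not in frame.columns:
            raise ParseError(f"{label}: missing required column {col!r}")
    _check_labels(frame, label)
    bad_sex = sorted(set(frame["sex"]) - set(SEXES))
    if bad_sex:
        raise ParseError(f"{label}: unknown sex value(s) {bad_sex}")
    numeric = [c for c in frame.columns if c not in ("age_group", "sex")]
    frame = _check_numeric(frame, numeric, label)
    try:
        return CoefficientTable(frame)
    except ValueError as exc:
        raise ParseError(f"{label}: {exc}") from exc


def _metadata_lines(metadata: Optional[Mapping[str, object]]) -> str:
    if not metadata:
        return ""
    return "".join(f"# {key}: {value}\n" for key, value in metadata.items())


def write_frame(
    frame: pd.DataFrame,
    path: Union[str, Path],
    metadata: Optional[Mapping[str, object]] = None,
) -> None:
    """Write a CSV with a '#'-comment metadata header (no timestamps, so
    identical inputs produce byte-identical files)."""
    with open(path, "w", newline="") as fh:
        fh.write(_metadata_lines(metadata))
        frame.to_csv(fh, index=False)


def write_coefficient_table(
    table: CoefficientTable,
    path: Union[str, Path],
    metadata: Optional[Mapping[str, object]] = None,
    decimals: Optional[int] = None,
) -> None:
    """Export a coefficient table; pass ``decimals=4`` for the published
    presentation precision (full precision is the default)."""
    out = table.rounded(decimals) if decimals is not None else table
    write_frame(out.frame, path, metadata)


def read_life_table(path: Union[str, Path]) -> AbridgedLifeTable:
    """Life-table CSV with columns age_group, l, L and optional m."""
    frame = _read_csv(path)
    for col in ("age_group", "l", "L"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    _check_labels(frame, str(path))
    frame = _check_numeric(
        frame, ["l", "L"] + (["m"] if "m" in frame.columns else []), str(path)
    )
    frame = frame.set_index("age_group").loc[list(AGE_LABELS)]
    m = frame["m"].to_numpy() if "m" in frame.columns else None
    try:
        return AbridgedLifeTable(
            l=frame["l"].to_numpy(), L=frame["L"].to_numpy(), m=m
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_life_table(
    lt: AbridgedLifeTable,
    path: Union[str, Path],
    metadata: Optional[Mapping[str, object]] = None,
) -> None:
    write_frame(lt.to_frame(), path, metadata)


def read_predictors(
    path: Union[str, Path], per_100k: bool = False
) -> pd.DataFrame:
    """Predictor CSV with columns year, sex, iid, pcdpf, u5mr.

    With ``per_100k=True`` the three rate columns are divided by 100 000
    on load (for inputs published on the per-100 000 scale).
    """
    frame = _read_csv(path)
    for col in ("year", "sex", "iid", "pcdpf", "u5mr"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    frame = _check_numeric(frame, ["year", "iid", "pcdpf", "u5mr"], str(path))
    bad_sex = sorted(set(frame["sex"]) - set(SEXES))
    if bad_sex:
        raise ParseError(f"{path}: unknown sex value(s) {bad_sex}")
    if per_100k:
        frame[["iid", "pcdpf", "u5mr"]] /= 100_000.0
    _check_proportions(frame, ["iid", "pcdpf", "u5mr"], str(path))
    return frame


def predictor_set_for(
    predictors: pd.DataFrame, sex: str, year: Optional[int] = None
) -> PredictorSet:
    """One PredictorSet from a predictor frame (latest year by default)."""
    block = predictors[predictors["sex"] == sex]
    if block.empty:
        raise ParseError(f"no predictor rows for sex {sex!r}")
    if year is None:
        year = int(block["year"].max())
    row = block[block["year"] == year]
    if row.empty:
        raise ParseError(f"no predictor row for sex {sex!r}, year {year}")
    row = row.iloc[0]
    return PredictorSet(
        iid=float(row["iid"]),
        pcdpf=float(row["pcdpf"]),
        u5mr=float(row["u5mr"]),
        sex=sex,
    )


def read_yld_series(path: Union[str, Path], sex: str) -> YLDSeries:
    """One 21-row YLD series (columns age_group, sex, yld[, yld_lo, yld_hi])."""
    frame = _read_csv(path)
    for col in ("age_group", "sex", "yld"):
        if col not in frame.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    _check_labels(frame, str(path))
    block = frame[frame["sex"] == sex]
    if len(block) != len(AGE_LABELS):
        raise ParseError(
            f"{path}: expected {len(AGE_LABELS)} rows for sex {sex!r}, "
            f"got {len(block)}"
        )
    cols = ["yld"] + [c for c in ("yld_lo", "yld_hi") if c in block.columns]
    block = _check_numeric(block, cols, str(path))
    block = block.set_index("age_group").loc[list(AGE_LABELS)]
    kwargs = {}
    if {"yld_lo", "yld_hi"}.issubset(block.columns):
        kwargs = {
            "lower": block["yld_lo"].to_numpy(),
            "upper": block["yld_hi"].to_numpy(),
        }
    try:
        return YLDSeries(sex=sex, values=block["yld"].to_numpy(), **kwargs)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_panel(
    yld_path: Union[str, Path],
    predictors_path: Union[str, Path],
    per_100k: bool = False,
) -> ReferencePanel:
    """Reference panel from the long YLD CSV plus the predictor CSV."""
    predictors = read_predictors(predictors_path, per_100k=per_100k)
    yld = _read_csv(yld_path)
    for col in ("year", "sex", "age_group", "yld"):
        if col not in yld.columns:
            raise ParseError(f"{yld_path}: missing required column {col!r}")
    _check_labels(yld, str(yld_path))
    cols = ["year", "yld"] + [c for c in ("yld_lo", "yld_hi") if c in yld.columns]
    yld = _check_numeric(yld, cols, str(yld_path))
    try:
        return ReferencePanel(predictors=predictors, yld=yld)
    except ValueError as exc:
        raise ParseError(f"{yld_path}: {exc}") from exc


def write_panel(
    panel: ReferencePanel,
    yld_path: Union[str, Path],
    predictors_path: Union[str, Path],
    metadata: Optional[Mapping[str, object]] = None,
) -> None:
    write_frame(panel.yld, yld_path, metadata)
    write_frame(panel.predictors, predictors_path, metadata)
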