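"""Reading, validating and describing daily diary (EMA) data.

The pipeline operates on one individual's diary: one row per day, one
column per self-report variable (e.g. a depression sum score and minutes
of physical activity), an optional calendar-date column and optional
user-supplied exogenous columns. Assessments must be daily and complete:
missing cells and date gaps are hard errors, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EmaDataset",
    "RunConfig",
    "DiaryError",
    "read_diary",
    "write_diary",
    "describe",
]

#: Below this many assessments a warning is raised: dynamic models on
#: shorter diaries are estimable but poorly powered.
RECOMMENDED_MIN_T = 50


class DiaryError(ValueError):
    """Invalid diary input (missing cell, date gap, non-numeric value...)."""


@dataclass(frozen=True)
class EmaDataset:
    """A validated, equidistant daily multivariate diary.

    Parameters
    ----------
    values
        T x V frame of endogenous diary scores, one column per variable.
    dates
        Optional length-T daily, consecutive calendar dates.
    exogenous
        Optional T x E frame of extra predictor columns (trend, dummies,
        user controls). Only ever used on the right-hand side.
    """

    values: pd.DataFrame
    dates: Optional[pd.Series] = None
    exogenous: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        values = self.values
        if values.ndim != 2 or values.shape[1] < 1:
            raise DiaryError("diary needs at least one variable column")
        _check_no_missing(values, "values")
        if not all(np.issubdtype(d, np.number) for d in values.dtypes):
            bad = [c for c in values.columns if not np.issubdtype(values[c].dtype, np.number)]
            raise DiaryError(f"non-numeric column(s): {bad}")
        if self.dates is not None:
            dates = pd.Series(pd.to_datetime(self.dates).values)
            if len(dates) != len(values):
                raise DiaryError("dates length does not match number of rows")
            deltas = dates.diff().dropna()
            gaps = deltas[deltas != pd.Timedelta(days=1)]
            if len(gaps):
                i = int(gaps.index[0])
                raise DiaryError(
                    f"dates are not daily-consecutive: gap between row {i} "
                    f"({dates.iloc[i - 1].date()}) and row {i + 1} ({dates.iloc[i].date()})"
                )
            object.__setattr__(self, "dates", dates)
        if self.exogenous is not None:
            if len(self.exogenous) != len(values):
                raise DiaryError("exogenous length does not match number of rows")
            _check_no_missing(self.exogenous, "exogenous")

    @property
    def T(self) -> int:
        return len(self.values)

    @property
    def variable_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def exogenous_names(self) -> list[str]:
        return [] if self.exogenous is None else list(self.exogenous.columns)

    def select(self, variables: Sequence[str]) -> "EmaDataset":
        """Restrict the endogenous block to ``variables`` (order kept)."""
        missing = [v for v in variables if v not in self.values.columns]
        if missing:
            raise DiaryError(f"unknown variable(s): {missing}")
        return replace(self, values=self.values[list(variables)])

    def with_exogenous(self, extra: pd.DataFrame) -> "EmaDataset":
        """Return a copy with columns of ``extra`` appended to the exogenous block."""
        if self.exogenous is None:
            exog = extra.reset_index(drop=True)
        else:
            exog = pd.concat(
                [self.exogenous.reset_index(drop=True), extra.reset_index(drop=True)], axis=1
            )
        return replace(self, exogenous=exog)


@dataclass(frozen=True)
class RunConfig:
    """Settings for one automated model-search run."""

    max_lag: int = 2
    criterion: str = "AIC"
    timestamps_enabled: bool = False
    allow_25_sd: bool = False
    alpha: float = 0.05
    selected_variables: Optional[tuple[str, ...]] = None
    exogenous_selection: tuple[str, ...] = field(default_factory=tuple)
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.max_lag < 1:
            raise ValueError("max_lag must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        crit = self.criterion.upper()
        if crit not in ("AIC", "BIC"):
            raise ValueError("criterion must be 'AIC' or 'BIC'")
        object.__setattr__(self, "criterion", crit)


def _check_no_missing(frame: pd.DataFrame, what: str) -> None:
    mask = frame.isna()
    if mask.to_numpy().any():
        row = int(mask.any(axis=1).idxmax())
        col = mask.columns[int(mask.loc[row].to_numpy().argmax())]
        # 1-based day index, matching how days are reported elsewhere
        raise DiaryError(f"missing value at row {row + 1}, column {col} (in {what})")


def read_diary(
    path: str | Path,
    date_column: Optional[str] = None,
    exogenous_labels: Sequence[str] = (),
) -> EmaDataset:
    """Read a delimited diary file (CSV/TSV, delimiter auto-detected).

    Every non-date column is numerically coerced; a cell that cannot be
    coerced, a missing cell, or a non-daily date gap is a hard error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, sep=None, engine="python")
    dates = None
    if date_column is not None:
        if date_column not in raw.columns:
            raise DiaryError(f"date column {date_column!r} not in file header")
        try:
            dates = pd.to_datetime(raw.pop(date_column))
        except (ValueError, TypeError) as exc:
            raise DiaryError(f"unparseable dates in column {date_column!r}: {exc}") from exc
    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise DiaryError(
                f"non-numeric value {raw[col][row]!r} at row {row + 1}, column {col}"
            )
        raw[col] = coerced.astype(float)
    exogenous_labels = list(exogenous_labels)
    missing = [c for c in exogenous_labels if c not in raw.columns]
    if missing:
        raise DiaryError(f"exogenous column(s) not in file header: {missing}")
    endo = raw.drop(columns=exogenous_labels)
    exog = raw[exogenous_labels] if exogenous_labels else None
    dataset = EmaDataset(values=endo.reset_index(drop=True), dates=dates, exogenous=exog)
    if dataset.T < RECOMMENDED_MIN_T:
        warnings.warn(
            f"only {dataset.T} assessments; at least {RECOMMENDED_MIN_T} are "
            "recommended for a stable dynamic model",
            UserWarning,
            stacklevel=2,
        )
    return dataset


def write_diary(dataset: EmaDataset, path: str | Path, date_column: str = "date") -> Path:
    """Write a dataset back to CSV in the layout ``read_diary`` accepts."""
    path = Path(path)
    out = dataset.values.copy()
    if dataset.exogenous is not None:
        out = pd.concat([out, dataset.exogenous.reset_index(drop=True)], axis=1)
    if dataset.dates is not None:
        out.insert(0, date_column, dataset.dates.dt.strftime("%Y-%m-%d").values)
    out.to_csv(path, index=False)
    return path


def describe(dataset: EmaDataset) -> pd.DataFrame:
    """Per-variable summary: n, mean, SD (n-1), min, max, zero count.

    The zero count feeds the log-transform shift decision: diary scales
    legitimately contain zeros, so the log branch uses ln(x + 1).
    A constant column is flagged degenerate (SD = 0; nothing to model).
    """
    rows = []
    for name in dataset.variable_names:
        col = dataset.values[name].to_numpy(dtype=float)
        sd = float(np.std(col, ddof=1)) if len(col) > 1 else float("nan")
        rows.append(
            {
                "variable": name,
                "n": len(col),
                "mean": float(np.mean(col)),
                "sd": sd,
                "min": float(np.min(col)),
                "max": float(np.max(col)),
                "zero_count": int(np.sum(col == 0)),
                "degenerate": bool(sd == 0),
            }
        )
    return pd.DataFrame(rows).set_index("variable")
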