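"""Candidate model structure: transforms and exogenous design columns.

A :class:`ModelSpec` is one point of the combinatorial search space — a lag
order plus flags for weekday dummies and log transformation, a per-variable
outlier-dummy severity level, a data-determined trend flag and any
user-selected exogenous columns. ``materialize`` turns a spec into a dataset
whose exogenous block carries the corresponding design columns, in a fixed
order so every downstream coefficient table is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .data_io import EmaDataset

__all__ = [
    "ModelSpec",
    "OUTLIER_LEVELS",
    "apply_log",
    "weekday_dummies",
    "detect_outliers",
    "materialize",
    "dominates",
]

#: Outlier-dummy escalation ladder, least to most severe. ``None`` means no
#: outlier dummies; 2.5 is only enumerated when explicitly allowed.
OUTLIER_LEVELS: tuple[Optional[float], ...] = (None, 3.5, 3.0, 2.5)

WEEKDAY_NAMES = ("Mon", "Tue", "Wed", "Thu", "Fri", "Sat")  # Sunday = reference


@dataclass(frozen=True)
class ModelSpec:
    """One candidate model structure.

    ``outlier_levels`` holds one severity per endogenous variable (ordered as
    the dataset's variables); ``outlier_days`` the resolved 1-based diary days
    flagged at that severity (empty tuples until resolved against residuals).
    ``constraints`` is filled by pruning: pairs (equation variable, regressor
    label) fixed to zero.
    """

    lag: int
    weekday: bool = False
    log_transform: bool = False
    outlier_levels: tuple[Optional[float], ...] = ()
    outlier_days: tuple[tuple[int, ...], ...] = ()
    trend: bool = False
    user_exogenous: tuple[str, ...] = ()
    constraints: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.lag < 1:
            raise ValueError("lag must be >= 1")
        for level in self.outlier_levels:
            if level is not None and level not in (3.5, 3.0, 2.5):
                raise ValueError(f"unknown outlier level {level}")
        if self.outlier_days and len(self.outlier_days) != len(self.outlier_levels):
            raise ValueError("outlier_days must align with outlier_levels")

    @property
    def base(self) -> "ModelSpec":
        """The same spec with no outlier dummies (the escalation base)."""
        n = len(self.outlier_levels)
        return replace(
            self,
            outlier_levels=(None,) * n,
            outlier_days=((),) * n,
            constraints=frozenset(),
        )

    def severity_ranks(self) -> tuple[int, ...]:
        return tuple(OUTLIER_LEVELS.index(lv) for lv in self.outlier_levels)

    def describe(self) -> str:
        parts = [f"lag={self.lag}"]
        parts.append(f"weekday={'yes' if self.weekday else 'no'}")
        parts.append(f"log={'yes' if self.log_transform else 'no'}")
        parts.append(f"trend={'yes' if self.trend else 'no'}")
        levels = ",".join("-" if lv is None else f"{lv}sd" for lv in self.outlier_levels)
        parts.append(f"outliers=[{levels}]")
        return " ".join(parts)


def dominates(simple: ModelSpec, complex_: ModelSpec) -> bool:
    """True iff ``simple`` makes ``complex_`` redundant.

    Requires identical lag/weekday/log/trend factors and a strictly less
    severe outlier configuration somewhere, never more severe anywhere.
    """
    if (simple.lag, simple.weekday, simple.log_transform, simple.trend) != (
        complex_.lag,
        complex_.weekday,
        complex_.log_transform,
        complex_.trend,
    ):
        return False
    a, b = simple.severity_ranks(), complex_.severity_ranks()
    if len(a) != len(b):
        return False
    return all(x <= y for x, y in zip(a, b)) and a != b


def apply_log(dataset: EmaDataset) -> EmaDataset:
    """Replace every endogenous variable by ln(x + 1).

    The +1 shift keeps legitimate diary zeros (e.g. zero minutes of
    activity) in the domain; exogenous columns are untouched.
    """
    values = dataset.values
    arr = values.to_numpy(dtype=float)
    if (arr < 0).any():
        row, col = np.argwhere(arr < 0)[0]
        raise ValueError(
            f"negative value at row {row + 1}, variable {values.columns[col]}: "
            "log transform needs nonnegative diary scores"
        )
    logged = pd.DataFrame(np.log1p(arr), columns=values.columns)
    return replace(dataset, values=logged)


def weekday_dummies(dates: pd.Series) -> pd.DataFrame:
    """One-hot columns for Monday..Saturday; Sunday is the dropped reference."""
    dates = pd.Series(pd.to_datetime(dates).values)
    out = {}
    dow = dates.dt.dayofweek.to_numpy()  # Monday=0 .. Sunday=6
    for j, name in enumerate(WEEKDAY_NAMES):
        out[f"wd_{name}"] = (dow == j).astype(float)
    return pd.DataFrame(out)


def detect_outliers(
    residual_series: np.ndarray, level: float, lag_offset: int = 0
) -> tuple[int, ...]:
    """1-based diary days whose residual is > ``level`` sample SDs from the mean.

    ``lag_offset`` shifts residual positions back to original diary days:
    residual t of a lag-p model belongs to day t + p.
    """
    e = np.asarray(residual_series, dtype=float)
    sd = float(np.std(e, ddof=1))
    if sd == 0:
        warnings.warn("constant residuals: no outliers detectable", UserWarning, stacklevel=2)
        return ()
    z = np.abs(e - e.mean()) / sd
    return tuple(int(i) + 1 + lag_offset for i in np.flatnonzero(z > level))


def materialize(dataset: EmaDataset, spec: ModelSpec) -> EmaDataset:
    """Apply the spec's transforms and append its design columns.

    Column order is fixed: trend, weekday dummies, outlier dummies (by
    variable, then day), then user exogenous columns. Outlier days must
    already be resolved (see the search driver's escalation logic).
    """
    out = dataset
    if spec.log_transform:
        out = apply_log(out)
    blocks: list[pd.DataFrame] = []
    T = dataset.T
    if spec.trend:
        blocks.append(pd.DataFrame({"trend": np.arange(1, T + 1, dtype=float)}))
    if spec.weekday:
        if dataset.dates is None:
            raise ValueError("weekday dummies require calendar dates")
        blocks.append(weekday_dummies(dataset.dates))
    if spec.outlier_levels and any(lv is not None for lv in spec.outlier_levels):
        if not spec.outlier_days:
            raise ValueError("outlier days not resolved for this spec")
        for var, level, days in zip(
            dataset.variable_names, spec.outlier_levels, spec.outlier_days
        ):
            if level is None:
                continue
            for day in days:
                if not 1 <= day <= T:
                    raise ValueError(f"outlier day {day} outside 1..{T}")
                col = np.zeros(T)
                col[day - 1] = 1.0
                blocks.append(pd.DataFrame({f"outlier_{var}_day{day}": col}))
    if spec.user_exogenous:
        if dataset.exogenous is None:
            raise ValueError("spec selects user exogenous columns but dataset has none")
        missing = [c for c in spec.user_exogenous if c not in dataset.exogenous.columns]
        if missing:
            raise ValueError(f"unknown exogenous column(s): {missing}")
        blocks.append(dataset.exogenous[list(spec.user_exogenous)].reset_index(drop=True))
    structural = pd.concat(blocks, axis=1) if blocks else None
    return replace(out, exogenous=structural)
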