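"""Sex/age normative percentile tables and percentile placement.

A :class:`NormativeTable` holds reference quantiles of postural
parameters on the grid (sex, age, parameter, percentile) with the seven
chart percentiles {3, 10, 25, 50, 75, 90, 97}. The packaged default
table covers the five sagittal angles (SS, LL, TK, CI, HP) for
7-year-old girls, in degrees, from a school-screening reference cohort
(N = 1083 in that stratum).

Individual values are placed on the chart by linear interpolation of the
percentile as a function of the tabulated values; values outside the
[p3, p97] envelope are reported categorically ("<3" / ">97") rather than
extrapolated, because the charts end there.

New tables are built from cohort observations with the usual linearly
interpolated empirical quantile (numpy's default, the "type 7"
definition); no smoothing across ages is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .landmarks import CohortRecord

CHART_PERCENTILES = (3, 10, 25, 50, 75, 90, 97)

_NORMATIVE_COLUMNS = ["sex", "age", "parameter", "percentile", "value"]


class NormativeTableError(ValueError):
    """The normative grid is malformed (e.g. non-monotone percentile row)."""


@dataclass(frozen=True)
class PercentilePlacement:
    """Where one measured value falls on its stratum's percentile chart."""

    parameter: str
    value: float
    sex: str
    age_years: int
    percentile: float | None  # interpolated, in [3, 97]; None when off-chart
    category: str  # "on-chart" | "<3" | ">97"

    def __str__(self) -> str:
        if self.category == "on-chart":
            return (
                f"{self.parameter}={self.value:g} ({self.sex}, age {self.age_years}): "
                f"percentile {self.percentile:.1f}"
            )
        return (
            f"{self.parameter}={self.value:g} ({self.sex}, age {self.age_years}): "
            f"percentile {self.category}"
        )


class NormativeTable:
    """Percentile grid: (sex, age, parameter, percentile) -> reference value."""

    def __init__(self, frame: pd.DataFrame, n_per_stratum: dict | None = None):
        frame = frame.loc[:, _NORMATIVE_COLUMNS].copy()
        frame["age"] = frame["age"].astype(int)
        frame["percentile"] = frame["percentile"].astype(int)
        frame["value"] = frame["value"].astype(float)
        self._validate(frame)
        self._frame = frame.sort_values(_NORMATIVE_COLUMNS[:4]).reset_index(drop=True)
        self.n_per_stratum = dict(n_per_stratum or {})

    @staticmethod
    def _validate(frame: pd.DataFrame) -> None:
        if frame.duplicated(["sex", "age", "parameter", "percentile"]).any():
            raise NormativeTableError("duplicate (sex, age, parameter, percentile) cells")
        for (sex, age, param), grp in frame.groupby(["sex", "age", "parameter"]):
            pcts = sorted(grp["percentile"])
            if pcts != list(CHART_PERCENTILES):
                raise NormativeTableError(
                    f"stratum ({sex}, {age}, {param}) must carry exactly the "
                    f"percentiles {CHART_PERCENTILES}, got {pcts}"
                )
            vals = grp.sort_values("percentile")["value"].to_numpy()
            if np.any(np.diff(vals) < 0):
                raise NormativeTableError(
                    f"stratum ({sex}, {age}, {param}): values must be "
                    f"non-decreasing in percentile, got {vals.tolist()}"
                )

    @property
    def frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __len__(self) -> int:
        return len(self._frame)

    @property
    def strata(self) -> list[tuple[str, int, str]]:
        return sorted(
            self._frame.groupby(["sex", "age", "parameter"]).groups.keys()
        )

    def knots(self, sex: str, age: int, parameter: str) -> np.ndarray:
        """The seven (percentile, value) knots for one stratum, sorted."""
        grp = self._frame[
            (self._frame["sex"] == sex)
            & (self._frame["age"] == age)
            & (self._frame["parameter"] == parameter)
        ]
        if grp.empty:
            raise KeyError(
                f"no normative data for sex={sex}, age={age}, parameter={parameter}"
            )
        grp = grp.sort_values("percentile")
        return np.column_stack([grp["percentile"].to_numpy(float), grp["value"].to_numpy()])

    def to_csv(self, path: str | Path) -> None:
        self._frame.to_csv(path, index=False)


def load_normative(source: str | Path | None = None) -> NormativeTable:
    """Load a normative table from CSV; ``None`` loads the packaged default."""
    if source is None:
        ref = resources.files("posturemetrics.data") / "normative_sagittal_girls7.csv"
        with resources.as_file(ref) as p:
            frame = pd.read_csv(p)
        return NormativeTable(frame, n_per_stratum={("F", 7): 1083})
    try:
        frame = pd.read_csv(source)
    except pd.errors.EmptyDataError:
        frame = pd.DataFrame(columns=_NORMATIVE_COLUMNS)
    missing = [c for c in _NORMATIVE_COLUMNS if c not in frame.columns]
    if missing:
        raise NormativeTableError(f"{source}: missing columns {missing}")
    if frame.empty:
        return NormativeTable(frame.reindex(columns=_NORMATIVE_COLUMNS))
    return NormativeTable(frame)


def percentile_of(
    table: NormativeTable, sex: str, age: int, parameter: str, value: float
) -> PercentilePlacement:
    """Place a measured value on its stratum's percentile chart.

    Exact knot hits return the printed percentile; between knots the
    percentile is linearly interpolated; beyond the chart the category
    "<3" or ">97" is returned with ``percentile=None``.
    """
    knots = table.knots(sex, age, parameter)
    pcts, vals = knots[:, 0], knots[:, 1]
    if value < vals[0]:
        return PercentilePlacement(parameter, value, sex, age, None, "<3")
    if value > vals[-1]:
        return PercentilePlacement(parameter, value, sex, age, None, ">97")
    exact = np.nonzero(vals == value)[0]
    if exact.size:
        return PercentilePlacement(parameter, value, sex, age, float(pcts[exact[0]]), "on-chart")
    pct = float(np.interp(value, vals, pcts))
    return PercentilePlacement(parameter, value, sex, age, pct, "on-chart")


def build_percentile_table(
    cohort: Iterable[CohortRecord],
    percentiles: Sequence[int] = CHART_PERCENTILES,
    min_stratum_size: int = 20,
) -> NormativeTable:
    """Empirical percentile grid from cohort observations.

    Quantiles use linear interpolation of the empirical CDF. Strata with
    fewer than ``min_stratum_size`` subjects still enter the table but
    trigger a warning; empty strata are simply absent.
    """
    if sorted(percentiles) != list(CHART_PERCENTILES):
        raise ValueError(f"percentile grid must be {CHART_PERCENTILES}")
    df = pd.DataFrame(
        [(r.sex, r.age_years, r.parameter, r.subject_id, r.value) for r in cohort],
        columns=["sex", "age", "parameter", "subject", "value"],
    )
    if df.empty:
        return NormativeTable(pd.DataFrame(columns=_NORMATIVE_COLUMNS))
    rows = []
    counts: dict[tuple, int] = {}
    for (sex, age, param), grp in df.groupby(["sex", "age", "parameter"]):
        n = len(grp)
        counts[(sex, int(age), param)] = n
        if n < min_stratum_size:
            warnings.warn(
                f"stratum ({sex}, {age}, {param}) has only {n} observations "
                f"(floor {min_stratum_size}); percentiles will be unstable",
                stacklevel=2,
            )
        qs = np.percentile(grp["value"].to_numpy(), list(CHART_PERCENTILES))
        rows.extend(
            (sex, int(age), param, p, q) for p, q in zip(CHART_PERCENTILES, qs)
        )
    return NormativeTable(
        pd.DataFrame(rows, columns=_NORMATIVE_COLUMNS), n_per_stratum=counts
    )


def chart_series(table: NormativeTable, sex: str, parameter: str) -> pd.DataFrame:
    """Per-age percentile curves for charting: one column per percentile.

    Returns a DataFrame indexed by age with columns p3 ... p97 — the raw
    chart data, unsmoothed.
    """
    frame = table.frame
    sel = frame[(frame["sex"] == sex) & (frame["parameter"] == parameter)]
    if sel.empty:
        raise KeyError(f"no normative data for sex={sex}, parameter={parameter}")
    wide = sel.pivot(index="age", columns="percentile", values="value")
    wide.columns = [f"p{int(c)}" for c in wide.columns]
    return wide.sort_index()
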