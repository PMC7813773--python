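"""Monthly count panels: reading, validation, stratification, preprocessing.

A panel holds, per stratum (sex x age band, or prefecture), a contiguous
monthly series of death counts and population, plus a shared national
unemployment series.  The unemployment series carries one extra leading
month so the one-month lag exists for the first observation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

SEXES = ("male", "female", "total")
AGE_BANDS = (
    "<20",
    "20-29",
    "30-39",
    "40-49",
    "50-59",
    "60-69",
    "70-79",
    ">=80",
    "unknown",
    "all",
)

DEFAULT_SCHEMA = {
    "year": "year",
    "month": "month",
    "sex": "sex",
    "age_band": "age_band",
    "region": "region",
    "count": "count",
    "population": "population",
    "unemployment_rate": "unemployment_rate",
}


class PanelValidationError(ValueError):
    """A panel file or in-memory panel violates its contract."""


class GapError(PanelValidationError):
    """A stratum's months are not contiguous."""


class LagCoverageError(PanelValidationError):
    """Unemployment does not cover the month before the series start."""


@dataclass(frozen=True, order=True)
class MonthCoord:
    """A calendar month, totally ordered by (year, month)."""

    year: int
    month: int

    def __post_init__(self) -> None:
        if self.year < 1900:
            raise ValueError(f"year must be >= 1900, got {self.year}")
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")

    def successor(self) -> "MonthCoord":
        if self.month == 12:
            return MonthCoord(self.year + 1, 1)
        return MonthCoord(self.year, self.month + 1)

    def predecessor(self) -> "MonthCoord":
        if self.month == 1:
            return MonthCoord(self.year - 1, 12)
        return MonthCoord(self.year, self.month - 1)

    def add(self, n_months: int) -> "MonthCoord":
        total = self.year * 12 + (self.month - 1) + n_months
        return MonthCoord(total // 12, total % 12 + 1)

    def months_since(self, other: "MonthCoord") -> int:
        """Signed number of months from ``other`` to ``self``."""
        return (self.year - other.year) * 12 + (self.month - other.month)

    @classmethod
    def from_string(cls, s: str) -> "MonthCoord":
        """Parse ``YYYY-MM``."""
        year, month = s.split("-")
        return cls(int(year), int(month))

    def __str__(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"


def month_range(start: MonthCoord, n: int) -> list[MonthCoord]:
    return [start.add(i) for i in range(n)]


@dataclass(frozen=True, order=True)
class StratumKey:
    """Analysis cell: sex, age band, region (prefecture or 'national')."""

    sex: str = "total"
    age_band: str = "all"
    region: str = "national"

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.age_band not in AGE_BANDS:
            raise ValueError(
                f"age_band must be one of {AGE_BANDS}, got {self.age_band!r}"
            )

    def label(self) -> str:
        return f"{self.sex}_{self.age_band}_{self.region}"


@dataclass
class MonthlyCountSeries:
    """One stratum's contiguous monthly observations.

    ``unemployment`` has length ``n + 1``: entry 0 is the month *before*
    ``start`` (so the lagged covariate exists at t = 1), entry ``i + 1``
    aligns with ``counts[i]``.
    """

    start: MonthCoord
    counts: np.ndarray
    population: np.ndarray
    unemployment: np.ndarray

    def __post_init__(self) -> None:
        self.counts = _coerce_counts(np.asarray(self.counts))
        self.population = np.asarray(self.population, dtype=float)
        self.unemployment = np.asarray(self.unemployment, dtype=float)
        n = len(self.counts)
        if len(self.population) != n:
            raise PanelValidationError(
                f"population length {len(self.population)} != counts length {n}"
            )
        if len(self.unemployment) != n + 1:
            raise LagCoverageError(
                f"unemployment must have length n+1={n + 1} (one month before "
                f"start), got {len(self.unemployment)}"
            )
        if np.any(self.counts < 0):
            raise PanelValidationError("counts must be non-negative")
        if np.any(self.population <= 0):
            raise PanelValidationError("population must be strictly positive")
        if np.any((self.unemployment < 0) | (self.unemployment > 100)):
            raise PanelValidationError("unemployment must lie in [0, 100] percent")

    @property
    def n(self) -> int:
        return len(self.counts)

    @property
    def end(self) -> MonthCoord:
        return self.start.add(self.n - 1)

    def coords(self) -> list[MonthCoord]:
        return month_range(self.start, self.n)

    def position(self, coord: MonthCoord) -> int:
        """0-based array position of ``coord``; raises if outside the series."""
        pos = coord.months_since(self.start)
        if not 0 <= pos < self.n:
            raise KeyError(f"{coord} outside series {self.start}..{self.end}")
        return pos

    def t_index(self, coord: MonthCoord) -> int:
        """1-based time index t of ``coord`` within the series."""
        return self.position(coord) + 1

    def u_at(self, coord: MonthCoord) -> float:
        """Unemployment rate u_t for the month at ``coord``."""
        return float(self.unemployment[self.position(coord) + 1])

    def u_lag_at(self, coord: MonthCoord) -> float:
        """Lagged unemployment u_{t-1} for the month at ``coord``."""
        return float(self.unemployment[self.position(coord)])

    def window(self, start: MonthCoord, end: MonthCoord) -> "MonthlyCountSeries":
        """Contiguous sub-series from ``start`` to ``end`` inclusive."""
        i = self.position(start)
        j = self.position(end)
        if j < i:
            raise ValueError(f"window end {end} precedes start {start}")
        return MonthlyCountSeries(
            start=start,
            counts=self.counts[i : j + 1].copy(),
            population=self.population[i : j + 1].copy(),
            unemployment=self.unemployment[i : j + 2].copy(),
        )

    def equals(self, other: "MonthlyCountSeries") -> bool:
        return (
            self.start == other.start
            and np.array_equal(self.counts, other.counts)
            and np.allclose(self.population, other.population, rtol=0, atol=1e-9)
            and np.allclose(self.unemployment, other.unemployment, rtol=0, atol=1e-9)
        )


def _coerce_counts(arr: np.ndarray) -> np.ndarray:
    """Counts must be integers; reals within 1e-9 of an integer are coerced."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.int64)
    rounded = np.rint(arr)
    if np.any(np.abs(arr - rounded) > 1e-9):
        bad = arr[np.abs(arr - rounded) > 1e-9][0]
        raise PanelValidationError(f"counts must be integers, got {bad}")
    return rounded.astype(np.int64)


@dataclass
class PanelDataset:
    """Mapping from stratum to series, with the shared unemployment series."""

    series: dict[StratumKey, MonthlyCountSeries]
    unemployment: np.ndarray
    start: MonthCoord
    n_months: int
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.unemployment = np.asarray(self.unemployment, dtype=float)
        if len(self.unemployment) != self.n_months + 1:
            raise LagCoverageError(
                "panel unemployment must cover one month before start through "
                f"the end: expected length {self.n_months + 1}, "
                f"got {len(self.unemployment)}"
            )
        for key, s in self.series.items():
            if s.start != self.start or s.n != self.n_months:
                raise PanelValidationError(
                    f"stratum {key.label()} does not share the panel window "
                    f"({s.start}, n={s.n}) vs ({self.start}, n={self.n_months})"
                )

    @property
    def strata(self) -> list[StratumKey]:
        return sorted(self.series)

    def __getitem__(self, key: StratumKey) -> MonthlyCountSeries:
        return self.series[key]


def read_panel_csv(
    path: str | Path,
    unemployment_path: str | Path | None = None,
    schema: Mapping[str, str] | None = None,
) -> PanelDataset:
    """Read a monthly count panel from CSV.

    The main file has columns year, month, sex, age_band, region, count,
    population (names remappable via ``schema``).  The unemployment rate is
    taken from an ``unemployment_rate`` column in the same file or, if
    ``unemployment_path`` is given, from a companion CSV keyed by
    (year, month).  The unemployment series must extend one month before
    the first count month.
    """
    cols = dict(DEFAULT_SCHEMA)
    if schema:
        cols.update(schema)
    df = pd.read_csv(path)
    required = ["year", "month", "sex", "age_band", "region", "count", "population"]
    missing = [c for c in required if cols[c] not in df.columns]
    if missing:
        raise PanelValidationError(f"missing columns: {missing} in {path}")

    if unemployment_path is not None:
        udf = pd.read_csv(unemployment_path)
    elif cols["unemployment_rate"] in df.columns:
        udf = df[
            [cols["year"], cols["month"], cols["unemployment_rate"]]
        ].drop_duplicates()
    else:
        raise PanelValidationError(
            "unemployment_rate column absent and no companion file given"
        )
    u_map = {
        MonthCoord(int(r[cols["year"]]), int(r[cols["month"]])): float(
            r[cols["unemployment_rate"]]
        )
        for _, r in udf.iterrows()
    }

    grouped = df.groupby([cols["sex"], cols["age_band"], cols["region"]], sort=True)
    series: dict[StratumKey, MonthlyCountSeries] = {}
    start: MonthCoord | None = None
    n_months: int | None = None
    for (sex, age_band, region), g in grouped:
        g = g.sort_values([cols["year"], cols["month"]])
        coords = [
            MonthCoord(int(y), int(m))
            for y, m in zip(g[cols["year"]], g[cols["month"]])
        ]
        _check_contiguous(coords, f"{sex}/{age_band}/{region}")
        s0 = coords[0]
        needed = [s0.predecessor()] + coords
        try:
            u = np.array([u_map[c] for c in needed])
        except KeyError as e:
            raise LagCoverageError(
                f"unemployment series missing month {e.args[0]} "
                f"(must cover one month before the series start)"
            ) from None
        key = StratumKey(sex=str(sex), age_band=str(age_band), region=str(region))
        series[key] = MonthlyCountSeries(
            start=s0,
            counts=g[cols["count"]].to_numpy(),
            population=g[cols["population"]].to_numpy(dtype=float),
            unemployment=u,
        )
        start = s0 if start is None else start
        n_months = len(coords) if n_months is None else n_months

    if not series:
        raise PanelValidationError(f"no rows in {path}")
    assert start is not None and n_months is not None
    first = series[sorted(series)[0]]
    return PanelDataset(
        series=series,
        unemployment=first.unemployment,
        start=start,
        n_months=n_months,
        metadata={"source": str(path)},
    )


def _check_contiguous(coords: Sequence[MonthCoord], label: str) -> None:
    if not coords:
        raise PanelValidationError(f"empty stratum {label}")
    seen = set(coords)
    if len(seen) != len(coords):
        dup = next(c for c in coords if coords.count(c) > 1)
        raise PanelValidationError(f"duplicate month {dup} in stratum {label}")
    expected = coords[0]
    for c in coords:
        if c != expected:
            raise GapError(f"missing month {expected} in stratum {label}")
        expected = expected.successor()


def write_panel_csv(
    panel: PanelDataset,
    path: str | Path,
    unemployment_path: str | Path | None = None,
) -> None:
    """Write a panel in the same CSV dialect ``read_panel_csv`` accepts.

    If ``unemployment_path`` is given the covariate goes to a companion file
    (including the leading pre-start month); otherwise it is repeated as a
    column of the main file and the leading month is lost on round-trip
    unless a companion file is used — so the companion form is preferred.
    """
    rows = []
    for key in panel.strata:
        s = panel.series[key]
        for i, coord in enumerate(s.coords()):
            rows.append(
                {
                    "year": coord.year,
                    "month": coord.month,
                    "sex": key.sex,
                    "age_band": key.age_band,
                    "region": key.region,
                    "count": int(s.counts[i]),
                    "population": s.population[i],
                }
            )
    df = pd.DataFrame(rows)
    if unemployment_path is None:
        u_lookup = {
            c: panel.unemployment[i + 1]
            for i, c in enumerate(month_range(panel.start, panel.n_months))
        }
        df["unemployment_rate"] = [
            u_lookup[MonthCoord(int(r.year), int(r.month))] for r in df.itertuples()
        ]
        df.to_csv(path, index=False)
        return
    df.to_csv(path, index=False)
    u_coords = [panel.start.predecessor()] + month_range(panel.start, panel.n_months)
    udf = pd.DataFrame(
        {
            "year": [c.year for c in u_coords],
            "month": [c.month for c in u_coords],
            "unemployment_rate": panel.unemployment,
        }
    )
    udf.to_csv(unemployment_path, index=False)


def exclude_unknown_age(panel: PanelDataset) -> PanelDataset:
    """Drop unknown-age strata; all other series pass through unchanged."""
    kept = {k: v for k, v in panel.series.items() if k.age_band != "unknown"}
    if len(kept) == len(panel.series):
        return panel
    return dataclasses.replace(panel, series=kept)


def allocate_monthly_population(
    national_monthly_pop: Sequence[float],
    composition_ratios: Mapping[int, Mapping[str, float]],
    months: Sequence[MonthCoord],
    tol: float = 1e-9,
) -> dict[str, np.ndarray]:
    """Split a national monthly population across prefectures.

    Prefecture population at month t is the national population at t times
    that prefecture's composition ratio for the calendar year of t.  For
    each year the ratios must be positive and sum to 1 within ``tol``;
    summing the result over prefectures recovers the national series.
    """
    pop = np.asarray(national_monthly_pop, dtype=float)
    if len(pop) != len(months):
        raise ValueError(
            f"population length {len(pop)} != number of months {len(months)}"
        )
    years = sorted({c.year for c in months})
    for year in years:
        if year not in composition_ratios:
            raise PanelValidationError(f"composition ratios missing year {year}")
        ratios = composition_ratios[year]
        total = sum(ratios.values())
        if abs(total - 1.0) > tol:
            raise PanelValidationError(
                f"composition ratios for {year} sum to {total!r}, expected 1"
            )
        if any(r <= 0 for r in ratios.values()):
            raise PanelValidationError(f"non-positive ratio in year {year}")
    prefectures = sorted(composition_ratios[years[0]])
    for year in years:
        if sorted(composition_ratios[year]) != prefectures:
            raise PanelValidationError(
                f"prefecture set changes in year {year}; must be constant"
            )
    out = {
        pref: np.array(
            [pop[i] * composition_ratios[c.year][pref] for i, c in enumerate(months)]
        )
        for pref in prefectures
    }
    return out
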