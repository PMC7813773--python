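"""Excess mortality, relative difference, and interval-exceedance flags.

Excess mortality for a month is observed minus model-predicted deaths,
y - y_tilde; the relative difference is (y - y_tilde) / y_tilde expressed
in percent.  An observed count is flagged "below"/"above" only when it
lies strictly outside the prediction interval; a count equal to a bound
counts as "within" (the tie rule at the bound is a package convention —
flags in published tables mark only strict exceedances).  Rounding (one
decimal for predicted/excess/relative difference) is applied for display
only; comparisons always use unrounded values.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .panel_io import AGE_BANDS, SEXES, MonthCoord, StratumKey
from .predictive_sim import PredictionResult

FLAG_BELOW = "below"
FLAG_WITHIN = "within"
FLAG_ABOVE = "above"

TABLE_COLUMNS = [
    "sex",
    "age_band",
    "region",
    "year",
    "month",
    "population",
    "observed",
    "predicted",
    "pi_lower",
    "pi_upper",
    "excess",
    "relative_diff_pct",
    "flag",
]


@dataclass(frozen=True)
class ExcessRecord:
    stratum: StratumKey
    coord: MonthCoord
    observed: int
    predicted: float
    pi_lower: int
    pi_upper: int
    population: float = float("nan")

    @property
    def excess(self) -> float:
        return excess_mortality(self.observed, self.predicted)

    @property
    def relative_diff_pct(self) -> float:
        return relative_difference(self.observed, self.predicted)

    @property
    def flag(self) -> str:
        return classify_vs_interval(self.observed, self.pi_lower, self.pi_upper)


def excess_mortality(observed: int, predicted: float) -> float:
    """observed - predicted."""
    if predicted <= 0:
        raise ValueError(f"predicted must be positive, got {predicted}")
    return observed - predicted


def relative_difference(observed: int, predicted: float) -> float:
    """(observed - predicted) / predicted, in percent."""
    if predicted <= 0:
        raise ValueError(f"predicted must be positive, got {predicted}")
    return (observed - predicted) / predicted * 100.0


def classify_vs_interval(observed: int, pi_lower: int, pi_upper: int) -> str:
    """'below' / 'within' / 'above' with strict inequality at the bounds."""
    if pi_lower > pi_upper:
        raise ValueError(f"inverted interval ({pi_lower}, {pi_upper})")
    if observed < pi_lower:
        return FLAG_BELOW
    if observed > pi_upper:
        return FLAG_ABOVE
    return FLAG_WITHIN


def exceedance_beyond_bound(observed: int, pi_lower: int, pi_upper: int) -> int:
    """How far the observation lies outside the interval (0 if within)."""
    flag = classify_vs_interval(observed, pi_lower, pi_upper)
    if flag == FLAG_ABOVE:
        return observed - pi_upper
    if flag == FLAG_BELOW:
        return pi_lower - observed
    return 0


def records_from_prediction(
    stratum: StratumKey,
    observed: Sequence[int],
    populations: Sequence[float],
    prediction: PredictionResult,
) -> list[ExcessRecord]:
    """Pair observed held-out counts with a prediction result."""
    if len(observed) != len(prediction.coords):
        raise ValueError(
            f"{len(observed)} observations for {len(prediction.coords)} "
            "predicted months"
        )
    return [
        ExcessRecord(
            stratum=stratum,
            coord=coord,
            observed=int(observed[i]),
            predicted=float(prediction.predicted[i]),
            pi_lower=int(prediction.pi_lower[i]),
            pi_upper=int(prediction.pi_upper[i]),
            population=float(populations[i]),
        )
        for i, coord in enumerate(prediction.coords)
    ]


def _stratum_sort_key(key: StratumKey) -> tuple:
    sex_order = {s: i for i, s in enumerate(SEXES)}
    age_order = {a: i for i, a in enumerate(AGE_BANDS)}
    region_rank = (0, "") if key.region == "national" else (1, key.region)
    return (sex_order[key.sex], age_order[key.age_band], *region_rank)


def assemble_table(
    records: Iterable[ExcessRecord],
    strata: Sequence[StratumKey] | None = None,
    months: Sequence[MonthCoord] | None = None,
) -> pd.DataFrame:
    """One row per (stratum, month), deterministically ordered.

    When ``strata`` and ``months`` are given, every requested cell must be
    present.  Predicted, excess, and relative difference are rounded to
    one decimal for the table; the flag is computed from unrounded values.
    """
    recs = list(records)
    have = {(r.stratum, r.coord) for r in recs}
    if strata is not None and months is not None:
        for s in strata:
            for m in months:
                if (s, m) not in have:
                    raise ValueError(f"missing cell: stratum {s.label()}, month {m}")
    recs.sort(key=lambda r: (_stratum_sort_key(r.stratum), r.coord))
    rows = [
        {
            "sex": r.stratum.sex,
            "age_band": r.stratum.age_band,
            "region": r.stratum.region,
            "year": r.coord.year,
            "month": r.coord.month,
            "population": r.population,
            "observed": r.observed,
            "predicted": round(r.predicted, 1),
            "pi_lower": r.pi_lower,
            "pi_upper": r.pi_upper,
            "excess": round(r.excess, 1),
            "relative_diff_pct": round(r.relative_diff_pct, 1),
            "flag": r.flag,
        }
        for r in recs
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def write_table_csv(table: pd.DataFrame, path: str | Path) -> None:
    """Byte-stable CSV export (fixed float formatting)."""
    table.to_csv(path, index=False, float_format="%.1f")


def plot_series_with_interval(
    coords: Sequence[MonthCoord],
    observed: Sequence[int],
    prediction: PredictionResult,
    path: str | Path,
    title: str = "",
) -> None:
    """Basic export: observed line, dashed predictions, interval band."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 4))
    x_obs = [c.year + (c.month - 1) / 12 for c in coords]
    ax.plot(x_obs, observed, color="black", lw=1, label="observed")
    x_pred = [c.year + (c.month - 1) / 12 for c in prediction.coords]
    ax.plot(x_pred, prediction.predicted, "--", color="tab:blue", label="predicted")
    ax.fill_between(
        x_pred,
        prediction.pi_lower,
        prediction.pi_upper,
        color="gray",
        alpha=0.4,
        label=f"{prediction.level:.0%} PI",
    )
    ax.set_xlabel("year")
    ax.set_ylabel("deaths / month")
    if title:
        ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
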