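"""Counterfactual unemployment paths for prediction-time sensitivity checks.

The unemployment rate is itself disturbed during a crisis, so predictions
that feed it forward mix "normal-conditions" baselines with crisis-era
covariate movement.  The sensitivity analysis replaces the unemployment
rate with a fixed pre-crisis value (e.g. 2.4%, the February 2020 rate)
from a cutoff month onward and re-runs the prediction step only — the
fitted model is never retrained.  The lagged covariate of the cutoff
month still reads the actual prior-month value; only months at or after
the cutoff are substituted.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .excess_metrics import classify_vs_interval, records_from_prediction
from .glm_core import FitResult, prediction_rows
from .panel_io import MonthCoord, MonthlyCountSeries, StratumKey, month_range
from .predictive_sim import SimSettings, simulate_predictions


class OverrideMisuseError(ValueError):
    """Override would reach into the training window."""


@dataclass(frozen=True)
class CovariateOverride:
    """Replace unemployment with ``substitute_value`` (%) from ``cutoff`` on."""

    cutoff: MonthCoord
    substitute_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.substitute_value <= 100.0:
            raise ValueError(
                f"substitute_value must be a percentage in [0,100], "
                f"got {self.substitute_value}"
            )


def apply_override(
    series: MonthlyCountSeries, override: CovariateOverride
) -> MonthlyCountSeries:
    """Return a copy of the series with the unemployment path overridden.

    u_t = substitute for every month >= cutoff; earlier entries untouched,
    so the lag term of the cutoff month keeps the actual prior value.
    """
    pos = series.position(override.cutoff)  # raises if outside the series
    out = copy.deepcopy(series)
    out.unemployment = out.unemployment.copy()
    out.unemployment[pos + 1 :] = override.substitute_value
    return out


def sensitivity_report(
    series: MonthlyCountSeries,
    fit: FitResult,
    override: CovariateOverride,
    settings: SimSettings,
    prediction_window: tuple[MonthCoord, MonthCoord],
    training_end: MonthCoord,
    stratum: StratumKey | None = None,
) -> pd.DataFrame:
    """Paired actual-vs-counterfactual excess records with per-month deltas.

    Both arms share the fit (trained on unmodified pre-crisis data) and
    the same simulation seed, so differences reflect the covariate path
    alone.  Raises if the cutoff falls at or before the training end,
    which would mean the override should have leaked into training.
    """
    if override.cutoff.months_since(training_end) <= 0:
        raise OverrideMisuseError(
            f"override cutoff {override.cutoff} does not follow the training "
            f"end {training_end}; the counterfactual may only touch "
            "prediction-time covariates"
        )
    start, end = prediction_window
    coords = month_range(start, end.months_since(start) + 1)
    stratum = stratum if stratum is not None else StratumKey()

    cf_series = apply_override(series, override)
    frames = {}
    for arm, s in (("actual", series), ("counterfactual", cf_series)):
        X, offsets = prediction_rows(s, coords, fit.year_center)
        pred = simulate_predictions(fit, X, offsets, coords, settings)
        observed = [int(s.counts[s.position(c)]) for c in coords]
        pops = [float(s.population[s.position(c)]) for c in coords]
        recs = records_from_prediction(stratum, observed, pops, pred)
        frames[arm] = recs

    rows = []
    for r_a, r_c in zip(frames["actual"], frames["counterfactual"]):
        rows.append(
            {
                "sex": r_a.stratum.sex,
                "age_band": r_a.stratum.age_band,
                "region": r_a.stratum.region,
                "year": r_a.coord.year,
                "month": r_a.coord.month,
                "observed": r_a.observed,
                "predicted_actual": r_a.predicted,
                "predicted_cf": r_c.predicted,
                "delta_predicted": r_c.predicted - r_a.predicted,
                "excess_actual": r_a.excess,
                "excess_cf": r_c.excess,
                "delta_excess": r_c.excess - r_a.excess,
                "flag_actual": r_a.flag,
                "flag_cf": r_c.flag,
                "flag_changed": r_a.flag != r_c.flag,
            }
        )
    return pd.DataFrame(rows)
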