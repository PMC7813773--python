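"""End-to-end orchestration: load, stratify, fit, predict, tabulate.

Each selected stratum is fitted independently on the training window
(no pooling or shrinkage across strata), predictions are simulated for
the prediction window, and the results are assembled into one excess
table.  Output is deterministic under a fixed seed: per-stratum
simulation seeds are spawned from the master seed in sorted-stratum
order, and all files are written with fixed formatting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import excess_metrics, panel_io
from .excess_metrics import ExcessRecord, assemble_table, records_from_prediction, write_table_csv
from .glm_core import FitResult, ModelSpec, build_design, fit_quasipoisson, prediction_rows
from .panel_io import MonthCoord, PanelDataset, StratumKey, month_range, read_panel_csv
from .predictive_sim import PredictionResult, SimSettings, simulate_predictions
from .sensitivity import CovariateOverride, sensitivity_report


@dataclass
class RunConfig:
    panel_path: str | Path
    training_window: tuple[MonthCoord, MonthCoord]
    prediction_window: tuple[MonthCoord, MonthCoord]
    sim: SimSettings
    output_dir: str | Path
    unemployment_path: str | Path | None = None
    strata: list[StratumKey] | None = None  # None = all non-unknown strata
    override: CovariateOverride | None = None

    def __post_init__(self) -> None:
        train_end = self.training_window[1]
        pred_start = self.prediction_window[0]
        if pred_start.months_since(train_end) <= 0:
            raise ValueError(
                f"prediction window ({pred_start}) must follow the training "
                f"window end ({train_end}) with no overlap"
            )


@dataclass
class RunBundle:
    """In-memory results of one pipeline run, mirrored to the output dir."""

    table: pd.DataFrame
    fits: dict[StratumKey, FitResult]
    predictions: dict[StratumKey, PredictionResult]
    skipped: list[tuple[StratumKey, str]]
    log_lines: list[str]
    sensitivity: pd.DataFrame | None = None


def run_analysis(config: RunConfig) -> RunBundle:
    """Run the full analysis described by ``config`` and write the bundle.

    Writes excess_table.csv, predictions.csv, one fit JSON per stratum,
    run_log.txt, and (when an override is configured) sensitivity.csv to
    the output directory.  Per-stratum failures are logged and reported
    without aborting the rest of the run.
    """
    panel = read_panel_csv(config.panel_path, config.unemployment_path)
    panel = panel_io.exclude_unknown_age(panel)
    out_dir = Path(config.output_dir)
    (out_dir / "fits").mkdir(parents=True, exist_ok=True)

    strata = config.strata if config.strata is not None else panel.strata
    strata = sorted(strata)
    master = np.random.SeedSequence(config.sim.seed)
    stratum_seeds = {
        key: int(ss.generate_state(1)[0] % (2**31))
        for key, ss in zip(strata, master.spawn(len(strata)))
    }

    pred_start, pred_end = config.prediction_window
    pred_coords = month_range(pred_start, pred_end.months_since(pred_start) + 1)
    model_spec = ModelSpec(
        training_window=config.training_window,
        year_center=config.training_window[0].year,
    )

    log: list[str] = []
    fits: dict[StratumKey, FitResult] = {}
    predictions: dict[StratumKey, PredictionResult] = {}
    records: list[ExcessRecord] = []
    skipped: list[tuple[StratumKey, str]] = []
    sens_frames: list[pd.DataFrame] = []

    for key in strata:
        series = panel.series[key]
        if int(series.counts.sum()) == 0:
            msg = "all-zero counts; stratum skipped"
            log.append(f"WARNING {key.label()}: {msg}")
            skipped.append((key, msg))
            continue
        settings = SimSettings(
            seed=stratum_seeds[key],
            n_draws=config.sim.n_draws,
            level=config.sim.level,
        )
        try:
            design = build_design(series, model_spec)
            fit = fit_quasipoisson(design, model_spec)
            X_new, offs = prediction_rows(series, pred_coords, model_spec.year_center)
            pred = simulate_predictions(fit, X_new, offs, pred_coords, settings)
        except Exception as exc:  # keep going; report per stratum
            msg = f"{type(exc).__name__}: {exc}"
            log.append(f"ERROR {key.label()}: {msg}")
            skipped.append((key, msg))
            continue
        fits[key] = fit
        predictions[key] = pred
        observed = [int(series.counts[series.position(c)]) for c in pred_coords]
        pops = [float(series.population[series.position(c)]) for c in pred_coords]
        records.extend(records_from_prediction(key, observed, pops, pred))
        log.append(
            f"INFO {key.label()}: n={fit.n_obs} psi_hat={fit.dispersion_hat:.4f} "
            f"family={fit.family_used} iterations={fit.iterations} "
            f"seed={settings.seed}"
        )
        if config.override is not None:
            sens = sensitivity_report(
                series,
                fit,
                config.override,
                settings,
                config.prediction_window,
                config.training_window[1],
                stratum=key,
            )
            sens_frames.append(sens)

    table = assemble_table(records)
    write_table_csv(table, out_dir / "excess_table.csv")
    pred_frames = []
    for key in sorted(predictions):
        df = predictions[key].to_frame()
        df.insert(0, "stratum", key.label())
        pred_frames.append(df)
    if pred_frames:
        pd.concat(pred_frames, ignore_index=True).to_csv(
            out_dir / "predictions.csv", index=False, float_format="%.6f"
        )
    for key, fit in fits.items():
        fit.to_json(out_dir / "fits" / f"{key.label()}.json")
    sensitivity = None
    if sens_frames:
        sensitivity = pd.concat(sens_frames, ignore_index=True)
        sensitivity.to_csv(
            out_dir / "sensitivity.csv", index=False, float_format="%.6f"
        )
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    return RunBundle(
        table=table,
        fits=fits,
        predictions=predictions,
        skipped=skipped,
        log_lines=log,
        sensitivity=sensitivity,
    )
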