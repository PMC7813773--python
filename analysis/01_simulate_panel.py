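#!/usr/bin/env python
"""Generate the working synthetic panel: male and female national totals,
January 2013 - June 2020, with known generative truth.

Writes results/panel/{panel.csv,unemployment.csv,truth.csv}.
"""

from pathlib import Path

from exmort.panel_io import write_panel_csv
from exmort.synthetic_data import default_panel_configs, generate_panel, write_truth_csv

SEED = 20210205
OUT = Path(__file__).resolve().parents[1] / "results" / "panel"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    configs = default_panel_configs(SEED, n_months=90)
    panel, truths = generate_panel(configs, SEED)
    write_panel_csv(panel, OUT / "panel.csv", OUT / "unemployment.csv")
    write_truth_csv(truths, configs, OUT / "truth.csv")
    for key in panel.strata:
        counts = panel.series[key].counts
        print(
            f"{key.label()}: {panel.n_months} months, "
            f"counts {counts.min()}..{counts.max()} (mean {counts.mean():.0f})"
        )
    print(f"wrote panel to {OUT}")


if __name__ == "__main__":
    main()
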