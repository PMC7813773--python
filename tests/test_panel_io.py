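import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from exmort.panel_io import (
    GapError,
    LagCoverageError,
    MonthCoord,
    MonthlyCountSeries,
    PanelValidationError,
    StratumKey,
    allocate_monthly_population,
    exclude_unknown_age,
    month_range,
    read_panel_csv,
    write_panel_csv,
)
from exmort.synthetic_data import default_panel_configs, generate_panel

coords = st.builds(
    MonthCoord, st.integers(1900, 2100), st.integers(1, 12)
)


@given(coords)
def test_month_coord_successor_is_next_month(c):
    s = c.successor()
    assert s > c
    assert s.months_since(c) == 1
    assert s.predecessor() == c


@given(
    st.builds(MonthCoord, st.integers(2000, 2100), st.integers(1, 12)),
    st.integers(-500, 500),
)
def test_month_coord_add_roundtrip(c, n):
    assert c.add(n).months_since(c) == n


def test_month_coord_parse_and_str():
    assert MonthCoord.from_string("2015-02") == MonthCoord(2015, 2)
    assert str(MonthCoord(2015, 2)) == "2015-02"
    assert MonthCoord(2019, 12).successor() == MonthCoord(2020, 1)


def test_series_contiguity_of_coords():
    cs = month_range(MonthCoord(2019, 10), 6)
    for a, b in zip(cs, cs[1:]):
        assert b == a.successor()


def test_series_validation():
    with pytest.raises(PanelValidationError):
        MonthlyCountSeries(MonthCoord(2013, 1), [1, -2], [10.0, 10.0], [2, 2, 2])
    with pytest.raises(LagCoverageError):
        MonthlyCountSeries(MonthCoord(2013, 1), [1, 2], [10.0, 10.0], [2, 2])
    # reals within 1e-9 of an integer are coerced, others rejected
    s = MonthlyCountSeries(
        MonthCoord(2013, 1), [1.0 + 1e-12, 2.0], [10.0, 10.0], [2, 2, 2]
    )
    assert s.counts.dtype == np.int64
    with pytest.raises(PanelValidationError):
        MonthlyCountSeries(MonthCoord(2013, 1), [1.5, 2], [10.0, 10.0], [2, 2, 2])


def test_lag_accessors():
    s = MonthlyCountSeries(
        MonthCoord(2020, 1), [5, 6], [100.0, 100.0], [2.2, 2.4, 2.6]
    )
    assert s.u_at(MonthCoord(2020, 1)) == 2.4
    assert s.u_lag_at(MonthCoord(2020, 1)) == 2.2
    assert s.u_lag_at(MonthCoord(2020, 2)) == 2.4
    assert s.t_index(MonthCoord(2020, 1)) == 1


def test_round_trip_synthetic_panel(tmp_path):
    configs = default_panel_configs(seed=5, n_months=30)
    panel, _ = generate_panel(configs, seed=5)
    write_panel_csv(panel, tmp_path / "p.csv", tmp_path / "u.csv")
    back = read_panel_csv(tmp_path / "p.csv", tmp_path / "u.csv")
    assert back.start == panel.start and back.n_months == panel.n_months
    assert sorted(back.series) == sorted(panel.series)
    for key, s in panel.series.items():
        assert back.series[key].equals(s), key.label()


def test_missing_month_names_first_gap(tmp_path):
    configs = default_panel_configs(seed=5, n_months=36)
    panel, _ = generate_panel(configs, seed=5)
    write_panel_csv(panel, tmp_path / "p.csv", tmp_path / "u.csv")
    df = pd.read_csv(tmp_path / "p.csv")
    df = df[~((df.year == 2015) & (df.month == 2))]
    df.to_csv(tmp_path / "p.csv", index=False)
    with pytest.raises(GapError, match="2015-02"):
        read_panel_csv(tmp_path / "p.csv", tmp_path / "u.csv")


def test_unemployment_must_cover_leading_month(tmp_path):
    configs = default_panel_configs(seed=5, n_months=12)
    panel, _ = generate_panel(configs, seed=5)
    write_panel_csv(panel, tmp_path / "p.csv", tmp_path / "u.csv")
    udf = pd.read_csv(tmp_path / "u.csv").iloc[1:]  # drop Dec 2012
    udf.to_csv(tmp_path / "u.csv", index=False)
    with pytest.raises(LagCoverageError):
        read_panel_csv(tmp_path / "p.csv", tmp_path / "u.csv")


def _mini_panel(with_unknown=True):
    start = MonthCoord(2019, 1)
    u = np.full(5, 2.5)
    mk = lambda counts: MonthlyCountSeries(start, counts, [1e5] * 4, u)
    series = {
        StratumKey("male", "20-29", "national"): mk([5, 6, 7, 8]),
        StratumKey("male", "30-39", "national"): mk([4, 4, 4, 4]),
        StratumKey("male", "all", "national"): mk([12, 11, 13, 14]),
    }
    if with_unknown:
        series[StratumKey("male", "unknown", "national")] = mk([3, 1, 2, 2])
    from exmort.panel_io import PanelDataset

    return PanelDataset(series=series, unemployment=u, start=start, n_months=4)


def test_exclude_unknown_age_drops_only_unknown():
    panel = _mini_panel()
    out = exclude_unknown_age(panel)
    assert len(out.series) == 3
    assert all(k.age_band != "unknown" for k in out.series)
    # retained series pass through unchanged
    for k, s in out.series.items():
        assert s is panel.series[k]
    # sum over retained age strata never exceeds the sex total
    kept = [
        s.counts
        for k, s in out.series.items()
        if k.age_band not in ("unknown", "all")
    ]
    total = out.series[StratumKey("male", "all", "national")].counts
    assert np.all(np.sum(kept, axis=0) <= total)


def test_exclude_unknown_age_noop_when_absent():
    panel = _mini_panel(with_unknown=False)
    assert exclude_unknown_age(panel) is panel


class TestPopulationAllocation:
    months = month_range(MonthCoord(2018, 7), 18)  # spans 2018-2019

    def test_single_prefecture_identity(self):
        nat = np.linspace(100.0, 120.0, 18)
        out = allocate_monthly_population(
            nat, {2018: {"A": 1.0}, 2019: {"A": 1.0}}, self.months
        )
        np.testing.assert_allclose(out["A"], nat)

    def test_proportional_split(self):
        ratios = {y: {"A": 0.6, "B": 0.4} for y in (2018, 2019)}
        out = allocate_monthly_population([100.0] * 18, ratios, self.months)
        np.testing.assert_allclose(out["A"], 60.0)
        np.testing.assert_allclose(out["B"], 40.0)

    def test_47_prefecture_conservation(self, rng):
        prefs = [f"pref{i:02d}" for i in range(47)]
        ratios = {}
        for y in (2018, 2019):
            w = rng.dirichlet(np.ones(47))
            w = w / w.sum()
            ratios[y] = dict(zip(prefs, w))
        nat = rng.uniform(9e6, 1.1e7, size=18)
        out = allocate_monthly_population(nat, ratios, self.months)
        total = np.sum([out[p] for p in prefs], axis=0)
        np.testing.assert_allclose(total, nat, rtol=1e-9)

    def test_bad_ratios_rejected(self):
        with pytest.raises(PanelValidationError, match="sum"):
            allocate_monthly_population(
                [100.0] * 18,
                {y: {"A": 0.6, "B": 0.39} for y in (2018, 2019)},
                self.months,
            )
        with pytest.raises(PanelValidationError, match="2019"):
            allocate_monthly_population(
                [100.0] * 18, {2018: {"A": 1.0}}, self.months
            )
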