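import numpy as np
import pandas as pd
import pytest

from cloudprobit.data_model import (UK_BOUNDING_BOX, assemble_analysis_table,
                                    filter_cohort, follow_up_summary,
                                    haversine_km, link_exposures,
                                    read_scaling_meta, unscale_weather,
                                    write_scaling_meta)
from cloudprobit.exceptions import ConfigurationError, DataError


def _stations():
    return pd.DataFrame({
        "station_id": ["S001", "S002", "S003"],
        "latitude": [51.5, 53.5, 55.9],
        "longitude": [-0.1, -2.2, -3.2],
    })


def _obs(hours, station="S001", temp=None):
    ts = pd.Timestamp("2016-02-01") + pd.to_timedelta(hours, unit="h")
    n = len(hours)
    return pd.DataFrame({
        "station_id": station, "timestamp": ts,
        "temperature": temp if temp is not None else np.full(n, 8.0),
        "pressure": np.full(n, 1010.0), "relative_humidity": np.full(n, 80.0),
        "wind_speed": np.full(n, 4.0),
    })


class TestLinkExposures:
    def test_ping_at_station_coordinates_matches_it(self):
        st = _stations()
        pings = pd.DataFrame({
            "participant_id": ["P1"], "timestamp": [pd.Timestamp("2016-02-01 10:00")],
            "latitude": [53.5], "longitude": [-2.2]})
        obs = pd.concat([_obs([10], "S001"), _obs([10], "S002", temp=[12.0]),
                         _obs([10], "S003")])
        out = link_exposures(pings, st, obs)
        assert len(out) == 1
        assert out["mean_temperature"].iloc[0] == 12.0

    def test_daily_mean_is_arithmetic_mean(self):
        st = _stations().iloc[:1]
        pings = pd.DataFrame({
            "participant_id": "P1",
            "timestamp": pd.Timestamp("2016-02-01") + pd.to_timedelta([9, 12, 15], "h"),
            "latitude": 51.5, "longitude": -0.1})
        obs = _obs([9, 12, 15], temp=[10.0, 12.0, 14.0])
        out = link_exposures(pings, st, obs)
        assert out["mean_temperature"].iloc[0] == pytest.approx(12.0)
        assert out["n_hours_linked"].iloc[0] == 3

    def test_non_uk_ping_yields_no_exposure(self):
        """A day spent in Madrid contributes no linked hours."""
        st = _stations()
        pings = pd.DataFrame({
            "participant_id": ["P1"], "timestamp": [pd.Timestamp("2016-02-01 10:00")],
            "latitude": [40.4], "longitude": [-3.7]})
        obs = _obs([10])
        out = link_exposures(pings, st, obs)
        assert out.empty

    def test_nearest_matches_exhaustive_search(self):
        """Linkage equals a brute-force haversine loop over all stations."""
        rng = np.random.default_rng(4)
        n_st, n_pings = 12, 300
        st = pd.DataFrame({
            "station_id": [f"S{i:03d}" for i in range(n_st)],
            "latitude": rng.uniform(50, 58, n_st),
            "longitude": rng.uniform(-5, 1, n_st)})
        ts = pd.Timestamp("2016-02-01") + pd.to_timedelta(
            rng.integers(0, 48, n_pings), "h")
        pings = pd.DataFrame({
            "participant_id": rng.choice(["P1", "P2", "P3"], n_pings),
            "timestamp": ts,
            "latitude": rng.uniform(50.2, 57.8, n_pings),
            "longitude": rng.uniform(-4.8, 0.8, n_pings)})
        obs = pd.concat([
            pd.DataFrame({
                "station_id": s,
                "timestamp": pd.Timestamp("2016-02-01") + pd.to_timedelta(np.arange(48), "h"),
                "temperature": float(i),   # station index as tracer value
                "pressure": 1000.0, "relative_humidity": 70.0, "wind_speed": 3.0})
            for i, s in enumerate(st["station_id"])])
        out = link_exposures(pings, st, obs)

        # independent brute-force oracle, python loop
        import math
        def hav(lat1, lon1, lat2, lon2):
            p1, p2 = math.radians(lat1), math.radians(lat2)
            dl = math.radians(lon2 - lon1)
            dp = p2 - p1
            h = math.sin(dp / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dl / 2) ** 2
            return 2 * 6371.0 * math.asin(math.sqrt(h))

        expected = {}
        for _, ping in pings.iterrows():
            dists = [hav(ping.latitude, ping.longitude, r.latitude, r.longitude)
                     for r in st.itertuples()]
            j = int(np.argmin(dists))
            key = (ping.participant_id, pd.Timestamp(ping.timestamp).normalize())
            expected.setdefault(key, []).append(float(j))
        for _, row in out.iterrows():
            key = (row.participant_id, row.date)
            assert row.mean_temperature == pytest.approx(np.mean(expected[key]))
            assert row.n_hours_linked == len(expected[key])

    def test_empty_station_table_rejected(self):
        with pytest.raises(ConfigurationError):
            link_exposures(pd.DataFrame(columns=["participant_id", "timestamp",
                                                 "latitude", "longitude"]),
                           _stations().iloc[:0], _obs([1]))

    def test_invalid_coordinates_rejected_with_warning(self, caplog):
        st = _stations().iloc[:1]
        pings = pd.DataFrame({
            "participant_id": ["P1", "P1"],
            "timestamp": [pd.Timestamp("2016-02-01 09:00")] * 2,
            "latitude": [51.5, 95.0], "longitude": [-0.1, -0.1]})
        with caplog.at_level("WARNING"):
            out = link_exposures(pings, st, _obs([9]))
        assert "invalid coordinates" in caplog.text
        assert out["n_hours_linked"].sum() == 1

    def test_tie_broken_by_lowest_station_id(self):
        st = pd.DataFrame({"station_id": ["S9", "S1"], "latitude": [52.0, 52.0],
                           "longitude": [-1.0, -1.0]})
        pings = pd.DataFrame({
            "participant_id": ["P1"], "timestamp": [pd.Timestamp("2016-02-01 09:00")],
            "latitude": [52.0], "longitude": [-1.0]})
        obs = pd.concat([_obs([9], "S1", temp=[1.0]), _obs([9], "S9", temp=[9.0])])
        out = link_exposures(pings, st, obs)
        assert out["mean_temperature"].iloc[0] == 1.0


def _baselines(rows):
    df = pd.DataFrame(rows, columns=["participant_id", "consented",
                                     "baseline_complete"])
    df["age"] = 50.0
    df["sex"] = "female"
    df["belief"] = 7
    df["diagnoses"] = "osteoarthritis"
    return df


class TestFilterCohort:
    def _reports(self, spec):
        rows = []
        for pid, n in spec.items():
            for d in range(n):
                rows.append({"participant_id": pid,
                             "date": pd.Timestamp("2016-02-01") + pd.Timedelta(days=d),
                             "pain": 2, "mood": 3.0, "exercise": 3.0})
        return pd.DataFrame(rows)

    def test_two_day_minimum(self):
        base = _baselines([("P1", True, True), ("P2", True, True)])
        reports = self._reports({"P1": 1, "P2": 2})
        inc = filter_cohort(base, reports)
        assert list(inc) == ["P2"]

    def test_incomplete_baseline_excluded(self):
        base = _baselines([("P1", True, False)])
        reports = self._reports({"P1": 100})
        assert len(filter_cohort(base, reports)) == 0

    def test_no_consent_excluded(self):
        base = _baselines([("P1", False, True)])
        reports = self._reports({"P1": 10})
        assert len(filter_cohort(base, reports)) == 0

    def test_monotone_in_reports(self):
        base = _baselines([("P1", True, True), ("P2", True, True),
                           ("P3", False, True)])
        small = self._reports({"P1": 2, "P2": 1})
        bigger = self._reports({"P1": 4, "P2": 3, "P3": 9})
        inc_small = set(filter_cohort(base, small))
        inc_big = set(filter_cohort(base, bigger))
        assert inc_small <= inc_big


class TestAssemble:
    def _inputs(self):
        base = _baselines([("P1", True, True), ("P2", True, True)])
        dates = pd.Timestamp("2016-02-01") + pd.to_timedelta(np.arange(4), "D")
        reports = pd.DataFrame({
            "participant_id": ["P1"] * 4 + ["P2"] * 4,
            "date": np.tile(dates, 2),
            "pain": [2, 3, 2, 4, 1, 2, 3, 2],
            "mood": [3, 3, np.nan, 2, 4, 3, 3, 3],
            "exercise": [2.0] * 8,
        })
        exposures = pd.DataFrame({
            "participant_id": ["P1"] * 4 + ["P2"] * 4,
            "date": np.tile(dates, 2),
            "mean_temperature": np.arange(8, dtype=float),
            "mean_pressure": 1000 + np.arange(8, dtype=float),
            "mean_humidity": 70 + np.arange(8, dtype=float),
            "mean_wind": 2 + 0.5 * np.arange(8),
            "n_hours_linked": 24,
        })
        return base, reports, exposures

    def test_t_zero_on_first_report_day(self):
        base, reports, exposures = self._inputs()
        table, _ = assemble_analysis_table(base, reports, exposures)
        first = table.groupby("participant_id")["t"].min()
        assert (first == 0).all()

    def test_weather_columns_centered(self):
        base, reports, exposures = self._inputs()
        table, _ = assemble_analysis_table(base, reports, exposures)
        for col in ("x_temp", "x_press", "x_hum", "x_wind"):
            assert abs(table[col].mean()) < 1e-10

    def test_stated_scaling(self):
        """Raw humidity 75% against an analysis mean of 80% gives x = -0.5."""
        base, reports, exposures = self._inputs()
        exposures = exposures.copy()
        exposures["mean_humidity"] = [75.0] + [80.0 + 5.0 / 7] * 7  # mean 80
        table, meta = assemble_analysis_table(base, reports, exposures)
        # row for P1 day 0 was dropped? no: mood missing only on day 2
        row = table[(table.participant_id == "P1") & (table.t == 0)]
        assert meta["x_hum"]["divisor"] == 10.0
        # centering is at the mean of *kept* rows; recompute expectation
        kept_hum = exposures.merge(
            reports.dropna(subset=["mood"]), on=["participant_id", "date"])["mean_humidity"]
        expected = (75.0 - kept_hum.mean()) / 10.0
        assert row["x_hum"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_missing_mood_row_dropped(self):
        base, reports, exposures = self._inputs()
        table, _ = assemble_analysis_table(base, reports, exposures)
        assert len(table) == 7       # one NaN mood row dropped

    def test_unknown_participant_hard_error(self):
        base, reports, exposures = self._inputs()
        reports.loc[0, "participant_id"] = "GHOST"
        with pytest.raises(DataError, match="GHOST"):
            assemble_analysis_table(base, reports, exposures)

    def test_scaling_round_trip(self, tmp_path):
        base, reports, exposures = self._inputs()
        table, meta = assemble_analysis_table(base, reports, exposures)
        raw = unscale_weather(table, meta)
        merged = table.join(raw.drop(columns="participant_id"))
        kept = exposures.merge(
            reports.dropna(subset=["mood", "exercise"])[["participant_id", "date"]],
            on=["participant_id", "date"])
        for col in ("mean_temperature", "mean_pressure", "mean_humidity", "mean_wind"):
            assert np.allclose(np.sort(merged[col]), np.sort(kept[col]), atol=1e-9)
        # sidecar round-trips exactly
        write_scaling_meta(meta, tmp_path / "scaling.txt")
        meta2 = read_scaling_meta(tmp_path / "scaling.txt")
        assert meta2 == meta


class TestFollowUp:
    def test_definition(self):
        reports = pd.DataFrame({
            "participant_id": ["P1", "P1"],
            "date": [pd.Timestamp("2016-02-01"), pd.Timestamp("2016-02-10")],
            "pain": [2, 3]})
        out = follow_up_summary(reports)
        assert out["followup_days"].iloc[0] == 10
        assert out["compliance"].iloc[0] == pytest.approx(0.2)

    def test_single_report_degenerate(self):
        reports = pd.DataFrame({
            "participant_id": ["P1"], "date": [pd.Timestamp("2016-02-01")],
            "pain": [2]})
        out = follow_up_summary(reports)
        assert out["followup_days"].iloc[0] == 1
        assert out["compliance"].iloc[0] == 1.0
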