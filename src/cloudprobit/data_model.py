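"""Study data ingestion, exposure linkage, cohort filtering, table assembly.

Input tables (comma-separated, header row, ISO-8601 dates):

* ``baselines.csv`` — participant_id, age, sex, belief, diagnoses
  (semicolon-separated labels), consented, baseline_complete
* ``reports.csv`` — participant_id, date, pain, mood, exercise
* ``pings.csv`` — participant_id, timestamp, latitude, longitude
* ``stations.csv`` — station_id, latitude, longitude
* ``observations.csv`` — station_id, timestamp, temperature, pressure,
  relative_humidity, wind_speed

The analysis table holds one row per participant-day with both a pain
report and a linked daily exposure; weather columns are divided by fixed
unit divisors (1 degC, 10 mbar, 10 percentage points, 1 m/s) and centered
at the analysis-table mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0

#: lat/lon box used to drop days spent outside the UK (the study could not
#: link to non-UK weather stations); configurable because the rule, not the
#: box, is the study's statement.
UK_BOUNDING_BOX = (49.8, 60.9, -8.7, 1.8)   # lat_min, lat_max, lon_min, lon_max

#: raw-unit divisors giving the reporting units of the coefficient table
WEATHER_SCALING = {
    "mean_temperature": ("x_temp", 1.0),
    "mean_pressure": ("x_press", 10.0),
    "mean_humidity": ("x_hum", 10.0),
    "mean_wind": ("x_wind", 1.0),
}

DIAGNOSIS_LABELS = [
    "arthritis-unspecified", "osteoarthritis", "fibromyalgia/CWP",
    "rheumatoid-arthritis", "neuropathic", "chronic-headache",
    "ankylosing-spondylitis/spondyloarthropathy", "gout", "other/none",
]


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km (spherical Earth, radius 6371 km)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(v, dtype=float))
                              for v in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def link_exposures(pings: pd.DataFrame, stations: pd.DataFrame,
                   observations: pd.DataFrame,
                   bounding_box: tuple = UK_BOUNDING_BOX,
                   min_hours: int = 1) -> pd.DataFrame:
    """Link hourly locations to the nearest station and average per day.

    Each in-box ping is matched to the great-circle-nearest station (ties
    broken by lowest station_id); the matched station's observation for that
    hour contributes to the participant-day means.  Days with fewer than
    ``min_hours`` linked in-box hours are absent from the output.
    """
    if stations.empty:
        raise ConfigurationError("station table is empty")
    st = stations.sort_values("station_id", kind="mergesort").reset_index(drop=True)

    p = pings.copy()
    valid = (p["latitude"].between(-90, 90) & p["longitude"].between(-180, 180)
             & p["latitude"].notna() & p["longitude"].notna())
    if (~valid).any():
        logger.warning("rejecting %d pings with invalid coordinates", int((~valid).sum()))
        p = p[valid]

    lat_min, lat_max, lon_min, lon_max = bounding_box
    inbox = (p["latitude"].between(lat_min, lat_max)
             & p["longitude"].between(lon_min, lon_max))
    p = p[inbox]
    if p.empty:
        return _empty_exposures()

    # nearest station per ping (stations are few; full distance matrix)
    d = haversine_km(p["latitude"].to_numpy()[:, None], p["longitude"].to_numpy()[:, None],
                     st["latitude"].to_numpy()[None, :], st["longitude"].to_numpy()[None, :])
    nearest = d.argmin(axis=1)   # first minimum = lowest station_id (sorted)
    p = p.assign(station_id=st["station_id"].to_numpy()[nearest])

    obs = observations.copy()
    obs["timestamp"] = pd.to_datetime(obs["timestamp"])
    p["timestamp"] = pd.to_datetime(p["timestamp"])
    merged = p.merge(obs, on=["station_id", "timestamp"], how="inner")
    if merged.empty:
        return _empty_exposures()

    merged["date"] = merged["timestamp"].dt.normalize()
    g = merged.groupby(["participant_id", "date"], sort=True)
    out = g.agg(mean_temperature=("temperature", "mean"),
                mean_pressure=("pressure", "mean"),
                mean_humidity=("relative_humidity", "mean"),
                mean_wind=("wind_speed", "mean"),
                n_hours_linked=("temperature", "size")).reset_index()
    out = out[out["n_hours_linked"] >= min_hours].reset_index(drop=True)
    return out


def _empty_exposures() -> pd.DataFrame:
    return pd.DataFrame(columns=["participant_id", "date", "mean_temperature",
                                 "mean_pressure", "mean_humidity", "mean_wind",
                                 "n_hours_linked"])


def filter_cohort(baselines: pd.DataFrame, reports: pd.DataFrame) -> pd.Index:
    """Participants meeting all four inclusion criteria.

    (1) present in the baseline table (downloaded the app), (2) consented,
    (3) completed the baseline questionnaire, (4) contributed at least two
    distinct days of pain severity data.
    """
    eligible = baselines.loc[
        baselines["consented"].astype(bool) & baselines["baseline_complete"].astype(bool),
        "participant_id"]
    if reports.empty:
        return pd.Index([], name="participant_id")
    days = (reports.dropna(subset=["pain"])
            .groupby("participant_id")["date"].nunique())
    enough = days[days >= 2].index
    return pd.Index(sorted(set(eligible) & set(enough)), name="participant_id")


def assemble_analysis_table(baselines: pd.DataFrame, reports: pd.DataFrame,
                            exposures: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Build the model-ready analysis table (complete-case).

    One row per participant-day having both a pain report and a daily
    exposure; ``t`` counts days since the participant's first pain entry;
    weather columns are scaled by the fixed unit divisors and centered at
    the analysis-table mean; rows with missing mood or exercise are dropped.

    Returns ``(table, scaling_meta)`` where ``scaling_meta`` records, per
    weather column, the divisor and the subtracted mean (of the scaled
    values), enabling an exact round-trip to raw daily means.
    """
    rep = reports.copy()
    rep["date"] = pd.to_datetime(rep["date"])
    exp = exposures.copy()
    exp["date"] = pd.to_datetime(exp["date"])

    unknown = set(rep["participant_id"]) - set(baselines["participant_id"])
    if unknown:
        raise DataError(f"reports reference unknown participants: {sorted(unknown)[:5]}")

    first = rep.dropna(subset=["pain"]).groupby("participant_id")["date"].min()
    rep = rep.merge(first.rename("entry_date"), on="participant_id")
    rep["t"] = (rep["date"] - rep["entry_date"]).dt.days

    base_cols = baselines[["participant_id", "age", "sex", "belief"]].copy()
    base_cols["sex_indicator"] = (base_cols.pop("sex") == "female").astype(int)

    df = (rep.merge(exp, on=["participant_id", "date"], how="inner")
             .merge(base_cols, on="participant_id", how="left"))
    df = df.dropna(subset=["pain", "mood", "exercise"]).reset_index(drop=True)

    meta = {}
    for raw_col, (x_col, divisor) in WEATHER_SCALING.items():
        scaled = df[raw_col].to_numpy(dtype=float) / divisor
        center = float(scaled.mean()) if len(scaled) else 0.0
        df[x_col] = scaled - center
        meta[x_col] = {"divisor": divisor, "center": center, "raw_column": raw_col}

    df["y"] = df["pain"].astype(int)
    cols = ["participant_id", "date", "t", "y", "x_temp", "x_press", "x_hum", "x_wind",
            "mood", "exercise", "age", "sex_indicator", "belief"]
    return df[cols].sort_values(["participant_id", "t"]).reset_index(drop=True), meta


def unscale_weather(table: pd.DataFrame, meta: dict) -> pd.DataFrame:
    """Invert scaling/centering: recover raw daily means from x columns."""
    out = pd.DataFrame({"participant_id": table["participant_id"]})
    for x_col, m in meta.items():
        out[m["raw_column"]] = (table[x_col] + m["center"]) * m["divisor"]
    return out


def follow_up_summary(reports: pd.DataFrame) -> pd.DataFrame:
    """Per-participant follow-up days and reporting compliance.

    follow-up = last report date - first report date + 1;
    compliance = distinct report days / follow-up.
    """
    rep = reports.dropna(subset=["pain"]).copy()
    rep["date"] = pd.to_datetime(rep["date"])
    g = rep.groupby("participant_id")["date"]
    first, last, n = g.min(), g.max(), g.nunique()
    follow = (last - first).dt.days + 1
    return pd.DataFrame({
        "participant_id": follow.index,
        "followup_days": follow.to_numpy(),
        "n_reports": n.to_numpy(),
        "compliance": (n / follow).to_numpy(),
    }).reset_index(drop=True)


def write_scaling_meta(meta: dict, path) -> None:
    """Sidecar key-value text file with the exact scaling constants."""
    lines = []
    for x_col, m in meta.items():
        lines.append(f"{x_col}.divisor = {m['divisor']!r}")
        lines.append(f"{x_col}.center = {m['center']!r}")
        lines.append(f"{x_col}.raw_column = {m['raw_column']}")
    path.write_text("\n".join(lines) + "\n")


def read_scaling_meta(path) -> dict:
    meta: dict = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        key, val = [s.strip() for s in line.split("=", 1)]
        col, attr = key.split(".")
        meta.setdefault(col, {})[attr] = val if attr == "raw_column" else float(val)
    return meta
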