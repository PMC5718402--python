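"""CSV readers/writers and GeoJSON export.

Column dictionaries:

fixes.csv      animal_id, time (ISO UTC), lon, lat, lc
dives.csv      dive_id, animal_id, start_time, end_time, duration_s,
               max_depth_m, post_surface_s, t_0..t_5 (s), d_0..d_5 (m)
haulouts.csv   animal_id, start, end
ctd.csv        animal_id, time, lon, lat, depth_m, temp_C
"""

from __future__ import annotations

import json

import pandas as pd


def read_fixes_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["time"])
    df["lc"] = df.lc.astype(str)
    return df


def read_dives_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["start_time", "end_time"])


def read_haulouts_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["start", "end"])


def read_ctd_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, parse_dates=["time"])


def trips_to_geojson(points: pd.DataFrame) -> dict:
    """One LineString feature per trip from trip-labelled track points."""
    features = []
    for trip_id, tp in points.dropna(subset=["trip_id"]).groupby("trip_id"):
        tp = tp.sort_values("time")
        features.append({
            "type": "Feature",
            "properties": {"trip_id": trip_id,
                           "animal_id": tp.animal_id.iloc[0]},
            "geometry": {"type": "LineString",
                         "coordinates": [[round(lo, 6), round(la, 6)]
                                         for lo, la in zip(tp.lon, tp.lat)]},
        })
    return {"type": "FeatureCollection", "features": features}


def points_to_geojson(df: pd.DataFrame, properties=()) -> dict:
    """Point features (e.g. flagged foraging-day positions)."""
    features = []
    for r in df.itertuples():
        features.append({
            "type": "Feature",
            "properties": {p: getattr(r, p) for p in properties},
            "geometry": {"type": "Point",
                         "coordinates": [round(r.lon, 6), round(r.lat, 6)]},
        })
    return {"type": "FeatureCollection", "features": features}


def write_geojson(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, default=str)
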