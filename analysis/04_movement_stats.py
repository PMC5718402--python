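"""Trip-level movement statistics and diving behavior in foraging areas.

Reads the pipeline tables, computes per-trip azimuth/distance/duration
summaries, tests trip directionality (Rayleigh), compares movement and
diving parameters between age/sex classes (Wilcoxon-Mann-Whitney), and
reports depth use relative to bathymetry on high-FPT foraging days.
Writes results/stats/.
"""

import itertools
from pathlib import Path

import pandas as pd

from sealforage import movestats as ms

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "stats"


def main() -> None:
    pipe = BASE / "pipeline"
    points = pd.read_csv(pipe / "track.csv", parse_dates=["time"])
    trips = pd.read_csv(pipe / "trips.csv",
                        parse_dates=["start_time", "end_time"])
    OUT.mkdir(parents=True, exist_ok=True)

    summaries = ms.summarize_trips(points, trips)
    summaries.to_csv(OUT / "trip_summaries.csv", index=False)
    r_bar, p = ms.rayleigh_test(summaries.azimuth_deg)
    print(f"{len(summaries)} trips; Rayleigh R = {r_bar:.2f}, p = {p:.3g} "
          f"({'non-random' if p < 0.05 else 'random'} directionality)")

    rows = []
    for var in ("max_distance_km", "duration_days", "cos_azimuth",
                "sin_azimuth"):
        for a, b in itertools.combinations(
                sorted(summaries.animal_class.dropna().unique()), 2):
            va = summaries.loc[summaries.animal_class == a, var].dropna()
            vb = summaries.loc[summaries.animal_class == b, var].dropna()
            if len(va) and len(vb):
                u, pv = ms.group_compare(va, vb)
                rows.append({"parameter": var, "group_a": a, "group_b": b,
                             "U": u, "p": round(pv, 4)})
    comp = pd.DataFrame(rows)
    comp.to_csv(OUT / "class_comparisons.csv", index=False)
    print(comp.to_string(index=False))

    flags = pd.read_csv(pipe / "foraging_flags.csv", parse_dates=["day"])
    depth = pd.read_csv(pipe / "daily_depth.csv", parse_dates=["day"])
    env = pd.read_csv(pipe / "daily_env.csv", parse_dates=["day"])
    behav = ms.foraging_dive_behavior(depth, env, flags)
    behav.to_csv(OUT / "foraging_dive_behavior.csv", index=False)
    if len(behav):
        print(f"foraging days: median depth "
              f"{behav.mean_max_depth.median():.0f} m, median "
              f"depth/bathymetry {behav.depth_over_bathymetry.median():.2f}")
    print(f"wrote statistics to {OUT}")


if __name__ == "__main__":
    main()
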