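"""Fit the additive mixed habitat models to the daily foraging indexes.

Reads the DailyRecord table written by 02_run_pipeline, screens covariate
collinearity, fits every combination of bathymetry/SST smooths per foraging
index (class-specific smooths and random intercepts for animal and trip),
ranks them by AIC with the parsimony rule, and writes the selection table
and the selected models' smooth curves to results/models/.
"""

from pathlib import Path

import pandas as pd

from sealforage import habitat as hb

BASE = Path(__file__).resolve().parents[1] / "results"
OUT = BASE / "models"

RESPONSES = ["fpt_hr", "transit_index", "drift_change"]


def main() -> None:
    daily = pd.read_csv(BASE / "pipeline" / "daily_audit.csv",
                        parse_dates=["day"])
    daily = daily.rename(columns={"animal_class": "class"})
    ok, pairs = hb.check_collinearity(daily.dropna(
        subset=["bathymetry_m", "sst_C"]), ["bathymetry_m", "sst_C"])
    print("collinearity screen (|r| <= 0.8):", "pass" if ok else
          f"FAIL {pairs.to_dict('records')}")

    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for season, sdf in daily.groupby("season"):
        for resp in RESPONSES:
            df = sdf.dropna(subset=[resp, "bathymetry_m", "sst_C"]).copy()
            classes = df["class"].nunique()
            if len(df) < 40 or df.animal_id.nunique() < 2:
                print(f"{season}/{resp}: too few rows ({len(df)}); skipped")
                continue
            by_class = classes > 1
            specs = hb.enumerate_specs(resp, by_class=by_class,
                                       class_effect=by_class)
            fits = [hb.fit_gamm(df, s) for s in specs]
            best = hb.select_model(fits)
            rows.append({"season": season, "response": resp,
                         "model": best.spec.label(),
                         "n_params": best.n_params,
                         "aic": round(best.aic, 1),
                         "adjusted_r2": round(best.adjusted_r2, 2),
                         "n_days": len(df)})
            for term in best.spec.smooth_terms:
                for cls in (sorted(df["class"].unique()) if by_class
                            else [None]):
                    curve = best.smooth_curve(term, cls)
                    tag = f"{season}_{resp}_{term}" + (f"_{cls}" if cls else "")
                    curve.to_csv(OUT / f"smooth_{tag}.csv", index=False)
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "model_selection.csv", index=False)
    print(table.to_string(index=False))
    print(f"wrote model tables to {OUT}")


if __name__ == "__main__":
    main()
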