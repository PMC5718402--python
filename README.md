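# sealforage

Foraging-area inference from satellite relay data logger (SRDL) telemetry,
built for deep-diving pinnipeds such as hooded seals (*Cystophora
cristata*). The package implements three complementary per-day foraging
indexes and the full processing chain that connects raw Argos fixes,
compressed dive profiles and CTD casts to additive mixed habitat models —
exercised end to end on a synthetic SRDL generator with known ground truth,
so that every inference step can be validated as a recovery experiment.

## The three foraging indexes

1. **First passage time (FPT).** FPT(r) at a track point is the time the
   animal takes to cross a circle of radius *r* centred there. Tracks are
   resampled to equidistant 5-km points along the path, radii 5–100 km are
   scanned in 1-km steps, and the area-restricted-search (ARS) scale is the
   radius maximizing the variance of log FPT. Daily mean FPT at that scale
   is the horizontal search-effort index; days above the 75% quantile flag
   important foraging areas.

2. **Vertical transit-rate index.** Per dive, the descent rate
   (d₁−d₀)/(t₁−t₀) and ascent rate −(d₅−d₄)/(t₅−t₄) are standardized and
   combined by PCA; the axis-1 score is a "foraging intensity" per dive.
   Because lung air dominates buoyancy above ~100 m, each score is
   multiplied by a weight w(d) = (d/100)² for mean transit depth d < 100 m
   and w = 1 at or below 100 m, then averaged per animal-day.

3. **Drift-rate change (body condition).** During drift dives the animal
   drifts passively at a rate set by its buoyancy (negative = sinking =
   lean). Candidate passive segments are screened from the 6-point
   profiles, scored by a random-forest classifier, isolated positive-rate
   segments are excluded, and per trip a weighted constrained smoothing
   spline (weights = depth weight × classifier probability) yields daily
   drift rates; their first difference is the daily body-condition change.

Habitat models: each daily index is modelled per season against
standardized bathymetry and SST with class-specific spline smooths and
random intercepts for animal and trip; all smooth-term combinations are
ranked by AIC (candidates within ΔAIC < 2; fewest parameters wins).

## Worked example

The numbered drivers under `analysis/` run the whole study on a seeded
6-animal, 60-day simulation and write their tables under `results/`:

```bash
python analysis/01_simulate.py        # raw synthetic SRDL bundle
python analysis/02_run_pipeline.py    # cleaning + the three indexes
python analysis/03_habitat_models.py  # GAMM selection tables
python analysis/04_movement_stats.py  # trip statistics
```

`02_run_pipeline.py` prints, for seed 1:

```
SDA filter kept 3351/4326 fixes (77.5%)
trips: 18 (12 complete)
common ARS scale: 40 km (log-FPT variance maximum)
transit PCA axis 1 explains 79% of rate variance
foraging days (FPT > 75% quantile): 62/247
drift splines fitted on 18 trips; daily change range [-0.025, +0.013] m/s per day
DailyRecord table: 247 complete animal-days (audit: 354)
```

The SDA filter drops invalid location-class-Z fixes and speed/angle
artifacts (the generator injects both); the 40-km ARS scale recovers the
30-km patches built into the simulation to within the resolution the
variance curve supports; the drift-rate change stays inside the ±0.05 m/s
per day envelope typical of free-ranging seals. `03_habitat_models.py`
then prints an AIC selection table, one row per foraging index, e.g.

```
       season      response                                              model  n_params     aic  adjusted_r2  n_days
post_breeding        fpt_hr 1+s(bathymetry_m,by=class)+s(sst_C,by=class)+class        30  1789.6         0.93     247
```

The same machinery is available as a CLI (`sealforage simulate`,
`sealforage all`, …) and as plain library calls
(`sealforage.pipeline.run_pipeline`).

## Layout

```
src/sealforage/    library: synthetic, tracks, dives, fpt, transit, drift,
                   envgrid, habitat, movestats, pipeline, cli
analysis/          numbered narrative drivers writing results/
tests/             pytest suite incl. the validation experiments
docs/methods.md    model and design notes
```
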