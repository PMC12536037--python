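# pmexposure

Personal PM2.5 exposure assessment from wearable low-cost optical sensors
and GPS.

Epidemiological studies usually assign each person the ambient PM2.5
concentration interpolated at their home address. That misses what people
actually breathe: most time is spent indoors, where infiltration, cooking,
and heating decouple exposure from the outdoor background, and the rest is
spent moving through offices, shops, parks, and vehicles. This package
implements the full assessment pipeline for minute-resolution personal
monitoring of the kind produced by wearable particle counters with an
on-board GPS receiver, for exposure scientists who want microenvironment-
resolved exposures rather than a single home-address surrogate:

1. **Pre-processing** — record-level filters (missing timestamp/id/channels)
   and removal of participants whose sensor reported all-zero channels for
   more than 99% of their monitoring time, with a stage-accounting ledger.
2. **Context identification** — moving-median GPS smoothing, gap
   imputation, trajectory clustering into stay points and trips (temporally
   contiguous runs that remain within an `eps` radius of the running
   cluster centroid for a minimum duration), nearest land-use assignment
   over seven classes plus `other`, a 10-m building buffer for the
   indoor/outdoor flag, and speed-based vehicle/walking trip
   classification; vehicle minutes count as indoor.
3. **In-situ calibration** — hourly means of outdoor-labelled sensor
   minutes are paired with the nearest regulatory station within a cut-off
   distance; a linear mixed model `reference ~ raw + RH + temperature +
   (1 | participant)` is fitted by REML at each cut-off on a grid and the
   R²-maximising cut-off is kept. Calibrated exposure uses the fixed
   effects only.
4. **Exposure assessment** — distributional summaries, per-microenvironment
   time budgets, inhaled-dose apportionment (dose = concentration ×
   breathing rate × time, so dose shares are breathing-rate invariant), and
   a home-address alternative reconstructed by inverse-distance-weighted
   (IDW) interpolation of the station network, compared with the personal
   series at minute and hour scales and as participant-level
   personal/outdoor (P/O) ratios.
5. **Inference** — the exposure mixed model

   ```
   PM2.5 ~ Landuse + IO * PM2.5_IDW + Season + Hour
           + Age + Sex + Marital + Race + Edu + Income + (1 | participant)
   ```

   fitted by REML with profile-likelihood 95% CIs, Benjamini–Hochberg
   adjustment over the non-intercept fixed effects, estimated marginal
   means (EMMs) per factor level, the indoor-stratum background slope
   (main effect + interaction), an intraclass correlation coefficient from
   an intercept-only random-intercept model, Wilcoxon/Kruskal–Wallis
   subgroup tests with Bonferroni post-hocs (exact permutation enumeration
   at pooled n ≤ 10), land-use Shannon entropy, and nested-model plus
   leave-one-group-out sensitivity analyses.

Because monitoring campaigns of this kind rarely release raw data, the
package ships a first-class synthetic study generator
(`pmexposure.synthetic`) that emits a landscape (land-use parcels, building
footprints, station network), ground-truth activity schedules, ambient and
indoor pollution fields with winter/evening maxima, and sensor streams with
a known linear distortion, GPS noise, and gaps — so every stage can be
validated against ground truth.

## Worked example

The numbered scripts under `analysis/` run a desk-scale synthetic study
(10 participants × 7 days at 1-min resolution) through the whole chain:

```sh
python analysis/01_simulate.py
python analysis/02_context.py
python analysis/03_calibrate.py
python analysis/04_exposure.py
python analysis/05_inference.py
```

Output (abridged) from a run of scripts 02–04:

```
minute-level (microenvironment, indoor) accuracy vs ground truth: 99.91 % under 10-m GPS noise and 2% gaps
selected cut-off: 3.0 km (R2 = 0.994, RMSE = 0.18 ug/m3, n = 285)
fitted slope on raw = 0.511 (generator truth 0.5); intercept = 3.95
overall exposure: 6.8 +/- 6.6 ug/m3 (median 5.1, n = 100,800 minutes)
indoor: 78 % of time, 80 % of inhaled dose (total dose 8249 ug over the week)
residential dose share: 73 %
personal vs home-IDW: r = 0.44 (minute), 0.46 (hour); P/O median 0.91 (IQR 0.87-1.00)
```

Reading this: context identification recovered the true microenvironment
and indoor flag for 99.9% of GPS-bearing minutes despite the injected
noise; the calibration scan recovered the generator's sensor distortion
(slope 0.5) from opportunistic outdoor collocation alone; indoor
environments held 78% of time and 80% of inhaled dose; and the home-address
IDW surrogate correlates only moderately with what the cohort actually
breathed — the package's core point.

The same stages are available as a CLI
(`pmexposure simulate|preprocess|context|calibrate|assess|infer|run`), e.g.

```sh
pmexposure simulate --seed 7 --out scratch/study
pmexposure run --data-dir scratch/study --out scratch/out --seed 7
```

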