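# circagest

Circadian analysis of behaviour change during mouse pregnancy, built for
metabolic-cage (Promethion-style) phenotyping data: food intake, water
intake, cage activity and wakefulness recorded around the clock under a
12:12 light–dark cycle (ZT0 = lights-on, dark phase ZT12–ZT24).

The package is organised as an analysis project: every computational step
lives in the library under `src/circagest/`, and the numbered scripts under
`analysis/` drive the study end-to-end (simulate → preprocess → onset →
fit → peaks → report).

## What it computes

**Preprocessing.** Raw per-interval records are filtered (food events
< 0.002 g excluded), sleep is scored as stillness runs ≥ 40 s, values are
aggregated into 5-min blocks and then per-mouse hourly series, and study
days are grouped into three blocks (days 0.5–6.5, 6.5–12.5, 12.5–17.5 —
thirds of mouse gestation).

**Activity onset.** Each mouse's threshold is its mean dark-phase 5-min
activity over the 7-day acclimation period; onset on a night is the start
of the first run of three consecutive 5-min blocks strictly above
threshold, censored at 12 h. Group differences per study night come from a
linear mixed model, `onset ~ pregnancy × night` with a random intercept
per mouse.

**Circadian curves.** Each behaviour is modelled with a Bayesian
multilevel natural-spline regression: 13 knots evenly spaced ZT8.5–ZT4.5
(next day) on the unwrapped ZT6→ZT30 axis, in full interaction with
pregnancy group and study block, nested random intercepts (study block
within mouse), and each mouse's acclimation-period baseline profile as a
covariate. Food, water and activity are fitted on the square-root scale
with Gaussian errors and back-transformed as `mean² + variance`;
wakefulness (a fraction of each 5-min block) uses a beta likelihood with
logit link. Samplers are written in-package: a conjugate Gibbs sampler for
the Gaussian family and an adaptive Metropolis-within-Gibbs sampler (with
exact interweaving moves) for the beta family; the reference setting is
3 chains × 10,000 iterations, half burn-in, thinned by 4 (3,750 draws).

**Peak inference.** For every posterior draw, local maxima of the fitted
group × block curve are detected inside five windows — I ZT8–12, II
ZT12–15, III ZT15–18, IV ZT18–24, V ZT24–28 (= ZT0–4) — and summarised as
presence (% of draws), peak time and amplitude with 2.5/97.5% quantiles,
and pregnant − non-pregnant differences computed per draw where both
groups show a peak. A difference is significant when its 95% credible
interval excludes zero.

**Synthetic cohort.** `circagest.cohort` generates raw records for a
virtual cohort (12 non-pregnant + 31 pregnant mice, staged terminations at
days 6.5/12.5/17.5) from smooth ground-truth profiles with known pregnancy
effects, plus a truth table for parameter-recovery testing.

## Worked example

```bash
python analysis/01_simulate_cohort.py --seed 1 --out results
python analysis/02_preprocess.py      --results results
python analysis/03_onset_analysis.py  --results results
python analysis/04_fit_circadian_models.py --results results --seed 1 --behaviours food
python analysis/05_peak_inference.py  --results results
python analysis/06_report.py          --results results
```

prints, among other things:

```
acclimation: 100.0% of mouse-nights reach onset within 2 h of lights-off; 100% of mice on >=1 night
pregnant onset delay: 1.83 h on night 1 -> 5.95 h on night 17 (interaction p = 0.00e+00)
food: 500 draws/cell, max split-R-hat 1.021
late-light food peak, mid-pregnancy: delay 1.68 h [1.50, 1.85], amplitude diff 0.087 g/h
```

Read: onset detection behaves as validated cage data should during
acclimation; pregnant mice take progressively longer to start moving after
lights-off (≈1.8 h on gestational day 1, ≈6 h by day 17); and in
mid-pregnancy the late-light (ZT8–12) food-intake peak is delayed by
≈1.7 h and raised by ≈0.09 g/h relative to non-pregnant controls — the
credible intervals exclude zero. `results/` also holds the per-behaviour
fitted-curve CSVs, peak tables shaped like the study's summary tables, and
raw-vs-fitted overlay figures per study block.

The same pipeline runs on real exports via
`circagest all OUTDIR --seed N --input-csv records.csv` (CSV columns
`mouse_id,group,day,zt_hour,behaviour,value`).

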