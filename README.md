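# mobilesense

Digital-phenotyping analysis pipeline for youth mental health: turns
passively collected smartphone sensor streams into daily behavioral
features and tests their association with self-reported internalizing
symptoms (anxiety and depression).

## Who this is for

Researchers running 14-day passive-sensing studies in which participants'
phones log four event streams — GPS fixes (emitted whenever displacement
exceeds 20 m), call events, screen on/off events, and ambient-light
samples — alongside baseline self-report instruments (SCARED, CES-DC,
ASRS). The package covers the full analysis path from raw CSV streams to a
covariate-adjusted association report, and ships a synthetic-cohort
generator with planted symptom–behavior couplings so the entire pipeline
is testable without access to any participant data.

## What it computes

**Daily features** (11 per participant-day):

- *Mobility* — total distance traveled (Haversine, km/day); hours
  classified stationary (1 location/h), moving (2–9), or transportation
  (≥10 locations visited ≥2 min within the hour); and normalized location
  entropy over 150 m greedy location clusters,

  H = −Σᵢ pᵢ ln pᵢ / ln N,

  where pᵢ is the share of dwell time in cluster i of N. H = 0 when all
  dwell sits in one cluster, H = 1 when dwell is uniform across clusters,
  independent of N.
- *Social interaction* — connected/incoming/outgoing call counts and total
  call duration per day (a call is connected when incoming or outgoing
  with positive duration; missed calls counted separately).
- *Phone use* — unlock count and total screen time per day from paired
  on/off events (with deterministic repair of duplicated/unpaired events).
- *Sleep proxy* — time-weighted mean ambient light and minutes below/above
  configurable lux thresholds in the 11 PM–7 AM window.

**Instrument scoring** — SCARED (33 items, 0–2, sum), CES-DC (20 items,
0–3, four reverse-keyed items), ASRS (18 items, 0–4, dimensional sum),
with mean imputation when ≥80% of items are answered.

**Association analysis** — per-participant feature means over non-missing
days; Tukey far-out-fence (3×IQR) extreme-outlier exclusion per sensor
domain; partial Spearman correlations adjusted for age, sex, maternal
education, OS, assessment month and comorbid symptom scores; nested OLS
F tests of whether sensor features improve covariate-only prediction; and
discriminant validity of model-predicted scores against the other
instruments.

## Worked example

```bash
mobilesense simulate --out demo --n 40 --seed 7
mobilesense run --out demo_run --input-dir demo --seed 7
```

The run prints the retention flow (`40 enrolled, 29 retained, exclusions
{'withdrew': 2, 'insufficient_days': 9, 'missing_sensors': 0}`) and writes
`associations.csv`, `model_comparison.csv`, `discriminant.csv` and a
Markdown report. With this seed the report's descriptives include

| Feature | Mean | SD |
|---|---|---|
| time_sedentary_h | 20.98 | 1.16 |
| distance_km | 6.46 | 2.85 |
| entropy_norm | 0.22 | 0.07 |
| n_outgoing | 2.07 | 1.07 |
| screen_time_min | 185.81 | 80.38 |

i.e. a cohort that is sedentary ~21 h/day, travels ~6.5 km/day and makes
~2 outgoing calls/day, and the nested-model rows
`SCARED F=3.418 (df 9, 4)` / `CESDC F=4.365 (df 9, 4)` — at this toy
cohort size the F test has almost no residual degrees of freedom, which is
why the demo is a smoke test and the statistical suites run at n = 300.

The same stages are available as library calls (`simulate_cohort`,
`analyze_cohort`, `run_pipeline`) and as per-stage subcommands
(`simulate | features | score | analyze | report | run`).

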