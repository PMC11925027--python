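# Methods

## Model structure

The forecast is a patient-level Monte Carlo simulation with two event types
in competition: structural degeneration of a bioprosthetic aortic valve, and
death of the patient carrying it. The simulation seeds every annual cohort
of index procedures over 1998–2035 for two procedure classes — native TAVR
and bioprosthetic surgical AVR — and follows each patient forward:

1. draw age at index, risk class, durability `D`, survival `S`;
2. the patient is a ViV candidate iff `D < S` (strict; a tie counts as
   death first) — otherwise they leave the model;
3. the failure is assigned to calendar year `index_year + floor(D)`
   (the failure occurs *within* that year; a `half_up` rounding variant is
   available as `failure_year_rounding` for sensitivity runs);
4. per failure year and failure type, surgical redo counts are subtracted
   from the candidate pool (clamped at zero), then each remaining candidate
   is independently treated with the year's penetration probability;
5. treated counts accumulate into TAVR-in-TAVR (failed TAVR) and
   TAVR-in-SAVR (failed surgical valve); failures beyond the horizon are
   discarded, and treated patients are never re-seeded (no third
   interventions).

The ensemble repeats this `n_replicates` = 20 times and reports per-year
sample means and SDs (n−1 denominator; a single-replicate ensemble reports
SD 0 by convention).

## Default parameters

| Parameter | Default | Notes |
|---|---|---|
| Horizon | 1998–2035 | 1998 is the earliest seeded SAVR cohort |
| TAVR durability | 0.2·N(4, 1.5²) + 0.8·N(11.5, 3.5²) years | bimodal: early vs. late structural failure |
| SAVR durability | N(10, 5²) if age < 70; N(17, 5²) if age ≥ 70 | strict inequality at 70 |
| Survival, intermediate-high risk | truncated normal, median 6 y, SD 2 | mean = median by symmetry |
| Survival, low risk | truncated normal, median 12 y, SD 4 | **package assumption** (no published values) |
| Age at index | discretized normal, mean 77, SD 7, support 60–95 | **package assumption**; swap via `age_model` |
| Risk mix, SAVR | 85% low / 15% intermediate-high | all years |
| Risk mix, TAVR | 0% low <2019; 1/3 2019–2024; 1/2 2024–2035 | half-open eras `[2014,2019)`, `[2019,2024)`, `[2024,2035]`; pre-2014 treated like 2014–2019 |
| Penetration, TAVR failure | 10% through 2022 → 60% in 2035 | linear between anchors, flat outside |
| Penetration, SAVR failure | 60% through 2022 → 80% in 2035 | idem |
| Redo series | SAVR-after-SAVR 3,000/yr; SAVR-after-TAVR 100→2,000 (2015→2030), flat after | **package assumption** |
| Max attained age | 100 | survival capped at `100 − age`; the minimal age dependence of survival |
| Replicates / seed | 20 / 20240710 | |

Volume inputs: the TAVR series is OLS-extrapolated from the shipped
registry-summary values 2012–2022 (fit window: most recent six observed
years, honouring the unsaturated-market reading; back-extrapolation to 2007
clamps at zero, which is historically right — TAVR was not commercially
available), reaching ≈ 217,000 native implants in 2035. The SAVR series uses
literature values 1998–2011, 80% of total surgical AVR 2012–2020, and a
constant 50,000/yr from 2021. All shipped values are approximations from
public annual-report summaries (see the CSV headers in
`src/vivforecast/data/`); registry exports can be substituted through the
config without touching code.

## Distribution families and numerical choices

- *Truncation.* Durability and survival are normals truncated to (0, ∞) by
  rejection, applied **within** the selected mixture component (component
  first, then truncation), so component frequencies match the configured
  weights exactly pre-truncation. The truncation shift is tiny for the
  default parameters (largest for N(10, 5²): mean +0.28 y) and the test
  suite compares against independently computed truncated CDFs rather than
  the untruncated moments.
- *Point masses.* A component or survival law with SD 0 is an exact point
  mass. This degenerate limit exists so that fully deterministic scenarios
  can be checked against a brute-force enumeration; the type invariants
  therefore require SD ≥ 0 (not > 0) with strictly positive means.
- *Penetration thinning* is per-candidate Bernoulli (uniforms compared to
  the year's fraction), not a deterministic rounding of expectations, so the
  replicate-to-replicate SD is a meaningful Monte Carlo dispersion. Using
  explicit uniforms (one per candidate, count independent of the schedule)
  also makes treated counts exactly monotone in the schedule under common
  random numbers — a property the test suite asserts.
- *Order of exclusions.* Redo subtraction precedes penetration (redo
  patients leave the pool before the treatment decision); the opposite order
  is available as `redo_before_penetration: false` for sensitivity analysis.
- *Untreated candidates do not queue*: a failed valve not treated in its
  failure year leaves the model.
- *RNG.* Each (replicate, procedure class, seeding year) cohort and each
  (replicate, failure type) thinning pass owns an independent
  `numpy.random.SeedSequence` substream keyed by those integers, so growing
  the horizon or ensemble never perturbs existing streams; replicate seeds
  derive from the master seed via `SeedSequence.generate_state`. Identical
  config + master seed ⇒ byte-identical `forecast.csv`.
- *Counts are integers*; fractional extrapolated volumes round half-to-even
  and clamp at zero.

## Headline definitions

- *ViV share of all TAVR* in year *y* = mean total ViV / (native TAVR +
  mean total ViV). The configured TAVR series is interpreted as native
  implants only (seeding ViV output back in would double-count);
  `tavr_series_includes_viv: true` switches the denominator for series that
  already contain ViV.
- *Crossover year* = first year with mean TAVR-in-TAVR ≥ 0.9 × mean
  TAVR-in-SAVR ("nearly match"); the strict 1.0 threshold is reported
  alongside. Years with zero mean TAVR-in-TAVR are not eligible. Both are
  computed on ensemble means.

## What the synthetic scenarios do and do not capture

`synthesize_scenario` provides hand-countable cohorts
(`tiny-deterministic`), configurable straight-line series with optional
jitter (`linear-growth`), and the US-magnitude default (`us-scale`).
These emulate the *scale and trend* of registry volume series, not their
institutional texture: no geographic or center-level structure, no COVID-style
shocks beyond what the shipped observed values contain, no reporting lags.
Tests passing on synthetic inputs therefore validate the simulation
machinery and its statistical behaviour, not the accuracy of any particular
registry series.

## Limitations

- Headline levels are calibration-sensitive: the registry volume inputs are
  not published in machine-readable form, so shipped values are documented
  approximations and the 2035 totals inherit their uncertainty.
- The low-risk survival curve, age distribution, and redo series are
  package assumptions (flagged above) chosen once to be clinically
  plausible; all are configurable.
- A single age distribution serves both procedure classes and all eras; no
  comorbidity, sex, or anatomy covariates; no procedural mortality of the
  ViV itself; no TAVR expansion below age 60; no third interventions.
- Problem size: the default scenario simulates ≈ 4.4 M patients per
  replicate (≈ 88 M per ensemble), chosen to match the configured national
  volume series exactly rather than sampling them down.
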