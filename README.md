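# asdcem

Lifetime patient-level microsimulation for cost-effectiveness analysis of
adaptive-behavior interventions in autism spectrum disorder (ASD).

The model compares two strategies — standard of care (SOC) and a one-time
cord-blood infusion added to it (CB) — for a cohort entering at age 2.
Individuals are followed monthly: adaptive-behavior (VABS-3) subscale scores
evolve from ages 2–7 and are frozen afterwards; a six-month trial-derived
communication-change distribution separates the arms; a published linear
mapping converts subscale scores to utilities for ages 2–17; at age 18 each
individual enters one of three permanent strata (composite >85, 70–85, <70)
that drive stratum-dependent adult productivity-loss costs; mortality uses
lifetable annual death probabilities converted to monthly rates, multiplied
by sex-specific standardized mortality ratios (2.49 male / 1.88 female), and
mixed at 78.2% male. Outcomes are QALYs and costs (societal and healthcare
payer perspectives), undiscounted and discounted at 3%/year, with the
incremental cost-effectiveness ratio (ICER) of CB over SOC as the headline
result. The two arms run under common random numbers so paired differences
isolate the intervention effect.

Included analyses: one-way (tornado) sensitivity, a two-way CB efficacy ×
cost ICER grid with willingness-to-pay classes, named scenarios (best/worst
case, MCID-truncated efficacy, payer perspective, reduced adult costs, zero
efficacy), calibration of the adult utility constant, and a 5-year budget
impact projection for the 247,000 eligible US children at configurable
uptake.

## Command-line usage

```bash
asdcem make-lifetable --out lt_synthetic.csv          # synthetic lifetable CSV
asdcem make-config --out model.yaml --lifetable lt_synthetic.csv
asdcem run --config model.yaml --n 100000 --seed 42 --strategy both --out results.csv
asdcem calibrate --config model.yaml --target 40.75 --out model_calibrated.yaml
asdcem tornado --config model.yaml --out tornado.csv
asdcem grid --config model.yaml --efficacy 1:6:1 --cost 3000:33000:5000 --out grid.csv
asdcem bia --config model.yaml --uptake 1.0 --out bia.csv
asdcem scenario zero_efficacy --config model.yaml
```

Any config value can be overridden on the command line with dotted keys,
e.g. `--set costs.adult_cost_divisor=3 --set intervention.cost_infusion=45000`.

## Using a real lifetable

Absolute life-expectancy and lifetime-cost targets require the 2017 US
period lifetable, which is not redistributed here. Transcribe it to CSV with
header `age,qx_male,qx_female` (one row per single year of age 0–100, `.`
decimal separator, annual death probabilities) and save it as
`data/us_lifetable_2017.csv`; the skipped tests in
`tests/test_acceptance.py` and the extra acceptance-report targets then run
automatically. Point `lifetable_path` in the YAML config (or
`--set lifetable_path=...`) at any such CSV for CLI runs.

## Layout

| module | role |
|---|---|
| `asdcem.life_tables` | lifetable IO, SMR-adjusted sex-mixed monthly mortality, analytic life expectancy |
| `asdcem.natural_history` | baseline cohort draws, monthly VABS-3 growth, adult strata |
| `asdcem.intervention` | six-month trial changes, adverse events, intervention costs |
| `asdcem.qol` | utility mapping, QALY accrual, adult-utility calibration |
| `asdcem.costs` | child/adult annual costs by stratum and perspective |
| `asdcem.engine` | vectorized monthly microsimulation, cohort aggregation, ICER |
| `asdcem.analyses` | tornado, two-way grid, scenarios, budget impact |
| `asdcem.synthetic_data` | Gompertz lifetable and fixture configs |
| `asdcem.config` | parameter dataclasses, YAML IO, dotted overrides |
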