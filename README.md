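# cvdshock

Scenario-based projection of cardiovascular-disease (CVD) burden caused by
unemployment shocks, with a proportional multi-state life-table (MSLT).

The package models a two-ethnicity population (an indigenous group with
higher unemployment and CVD burden, and a reference group): an aggregate
unemployment-rate shock is disaggregated into ethnicity x sex x age strata
preserving pre-shock relative rates, converted into relative risks on CHD
and stroke incidence via sex/age-specific effect sizes with a linear
scaling rule, and propagated through annual cohort life tables to produce
discounted health-adjusted life-year (HALY) losses, health-system costs,
per-1000-capita rates, ethnic equity ratios and Monte-Carlo uncertainty
intervals.

Because the original administrative inputs (census population counts,
labour-force unemployment rates, national disease-model epidemiology and
cost schedules) are not redistributable, a first-class synthetic-data
module generates seeded input sets with the same statistical structure;
absolute HALY/cost levels are fixture-dependent and only differences,
ratios and orderings are meaningful.

## Layout

| module | role |
| --- | --- |
| `cvdshock.synthetic_data` | seeded generators for population, unemployment and epidemiology/cost tables; bundle I/O (CSV + YAML) |
| `cvdshock.calibration` | disaggregation of aggregate unemployment changes into strata (ratio preservation + population-weighted conservation) |
| `cvdshock.scenarios` | built-in unemployment projection scenarios and model-year mapping |
| `cvdshock.risk_link` | effect sizes, relative-increase computation, incidence relative risks |
| `cvdshock.mslt` | the multi-state life-table engine, trends, discounting, differencing |
| `cvdshock.uncertainty` | log-normal / normal parameter sampling, Monte-Carlo runs, percentile intervals |
| `cvdshock.reporting` | per-capita rates, equity ratios, horizon shares, currency conversion, table export |
| `cvdshock.cli` | `cvdshock` command-line entry point |

## CLI

```bash
cvdshock generate --seed 1 --out-dir inputs/            # synthetic input bundle
cvdshock calibrate --inputs inputs/ --scenario base_case --out shock.csv
cvdshock run --inputs inputs/ --scenario base_case --out-dir out/
cvdshock montecarlo --inputs inputs/ --scenario base_case --draws 2000 --seed 1 --out-dir mc/
cvdshock report --outputs out/base_case.csv
```

`run` supports the sensitivity switches `--discount` (0 / 0.03 / 0.06),
`--duration 10` (prolonged shock), `--equity-params` (equalised ethnic
epidemiology) and `--freeze-disease-trend`.

## Python API

```python
import cvdshock as cs

bundle = cs.fixture_bundle(seed=1)
result = cs.run_analysis(bundle, "base_case", cs.EconomicConfig(discount_rate=0.03))
print(result.outputs)          # HALY/cost changes by stratum and horizon
```

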