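# tomtwin

A desk-scale digital twin of greenhouse cherry-tomato production with
techno-economic scoring. It simulates a December–May season — seeded
synthetic outside weather, a lumped greenhouse climate model driven by
open-loop setpoint schedules, and a source–sink crop model with per-truss
bookkeeping — and scores each season's yield, fruit quality (Brix),
resource use, costs and net profit at published tariffs. On top of the
simulator sit the strategy analyses: CO2 / temperature / lighting
sensitivity sweeps, per-week marginal lighting value, a weekly
lighting-hours optimizer, and an EC–Brix windowed correlation.

Six built-in strategy presets (ids 301–306) emulate the archetypal
control strategies of six experimental compartments: different
temperature regimes, lamp-hour budgets, CO2 dosing policies,
stem-density plans, fruit-pruning targets and topping dates.

## Layout

| module | role |
| --- | --- |
| `tomtwin.synthetic_weather` | seeded 5-min outside weather (clear-sky solar geometry × AR(1) cloudiness) |
| `tomtwin.strategy` | setpoint schedules, crop plans, the six presets, perturbation operators, validation |
| `tomtwin.climate_twin` | lumped greenhouse physics: energy / CO2 / humidity balances, fertigation, resource ledger |
| `tomtwin.crop_twin` | canopy photosynthesis, daily carbohydrate partitioning, truss development and harvest |
| `tomtwin.quality_economics` | Brix assignment, seasonal Brix-dependent pricing, cost breakdown, net profit, resource-use efficiency |
| `tomtwin.performance_analysis` | sensitivity sweeps, weekly marginal lighting, lighting optimizer, EC–Brix correlation |
| `tomtwin.runner` / `tomtwin.cli` | end-to-end season runs, manifests, preset comparison, CLI |

## CLI

```bash
tomtwin simulate --preset 306 --seed 1 --out runs/306   # one season + manifest
tomtwin compare --seed 1                                # all six presets, ranked
tomtwin sweep-co2 --preset 301 --seed 1
tomtwin sweep-temp --preset 303 --seed 1
tomtwin sweep-light --preset 302 --seed 1
tomtwin marginal-light --preset 302 --seed 1            # +2 h/day per week
tomtwin optimize-light --preset 302 --seed 1
tomtwin ec-brix --preset 306 --seed 1
```

Every run writes CSV outputs plus a `manifest.json` (config hash, seeds,
version); reruns from the same config are bit-identical. All randomness
is seeded: the weather generator and the Brix noise are the only random
components.

## Python API

```python
from tomtwin import RunConfig, run_season

res = run_season(RunConfig(preset=306, weather_seed=1, quality_seed=1))
print(res.economics.net_profit)     # EUR/m2
print(res.economics.rue)            # per-kg resource efficiencies
```

## Calibration and known limits

The simulator is calibrated at desk scale against seasonal aggregates
(per-compartment temperature averages, the 12.9–14.4 kg/m² class-A yield
range, the 33.0–37.2 €/m² income range, truss counts and plant-load
envelopes), not against any raw sensor record. Known, deliberate limits:

- Ripening does not accelerate after topping, so the late-season yield
  boost of a real topped crop is under-predicted.
- The two warmest presets respond ~neutrally to a −2 °C setpoint shift
  (they sit at the model's thermal optimum); cooler presets lose profit
  when cooled, as expected.
- Preset schedules are archetypes of the strategies they emulate, not
  reconstructions of slot-level setpoint logs.
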