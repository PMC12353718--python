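# dietopt

Mixed-integer weekly diet optimisation. Given a food database (per-100 g
compositions, serving sizes, per-kg prices and greenhouse-gas emission
factors), demographic nutrient requirement sets (daily lower bounds and
upper limits), and a baseline weekly diet, `dietopt` builds
nutrient-adequate weekly diets that minimise one of:

- **deviation from the baseline** (L1 distance in serving counts),
- **total weekly price**, or
- **total weekly greenhouse-gas emissions (GHGE)**,

optionally under price/GHGE caps expressed as fractions of the baseline's
totals. Serving counts are integer variables; the MILP is solved with
HiGHS via `scipy.optimize.milp` at zero MIP gap, and every optimal
solution is audited by independent re-evaluation of all constraints before
it is returned.

## Layout

| module | purpose |
| --- | --- |
| `dietopt.foods` | domain types, database-compilation transforms (composition averaging, amino-acid normalisation, bioavailability, price averaging), delimited-text readers |
| `dietopt.requirements` | requirement sets per (sex, age group), weekly bound conversion, adequacy audits |
| `dietopt.optimise` | MILP construction/solving, totals evaluation, brute-force enumeration oracle, LP export |
| `dietopt.scenarios` | the standard 9-scenarios-per-sex battery, battery runner, report tables (group intakes, nutrient contributions, percent changes) |
| `dietopt.synthetic` | seeded synthetic fixtures with controlled feasibility (planted-diet construction) |
| `dietopt.cli` | `dietopt` command-line tool |

## CLI

Generate a synthetic fixture, compile it, and run the full scenario
battery:

```sh
dietopt synth --seed 1 --out fixture/
dietopt compile --config config.yaml --out build/
dietopt optimise --config config.yaml --all --out runs/
dietopt report --run-dir runs/
```

`config.yaml` points at the input files:

```yaml
database:
  compositions: fixture/compositions.csv
  prices: fixture/prices.csv
  ghge: fixture/ghge.csv
  servings: fixture/servings.csv
  nutrients: fixture/nutrients.csv          # optional
  bioavailability: fixture/bioavailability.csv  # optional
baselines:
  female: fixture/baseline_female.csv
  male: fixture/baseline_male.csv
requirements: fixture/requirements.yaml
compiled_database: build/database.json
```

Scenario labels follow the `{F,M}.{Base,NAD,NAD_35,NAD_55,NAD_75,NAD_P,NAD_E,Min_E,Min_P}`
convention: minimum-deviation nutrient-adequate diets per age group
(`NAD*`), a 70% price cap (`NAD_P`), a 70% GHGE cap (`NAD_E`), and
unconstrained minimum-GHGE/price diets (`Min_E`, `Min_P`). Alcoholic
beverages are excluded from every optimised scenario by default.
Infeasible scenarios are recorded in the run summary (exit code 0);
configuration errors exit nonzero.

## Library use

```python
from dietopt import SynthSpec, generate, run_battery
from dietopt.scenarios import battery_summary

bundle = generate(SynthSpec(seed=42))
reports = run_battery(bundle.db, bundle.baselines, bundle.requirement_sets)
print(battery_summary(reports))
```

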