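# pigamu

Antimicrobial-use (AMU) quantification for farrow-to-finish pig farms.

Veterinary AMU surveillance needs farm-level records — feed tonnages
medicated with premixes, pack counts of water-soluble, oral and injectable
products — turned into indicators that are comparable across farms and
countries. `pigamu` implements that pipeline for epidemiologists and
veterinary scientists: from raw per-farm CSVs (or a built-in synthetic farm
population) to standardised consumption indicators and the usual summary
tables.

## What it computes

For each farm-year, and pooled over the population:

| Indicator | Definition |
|---|---|
| mg/PCU | mg active ingredient / population correction unit, `PCU = slaughter pigs × 65 kg + sows × 240 kg` |
| TK | treatable kilograms, `TK = mg / DDDvet` (long-acting injectables: `mg / la_dose × la_factor`) |
| TI | treatment incidence per age category, `mg / (DDDvet × kg at treatment × animals at risk × days at risk) × 100` |
| TI200 | stage-duration-weighted TI rescaled to a 200-day standard lifespan |
| DAPD | doses per 1000 animals per day (Danish convention) |
| DDDA_NAT | treatment days per average animal-year (Dutch convention) |

plus the class × route breakdown (% of active-ingredient weight, % of TK,
% of farms with use, mg/PCU), farm-level median (min–max) summaries,
medicated-diet pattern sets, EMA category-B / WHO HP-CIA summaries,
counterfactual record removal, and national extrapolation.

Amounts are resolved with the two standard formulas — feed: `kg of
medicated feed × inclusion rate (mg/kg)`; products: `packs × pack size ×
strength`, with prodrug and I.U. conversion — and missing pack counts are
imputed (farmer estimate first, else the peer-farm median).

The shipped reference catalog (19 compounds, 12 classes) marks every dose
standard not fixed by an authoritative printed value as `placeholder`;
replace them with the official ESVAC values for real analyses (see
`docs/methods.md`).

## Worked example

```python
import pigamu as pa

catalog = pa.default_catalog()
profiles, feed, products = pa.generate(pa.GeneratorConfig(n_farms=67, seed=1))
table = pa.quantify_usage(feed, products, catalog)

ind = pa.compute_indicators(table, profiles)
pooled = ind[ind.scope == "POOLED"].iloc[0]
farms = ind[ind.scope != "POOLED"]
print(f"total active ingredient: {pooled.total_mg / 1e9:.2f} t")
print(f"pooled mg/PCU: {pooled.mg_per_pcu:.1f}")
print(f"farm-level median mg/PCU: {farms.mg_per_pcu.median():.1f}")
print(f"farm-level median TI200: {farms.ti200.median():.1f}")

bd = pa.class_route_breakdown(table, profiles)
overall = bd[bd.route == "overall"].sort_values("ai_pct", ascending=False)
print(overall.head(5).round(2).to_string(index=False))
```

prints (seed 1):

```
total active ingredient: 10.59 t
pooled mg/PCU: 143.0
farm-level median mg/PCU: 127.8
farm-level median TI200: 32.8
      antimicrobial_class   route  ai_pct  tk_pct  farms_pct  mg_per_pcu
                    TOTAL overall  100.00  100.00     100.00      142.98
            tetracyclines overall   57.63   52.24      92.54       82.40
potentiated_sulphonamides overall   14.16   11.82      68.66       20.25
               macrolides overall   13.19   16.28      71.64       18.86
              penicillins overall    7.48    9.52     100.00       10.69
```

Reading: the 67 synthetic farms consumed 10.6 t of active ingredient —
143 mg per kg of standardised pig biomass produced — with tetracyclines
carrying the majority of the mass and medicated feed the dominant route.
A typical farm sits at ~128 mg/PCU, and its growing pigs spend about 33%
of a standardised 200-day life under treatment with one defined dose
(TI200 ≈ 33). Herd sizes, prevalences and class mix follow the generator's
stated world; see `docs/methods.md` for what that world does and does not
emulate.

The same pipeline runs from the shell:

```
pigamu all --n-farms 67 --seed 1 --out runs/demo
```

writing the generated inputs, usage table, indicator table, breakdown,
farm summary, diet patterns and a run manifest. `pigamu generate`,
`quantify`, `indicators` and `report` run the stages individually on your
own CSVs (schemas in `pigamu.records`).

## Acceptance script

`scripts/acceptance.py` runs the full pipeline on the default synthetic
population and then recomputes the package's reference quantities from
scratch (e.g. the worked treatable-kilograms dose example), writing them as
JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```
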