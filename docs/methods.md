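# Methods

`pigamu` quantifies on-farm antimicrobial use (AMU) on farrow-to-finish pig
farms for one calendar year and expresses it in the standard surveillance
indicators. This note records the model, its assumptions, the tunable
constants, and what the synthetic population does and does not establish.

## Quantification model

Two amount formulas resolve every record into mg of active ingredient:

* **Medicated feed** (antimicrobial oral premixes):
  `mg = medicated feed (kg) × inclusion rate (mg active / kg feed)`,
  evaluated per combination of diet category and inclusion rate. Each diet
  maps to exactly one production stage (creep → piglet; starter, link,
  weaner → weaner; finisher → finisher; sow diets → sow), so feed-borne AMU
  is allocated to ages deterministically.
* **All other products** (water-soluble remedies, top dressings, oral doses,
  injectables): `mg = packs × pack size (g or ml) × strength (mg per g or
  ml)`. Strengths declared in international units are divided by the
  compound's I.U.-per-mg factor; declared prodrug/salt masses are multiplied
  by a conversion factor in (0, 1] to give the active moiety. Combination
  products are decomposed into one record per constituent ingredient.
  Product amounts are split across age categories by explicit allocation
  fractions; when a user declares only target stages, the split defaults to
  equal shares (the neutral choice — true proportions are rarely recorded
  in the field).

**Missing pack counts** are imputed before quantification: the farmer's own
estimate takes precedence; otherwise the median pack count over the other
farms using the same product (even count: mean of the two central values).
Records filled this way are flagged `imputed`. With no estimate and no peer
farm the record is unimputable and the pipeline stops with an error rather
than guessing.

**Potency standardisation.** Amounts are converted to *treatable kilograms*
(TK): the kg of pig treatable for one day at the compound's defined daily
dose, `TK = mg / DDDvet`. Two long-acting injectable macrolides
(tulathromycin, tildipirosin) have no assigned DDDvet; they carry an
alternative single-administration dose `la_dose` (mg/kg) covering
`la_factor` days, and the engine folds this into one effective daily dose
`la_dose / la_factor` so a single formula serves every compound.

## Indicators

With `M` = total mg, `TK` = total treatable kg for a farm-year:

* **PCU** (population correction unit):
  `pigs slaughtered × 65 kg + sows × 240 kg`; **mg/PCU** = `M / PCU`.
  Standard weights are configurable (`IndicatorConfig`).
* **Treatment incidence** per age category:
  `TI = mg / (DDDvet × weight at treatment × animals at risk × days at
  risk) × 100`, summed over ingredients. Internally computed as
  `TK / (weight × animals × days) × 100`, which is algebraically identical
  and extends correctly to the long-acting compounds.
* **TI200**: the piglet/weaner/finisher TIs combined by stage-duration
  weighting and rescaled to a standard 200-day lifespan:
  `TI200 = (Σ TI_s × d_s / Σ d_s) × (200 / Σ d_s)`. When all stage TIs are
  equal and the rearing period is 200 days, TI200 equals that common TI.
* **DAPD** (Danish convention): `(TK / standard weight) / (animals present ×
  days) × 1000`. At farm level the animals present are derived from average
  standing biomass via a standard pig weight (default 50 kg), which cancels
  out of the rate: DAPD reduces to `TK / biomass / 365 × 1000`.
* **DDDA_NAT** (Dutch convention): `TK / average standing biomass` —
  treatment days per average animal-year.

The exact national DAPD/DDDA_NAT conventions (age-class standard weights,
the national average-weight denominator) are not public in a single printed
form; the implementations here are documented reconstructions with every
denominator explicit and configurable, and should be recalibrated before
any formal cross-country comparison.

**Pooling.** Pooled mg/PCU, DAPD and DDDA_NAT are ratios of totals, never
means of farm-level values. Pooled TIs divide summed TK by the summed
biomass-time denominator (weight × animals × days over farms); pooled TI200
uses the farm-average stage durations. This is a design choice: a
biomass-time-weighted pooled TI is the natural aggregation when farms share
a denominator convention, but other conventions exist.

**Default stage durations** are suckling 28 d, weaner 63 d, finisher 77 d
(total 168 d), matching weaning around 28 days, a nine-week weaner stage
and slaughter around 24 weeks. **Default weights at treatment** are piglet
2 kg, weaner 12 kg, finisher 70 kg, sow 220 kg. The fixed weaner weight
understates the weight of pigs treated late in a long weaner stage, which
inflates TI_weaner and hence TI200; no correction is applied, because the
bias is a property of the convention itself and correcting it silently
would break comparability.

## Reference catalog

The shipped catalog covers 19 compounds spanning all twelve antimicrobial
classes handled by the reports, with EMA category (A–D) and WHO HP-CIA
flags. Only values fixed by an authoritative printed source are marked
`stated` (marbofloxacin DDDvet = 2 mg/kg); every other DDDvet, conversion
factor, I.U. factor and long-acting parameter is marked `placeholder` and
must be replaced with the official ESVAC / published values before any
real-data analysis. The catalog is plain CSV precisely so that this
substitution is an edit, not a code change.

## Synthetic population

The generator emulates a 67-farm national cross-section:

* herd size log-normal around a median of 528 sows (σ = 0.55, clipped to
  110–3000) — only the median and range of the emulated population are
  known, so a right-skewed two-parameter family clipped to the range is the
  minimal choice;
* ~23.5 pigs slaughtered per sow-year (SD 2.0);
* per-diet medication prevalences: creep 0.522, starter/link (at least one)
  0.881, weaner 0.577, finisher 0.239, sow 0.254;
* per-route product-use prevalences: water 0.642, top dressing 0.239, oral
  dose 0.313, injectable 1.0 — every farm injects, and always at least one
  penicillin product;
* feed ingredient picks iid from configured weights whose class totals
  follow the rank order tetracyclines > potentiated sulphonamides >
  macrolides > penicillins; duplicate picks within a diet are kept and read
  as regime changes during the year;
* missing prescription records injected at farm level with probability
  5/67, with a log-normally noised farmer estimate attached with
  probability 0.6 (always, when the product has no peer farm — otherwise
  the record would be unimputable, and the emulated study managed to impute
  everything).

Feed tonnages per diet, medicated fractions, inclusion rates and pack-count
intensities are documented defaults chosen to put the pooled population in
a realistic range (order 100–150 mg/PCU, feed-dominated, oral routes near
~97% of mass); they are a stated world, not a fit, and parameter-recovery
tests compare the generated data against the *configured* values, not
against any published result.

Randomness contract: one master seed; each farm draws from its own
`SeedSequence`-spawned substream, so extending `n_farms` never perturbs
existing farms, and route/diet/product usages are exact Bernoulli draws —
giving recovery tests exact binomial sampling distributions.

**What a green synthetic test establishes:** that the pipeline's
arithmetic, aggregation and imputation behave correctly on data with the
right marginal structure. It does *not* establish realism of joint
structure: route usages are independent within a farm, there is no
within-year timing, no disease process, no correlation between herd size
and medication intensity.

## Numerical choices

* All mass arithmetic in mg as 64-bit floats; rounding (2 decimals for
  percentages and mg/PCU) only at output.
* Allocation fractions must sum to 1 within 1e-9; mass conservation under
  allocation is exact to float addition.
* Even-count medians are the mean of the two central values.
* CSV round-trips use exact float parsing (`float_precision="round_trip"`),
  making read → write byte-stable.
* Farms with zero use in a stratum contribute zeros to stratum medians
  (so a stratum used by under half the farms has median 0); this matches
  the zero-inflated medians typical of published farm-level tables.
* A TI denominator of zero with nonzero use is an error, never a silent 0
  or infinity; zero use with a zero denominator is 0.

## Known limitations

* No used-daily-dose (UDD) computation and no dose-regimen reconstruction:
  the pipeline works from annual totals.
* Partial-year farms are out of scope; all denominators are per calendar
  year.
* The placeholder dose standards make absolute TK/TI levels on the shipped
  catalog indicative only; relative and structural results (shares,
  patterns, recovery) are unaffected by a consistent rescaling of any one
  compound's dose.
* Venn-style diet-pattern rendering is not included; pattern subset counts
  are emitted as CSV.
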