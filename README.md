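# natremia

Predicts the plasma sodium response to crystalloid IV fluid therapy in SIADH
patients, and validates the predictions against measurement cohorts.

Two closed-form models are implemented:

- **Free-water-balance model** (`voets`): accounts for both infusate input
  and urine output,
  `Δ[Na⁺]p = [Na⁺]p · Vi/TBW · (1.7·Oi/Ou − 1)`,
  where `Oi` is the infusate tonicity and `Ou` the urine osmolality.
  The prediction changes sign at the *critical urine osmolality*
  `1.7 · Oi` (523.6 mOsmol/L for 0.9% saline): above it, saline lowers the
  plasma sodium.
- **Volume-generalised Adrogué-Madias model** (`adrogue_madias`):
  redistribution only, `Δ[Na⁺]p = Vi·([Na⁺]i − [Na⁺]p)/(TBW + Vi)`.

The package also ships the 15-measurement SIADH validation cohort, a
validation pipeline (Pearson r, two-sided t-test p-value, residual
summaries), a Fisher-z sample-size calculator, TBW estimation helpers, and a
seeded synthetic-cohort generator.

> **Not for clinical use.** This is a research/education tool, not a medical
> device. It implements first-order steady-state models with no correction-
> rate safety limits (e.g. osmotic-demyelination guard rails), no urine-
> volume simulation and no time dynamics.

## CLI

```sh
# one prediction, both models (warns: Ou 766 > critical 523.6 → saline lowers Na)
natremia predict --na 133 --tbw 34 --volume 1.5 --percent 0.9 --urine-osm 766

# validate both models against the bundled 15-measurement cohort
natremia validate --paper-cohort --model both
# → voets  n=15  r=0.94  p=1.61e-07 ;  adrogue_madias  n=15  r=0.50  p=0.058

# sample size to detect r = 0.70 (two-sided, alpha 0.05, power 0.80)
natremia samplesize --r 0.70 --alpha 0.05 --power 0.80   # → n = 13

# generate a seeded synthetic cohort as CSV
natremia simulate --n 50 --seed 1 --noise-sd 0.5 --out cohort.csv
```

All commands accept `--json` for machine-readable output; `--config FILE`
(YAML) overrides defaults such as `tonicity_factor` (the 1.7 urine
osmolality-to-tonicity factor).

## Cohort CSV schema

```
record_id,sex,age_y,weight_kg,tbw_l,infusate_volume_l,infusate_percent_nacl,
na_initial_mmol_l,na_final_mmol_l,urine_osm_mosm_l,causative_condition
```

Header required, UTF-8, decimal point. Repeat infusions in one patient are
separate rows. `natremia validate --cohort my.csv` consumes this schema;
`natremia simulate` emits it.

## Known reproduction caveats

- Five published free-water-balance predictions (cohort rows 2, 3, 5, 6, 7)
  differ from direct recomputation with the published inputs by 0.1–0.4
  mmol/L; the implementation follows the equation as stated and documents
  the discrepancy rather than fitting to the printed cells.
- The published Adrogué-Madias p-value (0.07) recomputes as ≈ 0.058 with the
  exact t-test at r = 0.499, n = 15; the original rounding procedure is
  unknown.
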