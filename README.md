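# lactodose

Compartmental I-131 biokinetics for a **nursing mother**, with time-variable
inhalation and ingestion scenarios built from environmental monitoring series,
and thyroid equivalent doses for mothers and their breast-fed infants.

After an atmospheric radioiodine release, small amounts of I-131 can appear in
breast milk of mothers living in mildly affected areas. `lactodose` answers
the questions a dose assessor asks of such measurements:

* Given air and tap-water concentration time series and a personal behaviour
  profile, what milk concentration does the biokinetic model predict day by day?
* Given a single measured milk concentration, what acute intake would explain
  it (bioassay-to-intake inversion)?
* What thyroid equivalent doses follow for the mother (inhalation of gaseous
  and particulate iodine, tap-water ingestion) and for a 3-month-old infant
  consuming 0.8 kg of that milk daily?

## Model

The lactating-adult model is a first-order compartment system
`dy/dt = (T − λI) y + b(t)` on 26 named compartments joining three sub-models:

* **respiratory tract** (ET, BB, bb, AI, LN): regional deposition for SR-1
  iodine vapour and for Type F aerosol with AMAD 1 µm, mucociliary clearance to
  the gut and rapid dissolution to blood (100 d⁻¹);
* **alimentary tract** (OC, OE, ST, SI, RC, LC, RS → FA): sequential transit
  with complete small-intestine absorption for iodine (f_A = 1);
* **systemic iodine kinetics during lactation**: blood iodide partitioned to
  thyroid (IT → organified OIT, 80-day retention), urine (UB → UR), salivary
  and gastric secretion back to the gut, other tissues (IO, OIO, OV), and a
  breast pathway **blood → BR → BM** secreting iodide into milk.

λ is the I-131 physical decay constant (T½ = 8.0252 d), applied in every
compartment. The system is integrated by classical fixed-step 4th-order
Runge-Kutta at 0.001 day. The daily milk concentration is the activity
delivered into the milk compartment during each calendar day divided by the
0.8 kg secreted per day.

Intake scenarios convert environmental series to intake rates:
`I_inh(t) = C_air(t)·V` per form and `I_ing(t) = C_water(t)·D`, where the
effective breathing volume is

```
V = F·(B_S·b_S,in + B_R·b_R,in + B_LE·b_LE,in) + B_LE·b_LE,out
```

with activity-specific breathing rates `B`, time budgets `b` and indoor
reduction factor `F = 0.75` (reference profile: V = 15.2 m³/d; behavioural
extremes 13.1–18.4 m³/d), and `D ∈ {0, 1, 2}` kg/d of tap water.

Doses are intake × ICRP age- and route-specific thyroid dose coefficient.

## Worked example

```python
import datetime
import lactodose as ld
from lactodose.scenarios import breathing_profile_preset
from lactodose.dosimetry import render_report

# effective breathing volume of the reference housewife profile
v = ld.effective_breathing_volume(breathing_profile_preset("default"))
print("V =", round(v, 1), "m3/d")

# intake consistent with 8.0 Bq/kg in milk sampled 2011-04-24,
# assuming one acute gaseous-form inhalation on 2011-03-15
q = ld.back_calculate_intake(8.0, datetime.date(2011, 4, 24),
                             datetime.date(2011, 3, 15), "vapour_inhalation")
print(f"acute vapour intake: {q/1e6:.2f} MBq")

# end-to-end dose report on a synthetic environmental bundle
bundle = ld.default_synthetic_bundle(seed=42)
report = ld.dose_report(ld.ScenarioConfig(), bundle)
print(render_report(report))
```

prints

```
V = 15.2 m3/d
acute vapour intake: 1.13 MBq
Thyroid equivalent dose (mSv); bracketed values are intakes (kBq)
window 2011-03-11 .. 2011-04-30

               gaseous inh.     particulate inh.  ingestion
mother         0.44 (1.1)       0.11 (0.7)         0-0.94 (0-2.2)
infant         0.51 (0.16)       0.14 (0.099)         0.49-1.2 (0.13-0.34)
```

The 15.2 m³/d is the daily inhaled volume of the reference behaviour profile.
The 1.13 MBq is the acute intake that would explain the measured milk sample
under a single-inhalation assumption — the inversion divides the measurement
by the per-unit-intake milk concentration 40 days after intake. In the report,
the mother's dose is dominated by inhalation while the infant's is dominated
by milk ingestion (the bracket spans the tap-water consumption sweep
D = 0–2 kg/d); the environmental bundle here is synthetic, so the absolute
numbers illustrate the pipeline, not any measured event.

The same stages are scriptable from a shell:

```bash
lactodose generate --kind air --seed 42 --out air.csv
lactodose generate --kind water --seed 43 --out water.csv
lactodose scenario --air air.csv --water water.csv --D 1.0 --out schedule.csv
lactodose simulate --schedule schedule.csv --out trajectory.csv --milk-out milk.csv
lactodose backcalc --measured 8.0 --sample-date 2011-04-24 --intake-date 2011-03-15 --route vapour
lactodose run --outdir out/          # full synthetic end-to-end run
```

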