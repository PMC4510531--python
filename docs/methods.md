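# Methods

## Model structure

The package simulates I-131 kinetics in a lactating adult as a linear
first-order compartment system

    dy/dt = (T − λI) y + b(t)

where `y` is the activity vector over 26 named compartments, `T` the matrix of
transfer coefficients (d⁻¹), `λ` the I-131 physical decay constant
(T½ = 8.0252 d, a literature physical constant), and `b(t)` a piecewise-
constant input built from the intake schedule and a per-route entry
distribution. Decay is applied identically in every compartment, sinks
included; decay products are not tracked. Sinks (urine UR, faeces FA, breast
milk BM, environment EN) have no outflow other than decay.

Three sub-models are joined:

* **Respiratory tract.** Regional deposition fractions of inhaled activity:
  SR-1 vapour deposits fully (ET 0.10, BB 0.20, bb 0.30, AI 0.40); Type F
  aerosol with AMAD 1 µm deposits 51% of the inhaled activity (ET1 0.165,
  ET2 0.211, BB 0.0124, bb 0.0165, AI 0.107), the rest being exhaled.
  The model graph carries a single extrathoracic compartment, so the
  anterior-nares (ET1) deposit — which never reaches systemic circulation —
  is assigned directly to the environment sink at entry; this changes only
  the bookkeeping timing of externally cleared material. Mucociliary
  clearance moves material toward the gut (ET→OE 100 d⁻¹, BB→ET 10 d⁻¹,
  bb→BB 2 d⁻¹, AI→bb deposition-weighted 0.0066 d⁻¹, small sequestration to
  lymph nodes); dissolution-absorption to blood is the fast-type 100 d⁻¹ in
  all thoracic/extrathoracic compartments for both vapour and Type F aerosol.
  Because dissolution dominates every competing mechanical rate, the absorbed
  fraction for the aerosol is essentially (total deposit − ET1 deposit) ≈ 0.35,
  and the result is insensitive to the mechanical-clearance details.
* **Alimentary tract.** Sequential transit OC→OE→ST→SI with gastric emptying
  20.57 d⁻¹ (70 min) and small-intestine transit 6 d⁻¹ (4 h); adult-female
  colon segments at 1.5 d⁻¹ feed the faeces sink. Iodine's fractional gut
  uptake is 1, which is represented by routing all small-intestine outflow to
  blood (the usual fA/(1−fA) construction diverges at fA = 1); the colon chain
  is still exercised by the organic-iodine faecal return (OIO→RC).
* **Systemic iodine during lactation.** Circulating iodide clears at
  3.09 d⁻¹ (T½ ≈ 5.4 h) partitioned to: thyroid trapping 27% (IT, organified
  to OIT at 8.32 d⁻¹), urinary excretion 42% (UB, voided at 12 d⁻¹ to UR),
  salivary + gastric secretion 11% (returned to the gut and reabsorbed),
  tissue iodide 9% (IO, and a small ovarian pool OV, returning at 1.39 d⁻¹),
  and breast uptake 11% (BR). Breast iodide splits 3:1 between milk secretion
  (BR→BM 1.386 d⁻¹) and return to blood. Organified thyroid iodine is
  released with an 80-day half-time (OIT→OIO 0.00866 d⁻¹); organic iodine
  turns over at 0.0577 d⁻¹, 80% recycled to circulating iodide and 20% lost
  to the faecal path. Net effect per circulation pass: ~35% of absorbed
  iodide reaches the thyroid, ~54% urine, ~11% milk — consistent with
  classic adult iodine kinetics with a lactation diversion.

The numeric rates are a reconstruction assembled from the ICRP model family;
they are not a verbatim copy of any single table, and the registry file
(`src/lactodose/data/iodine_lactation.yaml`) carries a provenance note per
rate. Replacing the registry swaps the whole parameterisation without code
changes.

The mother is assumed to be in established lactation throughout; no pregnancy
or lactation-onset dynamics are modelled. The infant's own systemic kinetics
are not simulated — infant doses use age-specific dose coefficients.

## Milk concentration and inversion

The daily milk concentration is the activity delivered into BM during each
calendar day divided by the daily secreted milk mass (0.8 kg). Operationally
the milk compartment is flushed at day boundaries (the infant drinks the day's
milk): the delivered activity is `BM(d+1) − BM(d)·e^(−λ·1 d)`, i.e. the
day-end content net of the decayed carry-over. Concentrations are physical
(decay included).

Back-calculation simulates a unit acute intake on the assumed intake date,
reads the per-unit daily concentration on the sampling date, and divides the
measurement by it. The operation is exactly linear in the measurement and
round-trips a forward-simulated intake by construction; it is refused when the
per-unit concentration falls below 1e−30 (ill-conditioned inversion).

The absorbed-to-blood fraction of a route is computed on a copy of the model
with blood converted to a sink, so the accumulated blood activity equals the
cumulative uptake exactly; multiplying by `e^(+λt)` at 30 days removes
physical decay from the bookkeeping.

## Exposure scenarios

Inhalation rate: `C_air(t)·V` per form, with the air concentration held
constant within each sampling interval, carried forward through gaps and after
the last sample, and zero before the first. Ingestion rate: `C_water(day)·D`,
zero before the first sample, linearly interpolated across missing days,
carried forward after the last.

Effective breathing volume `V = F·(B_S·b_S,in + B_R·b_R,in + B_LE·b_LE,in) +
B_LE·b_LE,out`. The reference profile uses adult-female breathing rates
(0.32/0.39/1.25 m³/h for sleep/rest/light exercise) and a non-working
housewife's time budget; meal hours (1.45 h) are counted at the sleep rate,
a layout choice that reproduces all three reference volumes (15.2 m³/d
default, 13.1 with outdoor hours reassigned to indoor rest, 18.4 with all
light-exercise hours outdoor) simultaneously. The indoor reduction factor
F = 0.75 applies to indoor hours only. For the 3-month-old infant
(0.09 m³/h × 17 h asleep + 0.19 m³/h × 7 h awake) the infant is assumed fully
indoors, so F multiplies all hours, giving 2.145 m³/d; this assumption is a
modelling choice justified by consistency of the resulting infant/adult
intake ratio with the reference dose bookkeeping, and can be disabled by
setting the infant's F to 1.

Tap-water consumption D defaults to the sweep {0, 1, 2} kg/d — 0 covers
avoidance of tap water — and the dose report brackets all D-dependent
entries by the sweep's extremes.

## Dosimetry

Thyroid equivalent dose = intake × coefficient, per route and age group.
Shipped coefficients (Sv/Bq): adult — vapour 3.9e−7, Type F 1-µm particulate
1.5e−7, ingestion 4.3e−7; 3-month infant — 3.2e−6, 1.4e−6, 3.7e−6. They are
transcribed ICRP age-dependent thyroid coefficients and are overridable via
`DoseCoefficientTable`. Doses are deliberately not taken from the simulated
thyroid compartment: the biokinetic model supplies intake partitioning and
milk output, while committed doses come from the coefficient convention.
Human-readable reports round to two significant figures; the JSON report
keeps full precision.

## Numerics

* Classical 4th-order Runge-Kutta, fixed step 0.001 d (reference), output
  grid 0.01 d. For a linear system with input constant over a step the
  four-stage update collapses exactly to `y ← P y + Q b` with
  `P = Σ_{j≤4}(hM)^j/j!`; the implementation uses this propagator form plus
  stride-chunking between output points (a test asserts bit-level equality of
  one propagator step with the explicit stagewise form).
* Stability guard: the step must satisfy `h ≤ 1/max_j(Σ outflow_j + λ)`,
  otherwise a StabilityError names the bound. The registry caps the fastest
  transit (oral/oesophageal) at 720 d⁻¹ so the reference step is admissible;
  true transit is minutes-scale, orders of magnitude faster than every other
  process, so downstream results are unaffected by the cap.
* Intake discontinuities are snapped to grid indices with per-segment rate
  renormalisation, preserving each segment's integral exactly; administered
  totals therefore match the schedule's analytic integral to round-off.
* An independent forward-Euler mode (10× finer step) serves as an integration
  cross-check, and `scipy.linalg.expm` as a second oracle in the tests; both
  agree with the RK4 path to <0.1%.
* Acute intakes may be represented either as a one-step pulse of exact total
  (used for calendar-dated scenarios) or as an exact instantaneous initial
  condition (used for closed-form comparisons).
* Negative activities beyond −1e−9 of scale abort the run; tiny negative
  round-off is clipped to zero.

## Synthetic environmental data

The generator emulates the *structure* of post-release monitoring data: a few
short plume episodes (boxcar pulses with log-normally jittered peaks, default
first arrival four days after the origin date) over an exponentially decaying
background, split into gaseous/particulate components; and a tap-water series
that rises over a few days to a peak about a week after the origin, then
declines with a ~4-day half-time, with days dropped at a configurable missing
rate to exercise the interpolation rule. Default magnitudes (air peaks of
tens–hundreds Bq/m³, water peak 150 Bq/kg) are order-of-magnitude plausible
for a mildly affected area and give the qualitative regime in which the
breast-milk pathway dominates the infant's dose; they are deliberately not
calibrated to any measured monitoring record. What passing end-to-end tests
show is therefore that the pipeline reproduces the *pattern* of observations
(early milk peak far exceeding, but not extinguishing, the tail five weeks
later; infant milk-ingestion dose above infant inhalation dose), not any
measured concentration value. Real data enter through the documented CSV
dialects instead.

## Problem sizes

The shipped analyses integrate 26 compartments for 30–50 days at the 0.001-day
reference step (30 000–50 000 steps); the full test suite and the acceptance
script each complete in well under a minute on a single CPU.

## Known limitations

* Transfer rates are an edition-level reconstruction of the ICRP family, not
  a certified transcription; quantities driven by the systemic recycling
  (e.g. late-time milk concentrations) inherit that uncertainty, which is why
  the intake inversion is quoted with a wide tolerance.
* Single-nuclide kinetics only (no progeny, no other radionuclides); no
  stiff/adaptive solver; no uncertainty propagation over transfer rates.
* Food-chain ingestion (contaminated vegetables) is out of scope; intake
  routes are air inhalation and tap-water ingestion only.
* The gas/particulate split of air concentrations must be supplied by the
  input data; the package does not infer it.
* The ovaries compartment carries a small generic tissue-exchange rate; no
  iodine-specific ovarian kinetics are claimed.
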