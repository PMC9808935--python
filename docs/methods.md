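# Methods

## The decision problem and model structure

`tavicea` evaluates transcatheter aortic valve implantation (TAVI) against
surgical aortic valve replacement (SAVR) for elderly, high-surgical-risk
patients with severe aortic stenosis, from a healthcare-payer perspective
with costs in 2020 Iranian Rial. The model is a hybrid: a short-horizon
decision tree for the procedure and its acute consequences feeds a
discrete-time Markov cohort model with a lifetime horizon.

The Markov state space has nine states: NYHA functional classes I–IV, the
same four classes after a major stroke, and death. Death is the unique
absorbing state. The structural assumptions are:

* **Identical death transitions.** Every alive state shares the same
  per-cycle all-cause death probability (the source data provide no
  state-specific survival).
* **Frozen NYHA class.** Patients do not drift between NYHA classes
  except via stroke or death; no inter-class transition probabilities are
  available.
* **One-way stroke split.** NYHA-k moves to NYHA-k-post-stroke with the
  annualized major-stroke probability, composed multiplicatively on
  survivors (`(1 − p_death)·p_stroke`); post-stroke states never revert.

Per cycle `t ≥ 1`, state occupancy is propagated as `π_t = π_{t−1} P_t`.
QALYs and recurring costs accrue on the **end-of-cycle occupancy**,
discounted at the annual rate `r` (default 6.5 %, costs and effects alike)
with factor `(1+r)^{−t}`; the acute cost enters undiscounted at time zero.
An optional half-cycle correction (off by default, mirroring the
spreadsheet-style original) averages successive occupancy rows. The cohort
stops at `max_cycles` (default 50) or when survival drops below
`survival_stop_epsilon` (default 1e−4 — the "until nobody is left alive"
rule needs a numeric cut-off; at default mortality this truncates less
than 2·10⁻⁴ of a QALY).

## Entry: merging the tree with year one

The published outcome split (probability of being in NYHA I–IV or dead at
0–12 months, per arm) is applied as the Markov entry distribution
(cycle-0 row), i.e. the 30-day tree and first-year outcomes are merged —
no separate 30-day branch probabilities exist. Entry assigns zero mass to
the stroke states: acute strokes are costed as events, and the stroke
split begins with the first Markov transition. Acute deaths accrue the
full procedure-phase cost (they were operated on) and zero QALYs.

## Utilities

NYHA-class utilities (EQ-5D): 0.72, 0.72, 0.53, 0.47 with SDs 0.25, 0.25,
0.32, 0.35 (Beta-distributed in the PSA). Major stroke carries an
absolute disutility of 0.39, subtracted from the class utility and
floored at zero (NYHA IV post-stroke: max(0, 0.47 − 0.39) = 0.08).
Whether the decrement is subtractive or multiplicative is not specified
by the source; subtraction with a floor is the package's choice. The
decrement is deferred during the first long-term cycle (rehabilitation
year) and applied from cycle 2 onward.

## Event probabilities and annualization

Adverse-event probabilities (TIA, stroke, rehospitalization, myocardial
infarction, new atrial fibrillation, new pacemaker, aortic-valve
reintervention) are read as **cumulative over the five-year trial
follow-up** — the cited clinical outcomes are five-year results — and
converted to annual probabilities under a constant hazard:
`p_annual = 1 − (1 − p_cum)^{1/years}`. A knob (`event_annualization:
ALREADY_ANNUAL`) treats them as annual instead. Duplicated TIA rows in
the source table (identical values) are collapsed to one entry per arm.

## Mortality beyond year one

The source provides no post-year-1 survival. Cycle 1 always uses the
entry-cohort annual death probability (0.25 TAVI, 0.27 SAVR). The default
(`CONSTANT_YEAR1`) holds that value constant for all later cycles — the
only defensible zero-extra-data choice, exposed prominently because
lifetime QALYs are highly sensitive to it. `USER_TABLE` substitutes
per-arm, per-cycle-range annual probabilities from cycle 2 on, and
`annual_death_override` forces one probability for every cycle.

## Costs and the assignment table

The unit-cost inventory (procedures, hospitalizations, the 450 M stent,
the 800 M valve, pacemaker/ICD, angioplasty, reoperations, CABG) does not
itself say where each cost accrues. The **cost-assignment table is data**:
each item lists `(arm, phase[, event][, weight])` entries with phase one
of

* `PROCEDURE` — accrues once, in full (times `weight`), in the acute stage;
* `ACUTE_EVENT` — accrues once, weighted by the cumulative probability of
  the named triggering event in that arm;
* `PER_CYCLE_EVENT` — accrues every Markov cycle on alive patients,
  weighted by the annualized event probability (rehospitalization can be
  limited to the first cycle via `rehospitalization_recurring: false`).

Default mapping: TAVI procedure phase = procedure + hospitalization +
stent; SAVR procedure phase = procedure + hospitalization; valve and
arm-specific reoperations trigger on aortic-valve reintervention;
pacemaker/ICD on new pacemaker implantation; angioplasty and CABG on
myocardial infarction; the arm's hospitalization cost recurs with the
annualized rehospitalization rate. Assigning the 800 M valve wholly to
SAVR's procedure phase would exceed SAVR's published total per-patient
cost, so by default it is event-triggered only. New atrial fibrillation
has no plausible item in the printed inventory and therefore carries no
cost (its one-way curve is flat under the defaults).

Parameters printed **without** an SD are fixed in the PSA; the four
utilities (Beta) and the four cost items printed with SDs (Gamma) are
sampled by method-of-moments parameterization: Beta `α = m·c`,
`β = (1−m)·c`, `c = m(1−m)/σ² − 1` (infeasible variances raise, never
clip); Gamma `shape = (m/σ)²`, `scale = σ²/m`.

## Incremental metrics

ΔC, ΔE and the ICER between TAVI and SAVR, with quadrant handling: a
ratio is reported for costlier-and-better; cheaper-and-better is
DOMINANT, costlier-and-worse DOMINATED (no ratio either way);
cheaper-and-worse yields a ratio flagged `southwest` because its decision
meaning inverts; ΔE = 0 is flagged NO_RATIO. Net monetary benefit is
`wtp·ΔE − ΔC`. Dollar views divide by the fixed 250,000 IRR/US$ 2020
rate, rounded half-up for display only. The WHO willingness-to-pay
anchors are 551,400,000 (1× GDP per capita) and 1,654,200,000 IRR (3×).

## Uncertainty analysis

**PSA** re-runs the full two-arm model per draw (default configuration:
10,000 iterations recommended; the shipped analyses use 600–2,000, which
hold the Monte-Carlo error on the mean ICER well under 1 %). Each sampled
configuration is a point configuration (distribution tags cleared), so it
validates and runs like any deterministic one. Because "mean ICER" is
ambiguous, both aggregations are always reported: ratio of means
(`mean ΔC / mean ΔE`, the headline) and mean of ratios (over
northeast-quadrant draws, with the excluded-draw count).

**CEAC** reports, per willingness-to-pay value, the fraction of draws
with strictly positive net benefit; exact ties count as not
cost-effective.

**One-way analysis** scales one named parameter (both arms jointly for
event rates) over a multiplier grid, default 0.05×–2.50× — a grid wide
enough to cover "5 % to 150 % changes" read either as levels or as
growth; probabilities are clipped to [0,1] with a warning. The tornado
ranks parameters by ICER swing (max − min over the grid), ties broken by
name.

## Microsimulation oracle and synthetic data

`tavicea.microsim` simulates individual patients through the *same*
entry distribution, transition matrices, rewards and discounting as the
cohort engine, so its mean cost/QALYs must agree with the cohort result
up to Monte-Carlo error — the package's main correctness oracle (checked
at 200,000 patients per arm, 3-SE tolerance). Each patient owns an
independently seeded substream (`SeedSequence(seed, spawn_key=(i,))`), so
growing the cohort never perturbs earlier patients, and the
single-patient and vectorized cohort paths are bit-identical. Per-cycle
event costs are sampled Bernoulli per patient; the acute cost is added
as its deterministic expectation (same mean, lower oracle variance). The
event-log CSV (patient, cycle, state, event, discounted cost and QALY
accruals) is the package's synthetic dataset: it has exactly the
statistical structure the cohort model assumes — homogeneous cohort,
identical death hazards, frozen NYHA class — and none of the
heterogeneity (age/sex effects, state-dependent mortality, time-varying
hazards) real registries show, so passing oracle tests validates the
engine, not the clinical realism of those assumptions.

## Calibration

Under the documented defaults the reconstructed model yields TAVI ≈ 550 M
IRR / 1.17 QALYs and SAVR ≈ 105 M / 1.05: the qualitative picture (TAVI
more effective and far costlier, ICER positive and well above 1× GDP) is
reproduced, but not the published per-arm magnitudes — the published
totals imply mortality and cost allocations the printed inputs do not
determine. The shipped `model_calibrated.yaml` closes exactly the two
under-determined gaps, using only declared knobs and assignment data:

* long-term (cycle ≥ 2) annual death probabilities, solved per arm to the
  published QALY totals: TAVI 0.2236, SAVR 0.3332 (bisection on the
  monotone QALY–mortality relation, `scripts/calibrate.py`);
* valve-cost procedure-phase weights, solved per arm to the published
  cost totals: TAVI 0.2123, SAVR 0.3096 (costs are affine in the weight).

The calibrated model reproduces the published base case to <0.001 %
(ICER 995,082,681 vs 995,081,354 IRR/QALY) and, with no further tuning,
its PSA ratio-of-means ICER lands within 1 % of the published
probabilistic mean. The calibrated acceptability curve is steeper than
the published one (≈0.00/0.92 vs 0.31/0.83 at 1×/3× GDP): utilities are
sampled once and shared by both arms here, which cancels much of the
between-arm effect uncertainty; the original's draw-level correlation
structure is unknown. Four calibrated constants resolve four published
totals, so the calibration demonstrates *consistency* of the structure
with the published results, not independent validation.

## Numerical conventions

* Rewards at end of cycle; discount exponent = cycle index; cycle length
  1 year by default (general lengths convert rates/probabilities by
  constant hazard, and the one-year case is handled exactly).
* Entry rows and traces are conserved to 1e−9; transition rows to 1e−12.
* Probability/moment conversions round-trip to 1e−9 relative or better;
  infeasible Beta variances are errors, never clipped.
* Display rounding (whole Rial, whole dollars half-up, QALYs to two
  decimals, threshold ratios to one) never feeds back into computation.

## Known limitations

* No age-dependent background mortality, no tunnel states beyond the
  stroke split, exactly two strategies.
* Long-term mortality and the valve-cost split are calibrated, not
  evidence-based; any conclusion sensitive to them should be re-run over
  `death_table` and assignment-weight ranges.
* The stroke disutility model (absolute, floored, deferred one cycle) is
  one of several defensible readings.
* Event probabilities as five-year cumulative values is an
  interpretation; `event_annualization` exposes the alternative.
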