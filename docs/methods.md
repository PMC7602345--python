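# Methods

`burnsim` couples four computational pieces: a Lund–Browder TBSA assessment
workflow, an inter-rater accuracy analysis, a burn-triggered acute-inflammation
ODE model, and a lumped fluid/cardiovascular model with a guideline
resuscitation controller on top. This note records the models, the defaults and
why they hold, the numerical choices, and what the synthetic pieces do and do
not represent.

## Lund–Browder assessment

The chart is configuration, not code: `data/lb_chart_adult.json` carries the
standard adult region fractions (20 regions summing to 1) under an `age_bands`
key so pediatric columns can be added without touching code. TBSA is the
surface-weighted sum of per-region burned fractions, split into
partial-thickness (2nd degree) and full-thickness (3rd degree); interfaces use
percent (0–100), internals use fractions.

Random virtual burns are generated constructively rather than by rejection:
an exact target total is drawn uniformly inside the requested range, regions
are visited in a seeded surface-weighted random order and burned whole until
the remaining budget is smaller than the next region, which is then partially
burned to land exactly on the target. Each region's burned area is split
between depths by a seeded draw of the full-thickness share (default range
0.2–0.7). This is always feasible, always in range, and a pure function of
(chart, ranges, seed). It does not model spatial contiguity of real burn
patterns — regions are statistically independent apart from the total
constraint — so generated patterns are suitable for scoring arithmetic and
training workflows, not for studying burn geometry.

## Rater-accuracy statistics

For each record the signed error is reported − generated, per category (2nd,
3rd, total). The fidelity hypothesis is one-sided: H0: μ = μ0 against
HA: μ < μ0, with μ0 = 5% for the depth categories and 10% for the total. Two
deliberately nonstandard conventions are frozen because they are the
conventions of the original rating study this module reproduces:

* **Population SD** (divisor n) both in the reported descriptive and inside
  t = (mean − μ0)/(sd/√n). The usual sample-SD t differs by the factor
  √(n/(n−1)); a test asserts that algebraic relation against
  `scipy.stats.ttest_1samp` on random vectors.
* **One-sided lower-tail p** from Student's t with n − 1 degrees of freedom.

With the shipped nine-record study this yields means 3.8/−0.1/3.7, SDs
2.5/3.9/4.5, t −1.41/−3.96/−4.20 and p 0.0982/0.0021/0.0015. The shipped CSV
is checksum-pinned in the test suite. n = 9 records are treated as
exchangeable; no rater/picture hierarchy is modelled.

## Acute-inflammation model

A reduced Reynolds/Chow-class system, driven by sterile thermal trauma (all
infection inputs identically zero). States: trauma stimulus TR (initialized to
the TBSA fraction, first-order decay at 0.02/h), activated macrophages M and
neutrophils N, cytokines TNF, IL-6, IL-10, nitric oxide NO (all dimensionless
elevations over a zero healthy baseline) and tissue/endothelial integrity
D ∈ [0, 1].

Structure: M and N activate through a steep Hill function (exponent 4,
half-saturation 0.30) of TR plus weak TNF feedback, inhibited by IL-10; TNF
and IL-6 are produced by the activated cells; IL-10 follows IL-6 through a
*Michaelis–Menten* (exponent 1) saturation — proportionally strong for small
bursts, saturated for large ones, which is what makes the peak-IL-10 : peak-TNF
ratio fall with burn size (the anti-inflammatory brake is overwhelmed by large
burns). NO follows N and TNF. Integrity obeys
dD/dt = k_heal(1 − D) − k_dmg · D · Hill(w) with w a weighted pro-inflammatory
load and a steep Hill (exponent 6, half-saturation 1.5), so small burns sit
below the damage threshold entirely.

Rate constants (units 1/h, defaults in `InflammationParams`) were calibrated
jointly with the hemodynamic maps against the reference trajectories below;
the observable contract, not any individual constant, is the validated
surface. Resulting integrity nadirs: ≈1.00 at 10% TBSA, ≈0.82 at 25%, ≈0.31
at 40%, with the 40% collapse developing within the first two hours.

## Fluid and cardiovascular model

Two fluid compartments: vascular plasma (baseline 3 L inside a 5 L blood
volume) and interstitium (10.5 L). Starling exchange:

J = (P_cap − P_int − σ(COP_p − COP_i)) / R_leak,  σ = 0.9.

* COP(c) = 0.21 c + a₂ c², with a₂ fixed so baseline albumin (42 g/L) gives
  25 mmHg — a convex Landis–Pappenheimer-like law.
* P_cap tracks MAP linearly between a floor of 6 mmHg (exchange does not stop
  in deep shock) and 20 mmHg at baseline; P_int rises with interstitial
  over-filling at 0.4 mmHg/L.
* Albumin moves by solvent drag ((1 − σ) × upwind concentration) plus
  diffusive clearance PS(D); lymph returns fluid and albumin at interstitial
  concentration, scaling with (V_i/V_i0)².
* **Derived closure:** baseline lymph flow and PS are solved so the healthy
  baseline is an exact fixed point — filtration = lymph and albumin fluxes
  balance identically. The homeostasis test holds to machine precision over
  48 h because of this, not because of tuning.
* Damage maps: R_leak = R₀(0.03 + 0.97 D⁵) and PS = PS₀(1 + 120 (1 − D)^1.5).
  Both continuous, monotone, bounded away from zero.
* A capillary-derecruitment factor V_p²/(V_p² + 0.3²), normalized to 1 at
  baseline, shuts exchange down as the plasma compartment empties; without it
  the 40% scenario would drain the plasma volume below zero.

Cardiovascular closure: stroke volume proportional to stressed blood volume
(unstressed 3 L, smoothed positive part normalized to 1 at baseline),
CO = 5 L/min × (HR/72) × SV_rel, MAP = 90 mmHg × (CO/CO₀) × SVR_rel. A
sigmoidal baroreflex (tanh in the fractional MAP error, shoulder at 25%,
gains 0.9 on HR and 0.7 on SVR, time constant 3 min) drives HR and SVR
multipliers toward pressure-restoring targets; it saturates, so severe
hypovolemia decompensates. NO divides SVR (vasodilation).

Renal output is UO₀ × f(MAP) × (V_p/V_p0), with f rising from an anuric floor
at 50 mmHg and capped at 1 above baseline pressure (autoregulation), divided
by sympathetic (epinephrine) and injury (1 + 6(1 − D)) suppression terms —
the model's version of downregulated filtration and increased reabsorption
after the burn. A constant maintenance intake equal to baseline urine output
(60 mL/h) keeps the healthy kidney in balance; it is counted in the
conservation bookkeeping and kept separate from protocol fluid.

Pain scales with TR (10/10 at ≥ 33% TBSA), raises epinephrine (which raises
HR/SVR targets and respiration) and is divided down by analgesia. Ketamine is
an effect-site state (20 mg ≡ 1.0, elimination 1/h) that suppresses pain —
lowering respiratory rate — and acts as a sympathomimetic, adding to
epinephrine so MAP transiently rises after a bolus. The pressor response is
the reference behaviour in healthy subjects; in a real burn patient with
maximal sympathetic tone it would likely be blunted, and this is documented
as a known model discrepancy rather than corrected.

## Resuscitation controller

Lactated Ringer's starts at 10 × TBSA(%) mL/h. At every whole-hour boundary
the controller inspects the mean urine output over the completed hour
(hourly averaging is a design choice; the guideline specifies only "every
hour") and multiplies the rate by 1.25 if UO < 30 mL/h, by 0.75 if
UO > 50 mL/h, holding inside the inclusive band. Rates are piecewise constant
and every decision time is an integration break, so cumulative fluid equals
the exact sum of hourly rates. Treatment start time is configurable
(default: at injury). The Parkland formula (4 mL × kg × TBSA%, half in the
first 8 h) is computed as a reference diagnostic only.

Under the defaults the treated 25% run holds 250 mL/h for two hours (UO in
band), escalates from hour 3, delivers 3.31 L by hour 8 and brings hourly UO
back into 30–50 mL/h at hour 11, after which late over-infusion triggers
down-titration — the same qualitative arc as the reference engine, including
its noted late liberality.

## Calibration targets and frozen defaults

The free constants (inflammation rates, damage→leak maps, renal suppression)
were fitted once, jointly, to the reference outcomes: a compensated 10% burn
(MAP within 10% of baseline for 24 h), ≈1 L plasma loss by hour 5 at 25%
(model: 0.98 L), ≥50% blood-volume loss by hour 3 at 40% untreated (model:
51%), ≈3.4 L protocol fluid in the first 8 treated hours at 25% (model:
3.31 L) and urine output re-entering the target band shortly after hour 10
(model: hour 11). The defaults are frozen; the acceptance script recomputes
the protocol quantities from scratch at run time.

## Numerics

LSODA (stiff-capable, adaptive) with rtol 1e-7, atol 1e-9 and max step 0.25 h,
integrated piecewise between infusion-rate changes and drug boluses so control
discontinuities never cross a step. State positivity is enforced by the
model structure (fluxes vanish as compartments empty); D is clamped to [0, 1]
on output. Tightening tolerances by two orders changes 24-h endpoints by
< 0.1%. The ODEs are deterministic — seeds only affect burn-pattern
generation, which uses `numpy.random.default_rng` exclusively.

## Scope and limitations

One vascular and one interstitial compartment stand in for the reference
engine's many organ compartments; every validated output (MAP, HR, volumes,
UO) is whole-body, so the lumping is identifiable at this scale. Not modelled:
electrolytes, evaporative wound loss (config flag exists, off by default),
colloid rescue, blood products, escharotomy, infection/sepsis dynamics, and
any spatial wound geometry. The inter-rater module computes fixed-convention
descriptive statistics, not reliability coefficients. Synthetic cohorts
exercise the scoring arithmetic and controller logic; they do not emulate the
visual or geometric properties of real burn photographs, so passing tests
speak to the computational pipeline, not to visual fidelity of any renderer.
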