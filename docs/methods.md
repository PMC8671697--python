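# Methods

## Model structure

A deterministic cohort (state fractions, no microsimulation) moves through
three mutually exclusive states — progression-free (PFS), progressed (PD),
dead — in 1-month cycles over a 60-cycle (5-year) horizon. Everyone starts
in PFS; death is absorbing. Time-to-event in each arm is Weibull,
`S(t) = exp(−λ t^γ)` with `λ` in month^−γ, and the conditional per-cycle
transition probability is `P(t) = 1 − S(t)/S(t−1)`. Shape `γ > 1` (all four
fitted endpoints) means a hazard that rises with time, which is what makes
the per-cycle probabilities non-decreasing.

Transitions out of PFS: progression at `max(0, P_pfs(t) − bg)` and death at
the background rate `bg = 1 − (1 − 0.00707)^(1/12)` (the compounded monthly
version of the 0.707%/yr all-cause rate). Netting `bg` out of the PFS curve
avoids double-counting deaths that the curve itself already contains; the
subtraction is a config switch (`subtract_bg_from_progression`).

### Death after progression (`pd_death_rule`)

The trial's OS curve measures the whole cohort's survival, not the PD
state's hazard, so some construction is needed:

* `os_calibrated` (default): each cycle the PD death probability is solved
  so that total deaths equal `alive × (1 − S_os(t)/S_os(t−1))` after
  background deaths in PFS are counted, clipped to [0, 1]. The alive
  fraction then tracks `S_os(t)` to well under a percentage point, which is
  exactly the quantity the trial reports. This is the default because the
  alternative demonstrably over-fills the PD state: applying the OS hazard
  only to PD occupants leaves the model cohort alive markedly longer than
  the OS curve it was fitted to (PD QALYs ≈ 0.39 instead of ≈ 0.25 in the
  intervention arm).
* `os_hazard`: apply `P_os(t)` directly to PD occupants. Kept as a switch
  for comparison and for models whose OS source really is a
  post-progression curve.

### State membership and half-cycle handling (`membership`)

Rewards for cycle `t` accrue on:

* `cycle_start` (default): the occupancy entering the cycle — the
  convention of cycle-tree cohort software, crediting within-cycle
  transitioners with the full cycle. Chosen as the default because the
  per-arm totals of the reference analysis (built in such software) imply
  roughly half a cycle more state credit per arm than the trapezoid gives;
  with this convention the model reproduces those totals to within a few
  percent.
* `trapezoidal`: the classic half-cycle correction, averaging the
  occupancies at the cycle's boundaries (≈ the continuous-time integral).
* `cycle_end`: occupancy after transitions.

One-time quantities are exempt from the membership convention: SAE
management cost attaches to the entering cohort at cycle 1, terminal care
to the incident-death fraction in its cycle.

## Costs and QALYs

All costs in 2020 USD ($1 = ¥6.9). Per progression-free cycle: drug
acquisition plus routine follow-up ($73.57) plus laboratory/radiology
($356.60; `labs_accrual` can move this to a one-time cost). Per progressed
cycle: salvage therapy ($638.43) plus best supportive care ($167.29).
One-time: SAE management (Σ incidence × unit cost over anemia, WBC
decrease, neutrophil decrease — $414.42 intervention, $424.49 control) and
terminal care ($1,460.30). Utilities 0.68/0.42 per year, so a cycle
contributes `u/12`; discounting is `(1+0.03)^(−t/12)` applied to the cycle
index.

Chemotherapy doses scale with body surface area (1.72 m²): paclitaxel
175 mg/m² → 301 mg, cisplatin 75 mg/m² → 129 mg per administration;
camrelizumab is flat 200 mg. Drug prices are per vial-size unit
(e.g. $108.26/100 mg paclitaxel); the default charges fractional units,
with ceiling-to-whole-vials available (`vial_rounding`).

The 3-weekly schedule is bridged into the monthly cycle by costing
`(365.25/12)/21 ≈ 1.449` administrations per month (`bridging:
calendar`; `per_cycle` charges exactly one administration per cycle).
Chemotherapy carries a 6-administration budget drawn down on that
calendar — its cost runs out during cycle 5 — while camrelizumab continues
as long as the patient is progression-free. All drug costs are weighted by
PFS membership, so patients who progress stop paying for first-line drugs.

## Sensitivity analyses

* One-way (tornado): every distribution-listed parameter plus a synthetic
  `pfs_duration` scale is pushed to its bounds (printed ranges where the
  source tables give them — ±20% for costs/risks/BSA, 0.54–0.82 and
  0.34–0.50 for utilities, 0–8% for the discount rate — otherwise ±20% of
  base), the full model re-run, and entries ranked by ICER span.
  `pfs_duration` multiplies the PFS median of both arms by `s` via
  `λ → λ·s^(−γ)` with `γ` fixed.
* Probabilistic (PSA): 1000 joint draws by default; triangle distributions
  for costs and BSA (numpy's inverse-CDF triangular on low/mode/high), beta
  for utilities and SAE risks moment-matched to mean = base and
  SD = (high − low)/(2·1.96), the discount rate held fixed. Infeasible beta
  moments fall back to uniform(low, high) with a logged warning. Weibull
  parameters are not sampled, matching the stated sampling pattern of the
  reference analysis. All randomness flows through one `numpy.random.
  default_rng(seed)`; identical seeds give bitwise-identical draws.
* CEAC: fraction of draws with strictly positive net monetary benefit
  `w·ΔQALY − ΔCost` over a $0–100k grid in $1k steps; ties count as not
  cost-effective.
* Threshold price: bisection on the deterministic ICER-vs-price curve until
  the re-run ICER is within $1/QALY of the target, with an explicit
  bracket-sign check.

## Weibull fitting

`fit_weibull` does nonlinear least squares on `S(t)` directly (scipy
`curve_fit`, optimizing `log λ` for positivity), initialized by OLS on the
complementary log-log line `log(−log S) = log λ + γ log t`. Two usable
points are solved exactly by the linearized system; fewer raise. Points at
survival exactly 0 or 1 are excluded from the linearized loss (log
undefined) but kept in the direct loss; `t = 0` is always dropped. SEs come
from the fit covariance (delta method back to the λ axis), 95% CIs as
±1.96·SE. The estimator behind the published Table-1 parameters is not
stated, so its SEs are not reproduced exactly; base-case analyses consume
the published parameters directly, and the fitter is validated by parameter
recovery (noiseless round-trip to 1e−6 relative; median error < 10% at
digitization noise SD 0.01 over 20 seeds).

## Synthetic data

`generate_km_points` emulates graph-digitizer output: evenly spaced
readings of a known Weibull curve plus independent Gaussian error on the
survival axis (default SD 0.01 ≈ one axis percentage point, monthly
density), clipped, rounded, forced monotone, with the exact (0, 1) anchor.
It does not emulate censoring structure, risk-table-informed step
locations, or correlated reading error — so passing recovery tests show the
fitter handles digitization-scale noise, not that it reconstructs true
patient-level uncertainty. `generate_scenario` builds random admissible
two-arm configurations (shapes 0.8–2.5, PFS medians 3–24 months, OS median
≥ PFS median per arm, u_pfs > u_pd, PSA-ready distributions) for
property-style pipeline tests.

## Numerical choices and limitations

* Occupancy rows are conserved to 1e−9 and checked in tests; the engine is
  an explicit 60-iteration loop (milliseconds per run; a 1000-draw PSA
  takes ~3 s).
* The ICER is computed on unrounded deltas; dominance and zero-ΔQALY cases
  return flags rather than ratios.
* The calibrated death rule clips the PD death probability to [0, 1]; in
  the first cycle (empty PD state) the OS-implied deaths cannot all be
  realized, leaving the alive fraction ≈ 0.5% above `S_os` thereafter —
  visible only below the 0.01 tolerance asserted in tests.
* Quantitative agreement with the reference analysis is within ±10% on
  every headline quantity (most within ±7%); exact agreement is not
  attainable because several accrual conventions above are not printed in
  the source tables and had to be chosen here.
* Not modeled: SAE disutilities, subsequent-line immunotherapy, age-varying
  background mortality, alternative parametric survival families, and
  societal-perspective costs.
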