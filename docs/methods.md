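# Methods

## Model structure and assumptions

The model is a three-state partitioned-survival cohort model (PFS → PD →
death, no recovery) on 21-day cycles. Occupancy is read directly off the
two arm-specific Weibull curves: the death fraction is 1 − S_OS(t), the
PFS fraction is S_PFS(t) capped at the surviving fraction (extrapolated
PFS can cross OS far in the tail; the cap count is reported on the
occupancy object), and PD is the remainder. We chose the partitioned
construction over an explicit transition matrix because the published
inputs (two curves per arm) fully determine it, whereas a three-state
transition matrix would additionally need an unpublished split of PFS
exits into progression versus death. The two readings coincide in the
quantities the model accrues (state time and deaths), since any Markov
trace calibrated to the same two curves reproduces the same occupancy.

Implicit assumptions inherited from this construction: progression and
death risks are fully described by the trial-fitted curves (no cure
fraction, no treatment-effect waning beyond what the Weibull shapes
encode), and post-progression management is uniform best supportive care.

## Survival inputs

Weibull parameterization S(t) = exp(−λ·t^γ) with t in cycles. The
implied SIDCHM median OS is ≈25.96 cycles ≈ 17.9 months, the right
magnitude against the trial's 16.7-month median — which pins the time
unit (month- or day-based interpretations of the printed λ, γ are off by
large factors). The 99 %-death horizon lands at 114 cycles (≈6.5 years),
matching the stated ~6-year run time; a hard cap (default 160 cycles)
guards pathological configurations and is reported as a warning, not an
error.

Background all-cause mortality enters as a per-cycle hazard floor on
death, defaulting to a constant annual probability of 0.007 (an
age-indexed table can be supplied via config). For these curves the
OS-derived hazard exceeds the floor from the first cycle, so the floor
changes totals by well under $1 / 1e−3 QALY — the hook exists for
flatter-survival configurations.

## Accrual conventions

Where the source analysis is silent we fixed conventions once, as
follows, and exposed each as a setting:

* **State membership during a cycle** is the occupancy at the cycle
  start, discounted at cycle end (the TreeAge-style default). A
  half-cycle correction (averaging adjacent occupancies) is available
  but off by default. Start-of-cycle accrual reproduces the published
  per-arm QALYs to ~0.01.
* **Laboratory/radiology tests ($358.03) and follow-up ($73.86) accrue
  per cycle in both alive states** (settings `tests_in_pd`,
  `followup_in_pd`). Applying tests only during PFS leaves both arms'
  totals 16–23 % below the published costs; with the default, per-arm
  costs reproduce to within ~3 %. We read this as how the original
  model was costed.
* **Drug pricing is linear per mg** (no vial wastage); a vial-rounding
  mode (ceil to whole 100 mg vials) is available. Chemotherapy doses
  scale with a fixed 1.72 m² body surface area; the regimen mix (93 %
  cisplatin+paclitaxel / 7 % cisplatin+fluorouracil) weights the
  expected chemotherapy cost. Chemotherapy stops after 6 cycles;
  sintilimab after 35 cycles (the 24-month cap in whole cycles,
  configurable).
* **Adverse-event management** is an incidence-weighted lump sum at
  model entry (timing is unpublished); **end-of-life care** attaches to
  the newly dead fraction each cycle and is discounted at that cycle,
  consistent with "costs and utilities were discounted".

## Sensitivity analyses

One-way analysis sweeps every tabulated parameter to its printed bounds
(probability-like bounds clamped into [0, 1], e.g. the paclitaxel
proportion's printed max of 1.12; each clamp is logged). Survival-curve
parameters are not swept — no ranges were published for them. Ordering is
by descending ICER swing, ties alphabetical.

The PSA samples Beta (probabilities, utilities, proportions), Gamma
(costs) and zero-truncated Normal (BSA) distributions by moment matching:
mean = base value, SE = (high − low)/2. Every tabulated range is exactly
base ± 20 %, i.e. a plausibility band rather than a 95 % CI, so we read
it as mean ± one SD (equivalently SE = 20 % of the mean, the usual
convention in this literature). This choice is empirically decisive: it
yields a probability of cost-effectiveness at the WTP of ~0.88 against
the published 86 %, whereas treating ranges as 95 % CIs
(SE = range/3.92, available as `se_rule="ci95"`) makes the PSA nearly
deterministic relative to the decision margin (~0.99). An infeasible
Beta moment match falls back to the tighter rule, then to the base
value. The discount rate is sampled as Fixed, per the published table.
One seeded generator spawns per-iteration substreams, so results are
bit-reproducible per seed and iteration-order independent.

Subgroups rebuild the treatment arm from the comparator baseline under
Weibull proportional hazards — scale multiplied by the subgroup HR,
shape unchanged (exactly S^HR) — separately for OS and PFS; the
comparator keeps the overall curves. Subgroup-level acceptability
additionally samples the HRs log-normally from their published 95 % CIs.

## Synthetic data

The published Weibull inputs came from digitized Kaplan–Meier curves;
the synthetic-data module emulates that stage: inverse-CDF simulation of
patient-level times, administrative censoring (optional uniform
dropout), product-limit estimation, and censored maximum likelihood on
the same S(t) = exp(−λt^γ) parameterization (optimized in log-parameter
space; Wald errors from the numerical Hessian). What it does not emulate:
digitization error, reading-off granularity, and number-at-risk
reconstruction — so parameter-recovery tests validate the fitting and
modelling machinery, not the accuracy of curve digitization on real
figures. At n = 500 with ~30 % censoring the scale estimate is noisy
(median absolute relative error ~15 %, scale and shape being strongly
anticorrelated) but nearly median-unbiased; the recovery test therefore
checks the signed median bias over 50 replicates (< 5 %), with seeds
fixed as the replicate index.

## Numerical notes

* Conditional event probabilities use q(t) = 1 − S(t)/S(t−1), returning
  1 by convention once S underflows.
* Occupancy conserves probability mass to 1e−12 per cycle; the
  exponential special case (γ = 1) matches the closed-form
  two-compartment solution to 1e−10.
* Tail truncation: at the default 99 %-death horizon the surviving 1 %
  still accrues a few hundred dollars; totals are converged to $0.01 /
  1e−5 QALY only once the surviving fraction is below ~1e−7 (≈300
  cycles). The default horizon matches the published convention rather
  than full convergence.
* ICERs are reported to 2 decimals; when the signs of ΔC and ΔE imply
  dominance the conventional label replaces the ratio, and ΔE = 0 leaves
  the ICER undefined.

## Problem sizes

Deterministic runs use the 114-cycle horizon; the PSA uses 1000
Monte-Carlo replications (as published); parameter-recovery checks use
50 replicates of n = 500 patients plus single large-n checks (n = 5000
fits, n = 10,000 Kaplan–Meier uniform-convergence check).

## Known limitations and divergences

The published results table is internally inconsistent: per-arm values
(1.03 vs 0.67 QALYs; $24,044.49 vs $14,166.24) give ΔE = 0.36 and
ΔC = $9,878.25, yet the printed ICER of $23,458.08/QALY implies
ΔE = 0.4211. This model reproduces the per-arm costs and QALYs and the
incremental cost, and consequently lands the ICER near
$9,878/0.36 ≈ $28.3k, not the printed $23.5k. No accrual convention we
found raises ΔE to 0.42 while preserving the per-arm values.

Two published subgroup rows are similarly irrecoverable: the age<65 row
prints the table's lowest ICER with its least favourable hazard ratios
(no monotone HR method can do that, and the running text attributes that
ICER to an "age ≥ 50" subgroup absent from the table), and the CPS<1 row
prints a positive $107.7k ICER although HR_os = 1.32 > 1 makes the
treatment arm lose life-years in any survival-consistent model (we find
it dominated — costlier and less effective — which agrees with the
qualitative published conclusion that CPS<1 is the one subgroup where
the combination is not cost-effective). The remaining 21 published
subgroup ICERs are reproduced within ~8 %.
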