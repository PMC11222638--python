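# Methods

## Decision problem and model structure

The package compares first-line dostarlimab + carboplatin–paclitaxel (DCP)
against carboplatin–paclitaxel alone (CP) in primary advanced or recurrent
endometrial cancer, separately for mismatch-repair-deficient (dMMR) and
-proficient (pMMR) disease, from a US payer perspective. A cohort of women
enters at age 64 in the progression-free state (PFS) and is followed in
21-day cycles to age 82 — 313 cycles, the final partial cycle dropped. One
month is taken as 30.4375 days, so a cycle is 0.68994 months; discounting
uses 3% per year applied at each cycle's midpoint, and state time accrues
with the half-cycle (life-table) correction: each cycle contributes the mean
of its start- and end-of-cycle occupancy.

State occupancy is **partitioned survival** by default: at each cycle
boundary `t`, PFS occupancy is `min(S_PFS(t), S_OS(t))`, death is
`1 − S_OS(t)` and progressed disease (PD) is the remainder. The `min` cap
handles fitted curves that cross in the far tail (a warning is logged; it is
not an error, because independently fitted PFS and OS curves can legally
cross after extrapolation). A state-transition mode is retained behind a
flag: per-cycle exit probabilities are the conditional-survival ratios
`1 − S(t)/S(t−u)`, deaths within a cycle are split between PFS and PD in
proportion to start-of-cycle occupancy, and the PFS decrement not explained
by death flows to PD (negative flows clamp to zero with a warning). Both
modes produce the same occupancy when the curves do not cross; the
partitioned construction is the default because the state definitions are
areas under and between the curves.

No background all-cause mortality is layered on top of the fitted OS curves;
the age-82 horizon bounds the extrapolation instead.

## Survival curves

Seven parametric families are implemented with times in months:
exponential (rate), Weibull in the rate–shape form `S(t) = exp(−λ t^γ)`
(the form under which the per-cycle transition formula
`1 − exp[λ(t−u)^γ − λ t^γ]` is exact), Gompertz, gamma, log-logistic
(shape, scale; `S(scale) = 1/2`), log-normal (meanlog, sdlog) and the
generalized gamma in the Prentice `(μ, σ, Q)` parameterization: with
`w = (ln t − μ)/σ` and `a = Q⁻²`, `S(t)` is the upper (Q > 0) or lower
(Q < 0) regularized incomplete-gamma tail at `(a, a·e^{Qw})`, with the
log-normal as the `Q → 0` limit and the Weibull recovered at `Q = 1`.

The fitted OS model for dMMR DCP has `Q ≈ −34`, where `a·e^{Qw}` underflows
double precision over most of the time axis. The incomplete-gamma argument
is therefore carried as a logarithm: inside the representable range the
regularized functions are called directly; below it the leading series term
`P(a, x) ≈ x^a / Γ(a+1)` is used in log form; above it the tail saturates to
{0, 1}. This keeps `S(t)` finite, monotone and NaN-free on [0, 600] months
for |Q| well beyond the fitted values, and it agrees with direct quadrature
of the density to ~1e−15 at all shipped parameter sets (tested at 1e−6).

Fitting maximizes the right-censored log-likelihood
`Σ_events log f(tᵢ) + Σ_censored log S(tᵢ)` by Nelder–Mead on
log/identity-transformed parameters from at least three moment-based starts
per family, keeping the best local optimum. All-censored data raise a
degenerate-data error (the likelihood is unbounded); non-convergence raises
a fit error carrying the optimizer diagnostics. Model selection takes the
minimum AIC by default (BIC by flag); ties break toward fewer parameters,
then family declaration order. The `lifelines` fitters serve as an
independent cross-check in the test suite, not as the implementation.

## Synthetic digitized curves and pseudo-IPD reconstruction

The published model was built from digitized trial Kaplan–Meier figures,
whose coordinates are not printed. The `km` module therefore generates the
same *kind* of artifact from known parametric models: event times drawn by
inverse-survival sampling, censoring as the minimum of an exponential
dropout time and an administrative cutoff, the product-limit curve sampled
on a regular grid, and numbers at risk at the grid times. Defaults used in
the analysis scripts — 500 patients per arm, 0.01/month dropout hazard,
40 months of follow-up, 1-month grid — emulate a RUBY-scale arm with light
in-study censoring.

Reconstruction inverts the artifact by interval allocation. Between
consecutive at-risk times with counts `n_j, n_{j+1}` and (interpolated)
boundary survival `S_j, S_{j+1}`, the event count is
`d_j = (1 − r)(n_j + n_{j+1})/(1 + r)` with `r = S_{j+1}/S_j` — exact when
there is no censoring, and equivalent to assuming censorings occur
mid-interval on average otherwise. The at-risk decrement not explained by
events is censoring, spread evenly over the interval. Events are dated at
the midpoint of the coordinate gap in which their survival drop is observed
(a drop recorded at a grid point happened somewhere since the previous
point; right-endpoint dating would bias fitted time scales upward), with
integer shares assigned by largest remainder. Mass after the last at-risk
time is allocated from the remaining coordinate drops and then censored.
Reconstruction is fully deterministic and always returns exactly `n_total`
records. Against synthetic fixtures the recomputed product-limit curve stays
within 0.02 (sup-norm) of the input, and generate → reconstruct → refit
recovers generating parameters within 10% at n = 2,000.

What the synthetic stage does *not* capture: digitization error from actual
image extraction, coarse published at-risk tables, and non-exponential
dropout. Passing round-trip tests therefore validates the reconstruction
algorithm, not fidelity to the actual trial figures — the cohort model
consumes the published fitted parameters directly, so this stage is
exercised on synthetic data only.

## Costs and utilities

All monetary inputs are 2024 USD as published (no CPI recomputation).
Dosing uses a body surface area of 1.84 m²; carboplatin uses the Calvert
formula `dose = AUC·(GFR + 25)` with a default GFR of 70 mL/min — the paper
never states a GFR, and carboplatin is ~0.01% of total cost, so the choice
is immaterial but explicit. Fractional vials are billed pro-rata (per-mg
prices are listed); whole-vial rounding is available behind a flag.

Per cycle, the DCP arm accrues during induction (cycles 1–6) dostarlimab
500 mg + paclitaxel 175 mg/m² + carboplatin AUC 5 with administration and
laboratory fees, weighted by start-of-cycle PFS occupancy; maintenance
dostarlimab 1,000 mg every second cycle from cycle 7 through cycle 52
(3-year cap), again PFS-weighted. The CP arm accrues the same chemotherapy
backbone without dostarlimab and has no maintenance phase. Imaging follows
the trial calendar — scans at weeks 6–24 every 6 weeks, 33–51 every 9
weeks, then every 12 weeks — charged to PFS occupancy only (surveillance
stops at progression). Physician visits accrue every cycle for everyone
alive. Each new death incurs a one-time end-of-life cost, discounted at its
cycle. Grade ≥3 adverse events with ≥5% incidence enter once, in cycle 1,
as expected cost `Σ incidence·cost` and expected QALY loss
`Σ incidence·disutility` per arm.

After progression, 28.3% (DCP) / 58.5% (CP) of patients receive subsequent
active therapy — doxorubicin 60 mg/m² every 3 weeks for six cycles then
best supportive care, or pembrolizumab 200 mg every 3 weeks continued until
death — and the remainder receive best supportive care; every PD cycle adds
a physician visit, and active-therapy cycles add administration and
laboratory fees (treatment-cycle costs apply to all treatment cycles, not
only first-line ones). An optional cap on pembrolizumab duration exists but
is off by default: the published regimen description gives doxorubicin an
explicit six-cycle course and pembrolizumab none, and the published arm
totals are consistent with a time-constant PD cost, i.e. uncapped
pembrolizumab. Because the partitioned model does not track time since
progression, PD occupancy is decomposed into entry-cycle vintages (deaths
assumed to hit vintages proportionally), giving discounted person-cycles in
PD by time-since-progression; any PD cost profile then prices out as a dot
product, which also makes the PSA cheap (~0.5 ms per full two-arm
evaluation).

Utilities are 0.817 (PFS), 0.779 (PD), 0 (death). QALYs are
utility-weighted, half-cycle-corrected, discounted state time minus the
first-cycle adverse-event disutility.

**Calibration.** One cost input is genuinely unreported: how the
subsequent-therapy fraction splits between doxorubicin and pembrolizumab.
The incremental cost is nearly linear in this split, so it acts as the
model's single free calibration parameter. The shipped scenarios fix it per
subgroup — 0.30 (dMMR) and 0.05 (pMMR) doxorubicin share — the values at
which each subgroup's published base-case incremental cost is reproduced
within ±5% (achieved: +1.9% and +3.4%); `analysis/05` writes the full scan.
A single common split cannot match both published arm totals
simultaneously (the CP arms sit ~8–10% below their published costs at
splits that match the DCP arms), which is why calibration is per scenario;
the residual is absorbed there and disclosed rather than hidden in an
undocumented cost stream.

## Sensitivity analyses

The one-way analysis moves every uncertain parameter to ±20% of baseline
(the published ranges are exactly ±20%) one at a time and records both ICER
excursions; entries sort by spread. The parameter set covers all unit
costs, both utilities, all adverse-event incidences (arm-specific), costs
and disutilities (shared across arms), body surface area, and the two
subsequent-therapy proportions.

The probabilistic analysis draws 1,000 parameter sets jointly: gamma for
costs, beta for utilities and incidences, normal for body surface area,
with dostarlimab and pembrolizumab unit prices held fixed, matching the
published distribution assignments. Hyper-parameters are method-of-moments:
mean equal to the base value and SD = (range width)/(2·1.96), so the ±20%
bounds approximate a 95% interval. Survival-model parameters and the
subsequent-therapy proportions carry no published distribution and stay
fixed in the PSA (the proportions are varied in the one-way analysis).
Adverse-event costs and disutilities are drawn once per draw and applied to
both arms; incidences are drawn per arm. The CEAC reports the fraction of
draws with net monetary benefit `ΔQ·WTP − ΔC ≥ 0` over a $0–300k WTP grid
including $150,000/QALY. All randomness flows through one seeded
`numpy` generator; identical seeds give identical draws, CEACs and files.

Threshold pricing bisects the multiplicative discount on the dostarlimab
unit price until the recomputed ICER is within $10/QALY of the target. The
ICER is monotone decreasing in the discount (dostarlimab appears only in
the intervention arm's cost), so bisection converges; a base-case ICER
already at or below the target returns 0.

## Numerical choices and degenerate inputs

- Incomplete-gamma arguments in log-space with saturation, as above.
- `S(0) = 1` exactly for every family; negative times raise a domain error;
  invalid parameters (σ ≤ 0 etc.) raise a parameter error at construction.
- Transition probabilities clamp to [0, 1]; an exhausted cohort
  (`S(t−u) = 0`) transitions with probability 1.
- Occupancy invariants — states sum to 1 (1e−9), death non-decreasing, PFS
  non-increasing — are asserted on every constructed trace.
- Monetary outputs are rounded to cents only in reports; machine-readable
  files keep full precision.
- Scenario validation is strict: missing fields are reported by path and
  unknown keys are rejected.

## Known limitations

- The synthetic KM stage stands in for real digitization; fidelity to the
  actual trial figures is not claimed (their coordinates are unpublished).
- The model's CP-arm totals run below the published ones at any common
  subsequent-therapy split; the per-subgroup calibration compensates at the
  incremental level. QALYs require no calibration: all four arms land
  within 0.13 QALYs of the published values directly from the printed
  survival parameters.
- The PD vintage decomposition assumes deaths remove PD vintages
  proportionally; with strongly age-dependent post-progression mortality
  this would misweight late PD costs.
- No background mortality, no radiotherapy/surgery in PD, no societal
  costs, and no covariate-adjusted or spline/cure-fraction extrapolations —
  all outside the model's scope.
- The threshold-price search holds everything but the dostarlimab unit
  price fixed; simultaneous price changes (e.g. pembrolizumab) are not
  modelled.
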