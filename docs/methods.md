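# Methods

`pedallo` is a simulation–estimation toolkit: it generates virtual pediatric
and adult body-weight populations, simulates monoclonal-antibody (mAb)
pharmacokinetics under a known allometric population model, re-estimates the
model — allometric exponents included — with a nonlinear mixed-effects
engine, and measures how study-design choices affect how well the exponents
are recovered. This note records the models, the defaults and their
rationale, the numerical choices, and the limits of what the synthetic
populations can show.

## Virtual populations

**Pediatric weights.** A growth chart parameterized by the LMS method (Box–Cox
power `L`, median `M`, generalized coefficient of variation `S`, one row per
age-month) maps a standard-normal score `z` to a weight:

    weight(z) = M (1 + z L S)^(1/L)        (L ≠ 0)
    weight(z) = M exp(z S)                 (L → 0 limit)

For each age-month from 24 to 215 (2–17 years; younger children are out of
scope because immunoglobulin handling is still maturing rapidly below age 2),
100 independent `z` draws produce 100 virtual children. Draws that land
outside the chart's valid domain (`1 + zLS ≤ 0`) are redrawn rather than
clipped, preserving the distribution shape. Month-level random streams are
keyed on the month itself, so the pooled 2–17 population is exactly the union
of the 2–5, 6–11 and 12–17 populations built from the same seed. Age bands
use the inclusive month ranges 24–71, 72–143, 144–215 and 24–215.

The repository ships a **synthetic LMS table** (`data/lms_synthetic.csv`,
regenerated by `growth.synthetic_lms_table()`): smooth month-by-month curves
interpolated (monotone PCHIP) through anchor values patterned on public
weight-for-age references — median weight rising from ~12.4 kg at age 2 to
~62 kg at age 18, `S` peaking near 0.22 in early adolescence, `L` negative
throughout (heavy right tail). It is a stand-in, not measured data; the
loader also reads official CDC-format tables (`Sex`/`Agemos`/`L`/`M`/`S`,
fractional ages floored to months), with male, female or sex-averaged curves
(default: averaged, since nothing in the design is sex-specific).

**Adult weights.** Normal(70, 10) kg truncated to [60, 110] by rejection
sampling — a typical healthy Phase-1 population centered on the 70-kg
allometric reference. The adult pool holds 200 subjects; study arms of 20 are
subsampled from it.

## PK model

One-compartment, first-order absorption, apparent (per-bioavailability)
parameterization, single subcutaneous dose of 2 mg/kg at t=0 for everyone
(adults included — dosing is weight-based):

    V/F  = TV  · exp(η_V)  · (WT/70)^θ_V        TV  = 18 L
    CL/F = TCL · exp(η_CL) · (WT/70)^θ_CL       TCL = 1 L/day
    Ka   = TKa · exp(η_Ka)                      TKa = 0.9 /day

    C(t) = D·Ka / (V(Ka−ke)) (e^(−ke·t) − e^(−Ka·t)),   ke = CL/V,

with the limit form `C(t) = D·Ka·t/V·e^(−Ka·t)` when |Ka−ke|/ke < 1e-8.
True exponents are θ_V = 1.0 and θ_CL = 0.75. The random effects
(η_V, η_CL, η_Ka) are mean-zero trivariate normal with a V–CL correlation of
0.7 and η_Ka independent. Stated inter-individual variabilities (46%, 49%,
50% CV) are mapped to log-scale variances by the exact log-normal identity
var(η) = ln(1+CV²); the common approximation var(η) = CV² is available via
`cv_mapping="approx"` (at ~50% CV the two differ by ~10% in variance, enough
to matter). Observations carry proportional residual error
DV = C·(1+ε), ε ~ N(0, 0.25²), untruncated and with no quantification limit.

Typical-subject kinetics: half-life ln 2·18 ≈ 12.5 days, analytic peak at
tmax = ln(Ka/ke)/(Ka−ke) ≈ 3.3 days, and C(56)/Cmax ≈ 5.7% — the 56-day
horizon spans ~4.5 half-lives and late samples carry little information.

**Sampling schemes** (days post-dose): sparse {4, 14, 28}, five-point
{1, 2, 4, 14, 28}, dense {1, 2, 4, 7, 14, 28, 42, 56}; the intensively
sampled adult arm uses the dense schedule (a seven-point variant without day
42 is available as `adult_intensive_7`). Realized sampling times jitter
uniformly in a 0.6-day window centered on each nominal day (±0.3), floored
at zero and kept strictly increasing.

## Estimation engine (FOCE with interaction)

Writing the joint −2 log-density of one subject's data and random effects

    h(η) = Σ_j [ ln(2π g_j²) + (y_j − f_j(η))² / g_j² ] + η'Ω⁻¹η + ln|2πΩ|,
    g_j = σ·|f_j(η)|,

the marginal likelihood is approximated by a Laplace expansion at the
conditional mode η̂ (the empirical Bayes estimate), with the residual
variance evaluated at the conditional prediction — the "interaction":

    −2 ln L_i ≈ h_i(η̂_i) − 3 ln 2π + ln det(H_i/2),   H_i = ∇²h_i(η̂_i).

The inner mode search is a damped Newton iteration run simultaneously for
all subjects on the shrinking set of unconverged ones, using fully analytic
gradients and Hessians of `h` (chained through ke = CL/V and Ka; rows with
the removable Ka ≈ ke singularity fall back to a finite-difference stencil).
On small three-subject instances the resulting objective agrees with an
adaptive Gauss–Hermite quadrature (11 nodes/dimension) to ~0.1 units; the
test suite enforces 0.5.

The outer search maximizes the summed approximation over a transformed
vector — log typical values, free exponents, log random-effect SDs, atanh
correlation, log σ — with L-BFGS-B and central-difference gradients (forward
differences are visibly biased in the sharp valleys of low-variance fits).
Default initial values (10 L, 0.7 L/day, 0.5/day, both exponents 0.5, all
SDs 0.3, correlation 0, σ 0.2) sit deliberately away from the simulation
truth so recovery is never an artifact of initialization. Convergence:
relative objective change below `ftol` (1e-9) with the projected gradient
below 1e-3; on failure up to three restarts with ±20% log-scale jitter.
`n_starts > 1` runs extra independent starts and keeps the best — useful for
degenerate near-zero-variance likelihoods, which are multimodal. Parameter
regions where the joint density at η = 0 exceeds 1e8 (line-search overshoots)
return that value directly instead of a flat penalty so the optimizer can
always find its way back; the Laplace log-determinant clamps eigenvalues at
1e-8 against numerical non-positive-definiteness at the mode. Variance-scale
parameters are bounded below at 1e-3 on the natural scale. Non-convergence
is reported, never raised; scenario summaries use converged replicates only
and report the convergence rate (a cell under 50% is flagged unreliable).
Standard errors are out of scope — the study works with replicate
distributions of point estimates.

The estimated random-effect structure deliberately matches the generating
model (3 η's, V–CL correlation, η_Ka free), and adult and pediatric records
share one IIV and residual model in both simulation and fitting.

## Study driver and reproducibility

A scenario is one design cell: age group × pediatric sample size
(30/60/120/200/240) × sampling scheme × optional pooled adult arm (20
adults, intensive sampling). One replicate regenerates the weight pools with
fresh z-draws, samples the cohort, simulates, and fits with both exponents
free — "repeated 100 times" is read as repeating this whole cycle, the only
reading that yields an estimate distribution per cell. Replicate seeds
derive as SeedSequence(master_seed, spawn_key=(crc32(pediatric-cell-label),
replicate-index)), so any replicate reproduces in isolation and pooled vs
pediatric-only variants of the same cell share identical pediatric data —
the comparison the pooling question needs. Quartiles are type-7 (linear
interpolation, the numpy/R default; box whiskers extend to the most extreme
values within 1.5×IQR). Cliff's delta is computed exactly in O(n log n) with
ties contributing zero; the two-sample KS test uses the asymptotic p-value
(sample sizes here make exact p irrelevant at the 0.01 level).

## Problem sizes in the test suite

The study-design invariants (precision grows with n; broad age range beats
narrow; the three pediatric schemes are interchangeable; pooled adults help
2–5-year-olds but not adolescents) are exercised at 25 replicates per design
cell with a fixed master seed — enough for IQR widths whose Monte-Carlo
wobble is well below the effect sizes involved (the adjacent-cell slack
allowances, 0.05–0.2 depending on the comparison, are ~3 standard errors of
an IQR width at 25 replicates). The full 68-cell grid at 100 replicates
(`examples/full_grid.yaml`) is the production configuration.

## What the synthetic populations do and do not show

Passing tests demonstrate that the pipeline recovers known truth under its
own generative assumptions: weights from a realistic growth chart, exactly
allometric PK with body weight as the only covariate, log-normal IIV,
proportional error. They say nothing about maturation (FcRn ontogeny, organ
function), disease effects, target-mediated disposition, adherence or assay
artifacts — none of which are modeled. The synthetic LMS chart reproduces
the qualitative separation structure of real weight distributions (complete
adult separation for ages 2–11, substantial adolescent overlap) but its
adolescent upper tail is slightly heavier than official charts, so pooled-age
effect sizes computed from it shift a few hundredths relative to chart-exact
values; analyses aiming at chart fidelity should pass the official CDC table
to `read_lms_table`.

## Known limitations

- Single dose, one compartment, linear elimination only; no IV route, no
  LLOQ/BLQ handling, no covariates beyond body weight.
- FOCE-I is an approximation; its error is bounded by quadrature only on
  small instances. Degenerate designs (e.g. one subject, two observations)
  can stall in local optima — such fits are flagged, not repaired.
- The Ω structure is fixed to the generating one; no covariance selection.
- Box-plot summaries, not rendered figures, are the contract; plotting is
  left to the caller.
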