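# Methods

## Models

**One-compartment intermittent infusion (`pk_core`).** Zero-order infusion
of duration `t_in` into a single well-mixed volume `Vd` with first-order
elimination `Ke`. Three closed forms are used throughout:

- first-dose peak, sampled a fixed 1 h after the infusion ends:
  `Cpeak,first = FD/(Ke·Vd·t_in) · (1−e^(−Ke·t_in)) · e^(−Ke·1)`;
- steady-state trough (accumulation factor × end-of-interval decay):
  `Ctrough,ss = MD/(Ke·Vd·t_in) · (1−e^(−Ke·t_in))/(1−e^(−Ke·τ)) · e^(−Ke·(τ−t_in))`;
- `AUC24 = MD/(Ke·Vd) · 24/τ`, i.e. daily dose over clearance — exact at
  steady state for linear kinetics.

Units are fixed internally to mg, L, h, mg/L; µg/mL is numerically
identical to mg/L and doses in g are converted at the I/O boundary. The
1-h peak sampling lag is hard-coded in the closed form because the whole
Vd,app construction is defined at that draw time; the profile generator
accepts arbitrary sampling times since real peaks are drawn 0.5–2 h
post-infusion. `1−e^(−x)` is evaluated with `expm1` so small `Ke·t` does
not cancel.

**Two-compartment truth model (`twocomp`).** Central volume V1 with
elimination `k10 = CL/V1` and a peripheral compartment coupled by
`k12`/`k21`; `V1 = Vss/(1 + k12/k21)`. The central concentration under
constant-rate infusion is the convolution of the bi-exponential impulse
response, evaluated in closed form and superposed across doses, so profiles
are exact to machine precision at any time point (the trapezoidal AUC is
the only discretised quantity). The hybrid rates are the roots of
`s² − (k10+k12+k21)s + k10·k21`; the discriminant is bounded below by
`(k10−k21)²` and can only vanish when `k12 → 0` with `k10 = k21`, where a
relative 1e−6 perturbation of `k21` lifts the double root (error far below
every tolerance used).

## Pseudo-population study

5000 parameter sets are drawn: creatinine clearance from a truncated normal
(mean 70, SD 35, truncated to [10, 200] mL/min), and CL, Vss, k21 from
log-normals around CLcr-dependent typical values, `X = TV·exp(η)` with
`sd(η) = sqrt(ln(1+CV²))` — the standard pharmacometric convention; k12 is
fixed. Subjects with CLcr in [30, 110) mL/min are retained (~75–80%) and
assigned renal-function-stratified regimens: loading dose 1.5 g below
50 mL/min, 1.75 g above; maintenance 0.75 g q24h ([30, 40)), 0.5 g q12h
([40, 60)), 0.75 g q12h ([60, 80)), 1.0 g q12h ([80, 100)), 1.25 g q12h
([100, 110)); infusion times 1 h for doses ≤ 1 g, 1.5 h up to 1.5 g, 2 h
above.

Each subject is simulated 0–120 h (loading dose at t=0, maintenance at τ,
2τ, …; for both q12h and q24h the 120-h point is an interval end). The
reference `AUC_2com` is the trapezoidal integral over 96–120 h on a 0.01 h
grid with infusion start/end times inserted exactly (grid-halving changes
the result by <0.05%); the peak (1 h after the loading infusion ends) and
the 120-h trough are evaluated analytically. The one-compartment methods
are then applied exactly as at the bedside: a least-squares (Ke, Vd) fit to
the pair giving `AUC_1com`, and the Vd,app route (`Ke,alt` solved from the
trough at `Vd,app`) giving `AUC_1com,alt`.

**Population-model configuration.** The numeric defaults (CL =
0.0478·CLcr + 0.3 L/h, Vss 60 L, k21 0.45 h⁻¹, k12 0.55 h⁻¹ fixed; CVs
0.25/0.25/0.30) are a documented generic-adult placeholder chosen to give
clinically typical vancomycin kinetics (CL ≈ 2–5 L/h, distribution
half-life tens of minutes, elimination half-life 6–12 h, troughs mostly
5–20 µg/mL). `PopulationSpec` is fully configuration-driven: any published
population model — e.g. one fitted to a Japanese adult cohort — can be
transcribed into YAML and loaded with `PopulationSpec.from_yaml`, and any
quantitative claim tied to a *specific* published model requires exactly
that transcription. The CLcr truncation bounds ([10, 200]) are likewise
configuration; the two-stage design (wide sampling, then the 30–110
selection window) is fixed.

## Inverse problems

- **`solve_ke_from_trough`** uses the strict monotone decrease of the
  steady-state trough in Ke; Brent root-finding on the bracket
  [1e−4, 5] h⁻¹ (half-lives ~8 min to ~290 days) with the residual checked
  to <1e−10 mg/L. Targets outside the attainable interval raise an error
  naming that interval — they are data errors, not extrapolated.
- **`fit_1c_peak_trough`** exploits the fact that the peak/trough ratio is
  free of Vd: Ke is a 1-D bracketed root of the ratio (strictly increasing
  in Ke), and Vd follows from the peak equation. With two observations and
  two parameters this is the exact least-squares optimum and removes all
  initialisation sensitivity; a Nelder–Mead fallback on (log Ke, log Vd)
  covers targets at the bracket edge. Pairs with peak ≤ trough are rejected
  as non-convergent: under heavy accumulation (very low Ke, short interval)
  the model can represent them, but for the loading-dose regimens used here
  they indicate a distribution artefact or a data error, and downstream
  callers flag and exclude such subjects rather than fit them.
- **`map_estimate_2c`** minimises
  `Σ((c_obs − c_pred)/σ_i)² + Σ(log(P/TV)/ω)²` over log-scale (CL, Vss,
  k21) with k12 fixed at its typical value. Residual weights are anchored
  at the *observed* concentration (σ² = (prop·c_obs)² + add²), keeping the
  objective a genuine least squares; the default is 20% proportional,
  matching the error margin usually quoted for Bayesian AUC estimates
  against true AUCs. ω = 0 pins a parameter at its typical value, ω = ∞
  makes it flat. Optimisation is Nelder–Mead from the typical values
  (deterministic) with optional seeded random restarts; `AUC_Bayes` is
  clearance-based (daily dose / CL_MAP), equivalent at steady state to the
  profile integral. This is a standard MAP TDM estimator specified in full
  here precisely because commercial/web TDM tools rarely document theirs.

## Nomograms

15 canonical regimens (0.5/0.75/1.0/1.25/1.5 g × q8h/q12h/q24h; infusion
time from the dose-size rule above, configurable) each give a 13×21 grid:
Vd 20–80 L in 5 L steps, trough 5–25 µg/mL in 1 µg/mL steps. Cell AUCs
come from the same Ke inversion as above; unattainable cells become
explicit missing values. Banding: white 400 ≤ AUC ≤ 600, light grey
350 ≤ AUC < 400 or 600 < AUC ≤ 650, dark grey otherwise. Lookup snaps each
coordinate to the nearest axis value with ties rounding up (deterministic,
unbiased with respect to the AUC direction); inputs outside the span clamp
to the boundary and carry an out-of-range flag. No interpolation between
cells — the tables are for approximate estimation, and the grid pitch is
the stated precision. A robust empirical property of these tables is
interval-insensitivity: at fixed single dose, Vd and trough, the AUC varies
by only a few percent across q8h/q12h/q24h, because the trough constrains
clearance nearly identically once the dose rate is fixed.

## Agreement statistics

Passing–Bablok regression follows the original 1983 procedure: pairwise
slopes with `S_ij = −1` excluded and the median shifted by
`K = #{S_ij < −1}` (making the estimator equivariant under swapping
methods); ties with `dx = 0, dy ≠ 0` contribute signed infinite slopes,
`0/0` pairs are dropped; even slope counts use the arithmetic mean of the
two central order statistics; CIs from rank positions with
`C_γ = z_{0.975}·sqrt(n(n−1)(2n+5)/18)`. Kendall's τb (tie-corrected) is
delegated to scipy and cross-checked against pair enumeration in the tests.
Therapeutic classification uses the closed band 400 ≤ AUC ≤ 600. The
weighted kappa uses **linear** disagreement weights `|i−j|/(k−1)` — the
natural penalty for ordered bands where a one-band miss is half a two-band
miss; the quadratic convention gives materially different values on the
same tables. The kappa CI is the large-sample Fleiss–Cohen–Everitt (1969)
standard error and is reported for orientation only, since reference
implementations differ in their variance formulas.

## Synthetic clinical cohort

The generator emulates an elderly, low-body-weight hospital TDM cohort:
age ~ N(70, 12) clipped to [30, 95] y, weight log-normal around 55 kg,
creatinine log-normal around 0.65 mg/dL, 62% male. Cockcroft–Gault
clearance (clamped into the dosable 30–110 mL/min window) drives regimen
assignment and the typical values; unlike the body-weight-free
pseudo-population, Vss scales with weight (0.85 L/kg default), as it does
clinically. Peaks are drawn at a uniform 0.5–2 h offset, troughs exactly
pre-dose at 120 h; both carry proportional measurement noise (default 10%
CV). Creatinine at the trough drifts by a uniform 0.9–1.2 factor, so the
1.5× exclusion rule fires only on constructed violations. What the
generator does **not** emulate: missed/late doses, non-steady-state
troughs, assay bias, augmented renal clearance beyond the sampled
variability, obesity, renal replacement therapy, or any covariate effects
on k12/k21 — so passing pipeline checks demonstrate internal consistency
of the estimators under the stated model, not clinical performance in
populations with those features.

Screening applies, in order: mandatory fields present; body weight known;
no renal replacement therapy; peak offset within [0.5, 2] h; trough at or
above the 3 µg/mL detection limit; trough drawn ≤ 1 h before the next
dose; creatinine at trough ≤ 1.5× baseline; ≥ 3 doses (loading dose
included) before the trough. Every rule is evaluated and logged for every
record (the audit trail), with the first failure as the headline reason;
screening is idempotent. Troughs drawn up to 1 h early are used as-is (no
back-extrapolation) — the conservative reading of routine practice.

## Numerical choices and problem sizes

- Root solves: Brent with xtol 1e−14; forward–inverse round trips hold to
  better than 1e−8 relative.
- Profile grid for trapezoidal AUC: 0.01 h with event times inserted;
  bounds the integration error well under 0.1%.
- The shipped study sizes — 5000 pseudo-population draws, a 200-patient
  synthetic cohort, 15 full nomograms — run end to end in well under a
  minute and are the sizes at which the reported summaries are computed.
- Seeds: every stochastic component takes an explicit seed
  (`PopulationSpec.seed`, generator `seed`); fixed seed ⇒ bit-identical
  tables and CSV bytes.

## Known limitations

- `AUC_Bayes` here is *a* MAP estimator, not a re-implementation of any
  particular TDM product; agreement with published Bayesian numbers is
  therefore structural, not numeric, unless the same population model and
  error model are configured.
- Vd,app inherits its documented upward bias (~10–20% above the fitted
  Vd in the shipped configuration, growing with clearance); in augmented
  renal clearance the nomogram route degrades first.
- The one-compartment closed forms assume a constant regimen from first
  dose to trough and true steady state; dose changes or unstable renal
  function invalidate the nomogram route by construction.
- Nonlinear elimination, absorption models, three-compartment kinetics and
  paediatric/dialysis populations are out of scope.
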