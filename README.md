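# vancoauc

Vancomycin dosing is steered by the 24-hour area under the concentration–time
curve (AUC24): efficacy against MRSA tracks AUC/MIC, with a therapeutic
target of 400–600 mg·h/L at MIC = 1 mg/L. The recommended way to obtain
AUC24 — MAP Bayesian fitting of a two-compartment model — needs specialised
software and training, which many hospitals lack. `vancoauc` implements and
evaluates a deliberately simple alternative built from two routine levels:

1. **Apparent distribution volume.** From the concentration drawn ~1 h after
   the end of the *first* infusion, `Vd,app = FD / Cpeak,first` (first dose
   over first peak).
2. **Nomogram lookup.** A per-regimen table over (Vd, Ctrough,ss): each cell
   solves the one-compartment steady-state trough equation

   `Ctrough,ss = MD/(Ke·Vd·t_in) · (1−e^(−Ke·t_in))/(1−e^(−Ke·τ)) · e^(−Ke·(τ−t_in))`

   for the elimination rate constant Ke, then reports
   `AUC24 = MD/(Ke·Vd) · 24/τ`. Reading the table at (Vd,app, measured
   trough) gives a bedside AUC estimate with no software at all.

The package also contains everything needed to validate that shortcut:

- `pk_core` — the one-compartment intermittent-infusion closed forms
  (first-dose peak, steady-state trough, AUC24) plus a superposition profile
  generator used as a numerical oracle;
- `twocomp` — an analytic two-compartment infusion simulator, trapezoidal
  AUC, renal-function-stratified regimen assignment, and a Monte-Carlo
  pseudo-population study comparing the one-compartment estimates against
  the two-compartment reference AUC;
- `estimators` — the inverse problems: Vd,app, Ke from a trough, joint
  (Ke, Vd) least squares from a peak/trough pair, and a MAP Bayesian
  two-compartment estimator;
- `nomogram` — construction, banding (white 400–600, light grey
  350–400/600–650, dark grey otherwise), nearest-cell lookup and CSV export
  of the 15 canonical dose × interval grids;
- `agreement` — Passing–Bablok regression with CIs, Kendall τb, therapeutic
  classification, linearly weighted Cohen's kappa;
- `clinical` — patient records, the enrolment screening filter,
  Cockcroft–Gault renal function, a synthetic-cohort generator, and the
  three-way AUC pipeline (Bayes vs least-squares vs nomogram).

## Worked example

A patient receives a 1.5 g loading dose (1.5 h infusion) then 1 g q12h
(1 h infusions). The first peak is 25.3 µg/mL; the steady-state trough is
9.7 µg/mL.

```python
import vancoauc as v

reg = v.DosingRegimen(first_dose=1500, maintenance_dose=1000,
                      tau=12, t_in=1, t_in_first=1.5)

vd = v.vd_app(1500, 25.3)                 # 59.3 L
ke = v.solve_ke_from_trough(reg, vd, 9.7) # 0.0863 1/h
auc_alt = 1000 / (ke * vd) * 24 / 12      # 391.0 mg·h/L (continuous)

grid = v.build_nomogram(1000.0, 12.0)
hit = v.lookup_auc_nmg(vd, 9.7, grid)
# hit.auc = 397.0, band = "light", snapped cell (60 L, 10 µg/mL)

fit = v.fit_1c_peak_trough(reg, 25.3, 9.7)
# ke = 0.0958, vd = 50.2 L, AUC_LS = 416.1 mg·h/L
```

The three numbers tell one story: this patient sits just at the lower edge
of the 400–600 mg·h/L therapeutic window — the nomogram cell lands in the
light-grey marginal band, and the exact least-squares fit puts the AUC at
416. A dose increase would be discussed, not mandated.

The same operations are exposed on the command line:

```sh
vancoauc nomogram lookup --dose 1.0 --tau 12 --vd 59.3 --ctrough 9.7
vancoauc nomogram build --dose 1.0 --tau 12 --out nmg_1g_q12.csv
vancoauc simulate --n 5000 --seed 1 --summary-json sim.json
vancoauc synth-cohort --n 51 --seed 7 --out cohort.csv
vancoauc estimate --records cohort.csv --report-json report.json
vancoauc agree --input paired_aucs.csv
```

## Cohort CSV schema

One row per patient; concentrations in µg/mL, doses in mg, times in hours:
`patient_id, age, sex, body_weight, scr_baseline, scr_at_trough,
first_dose_mg, maintenance_dose_mg, tau_h, t_in_h, t_in_first_h,
n_doses_before_trough, cpeak_first_ug_ml, peak_offset_h,
ctrough_ss_ug_ml, trough_offset_h, on_rrt`. `peak_offset_h` is the delay
from first-infusion end to the peak draw; `trough_offset_h` is how long
before the next scheduled dose the trough was drawn.

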