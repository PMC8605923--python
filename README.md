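# stabval

Toolkit for HPLC stability studies of a drug substance: ICH Q2-style method
validation statistics, chromatographic figures of merit, and forced-degradation
kinetics with first-order fitting, Arrhenius adjustment across temperatures,
and t90 shelf-life estimation.

## What it does

- **`stabval.regression`** — OLS with standard errors, Student-t confidence
  intervals, Pearson correlation, and %RSD; the statistical core every other
  module consumes.
- **`stabval.chromatography`** — peak-table data model (CSV in/out), percent
  recovery from peak areas, capacity factor k', resolution Rs, and a
  trapezoidal peak integrator with linear baseline for synthetic traces.
- **`stabval.validation`** — the validation battery: system and method
  linearity (with inverse-prediction of found concentrations through the
  system calibration), accuracy/precision, LOD/LOQ from the intercept
  dispersion and slope (LOD = 3.3·s/β1, LOQ = 10·s/β1), robustness |dᵢ|, and
  the specificity decision rule. Criteria (|r| ≥ 0.998, r² ≥ 0.995, recovery
  98–102%, %RSD < 2, |dᵢ| < 2, CI containment flags) are configurable.
- **`stabval.kinetics`** — first-order fits of ln(recovery) vs. time
  (zero-recovery points excluded and footnoted), Arrhenius regression of
  ln(k) on 1/T (B = 1/11605 K·eV⁻¹, activation parameter in eV), adjusted
  rates at target temperatures, t90 = ln(10/9)/k, and a study-level
  stability table.
- **`stabval.synthetic`** — seeded generators for every input: calibration
  curves (6 two-fold levels, 0.525–16.8 µg/ml, triplicate), fortified
  placebos (80–120% of 3.5 µg/ml), robustness sets, degradation time courses
  (0/24/72/120 h at 4/25/40/60 °C) obeying a known Arrhenius law with
  multiplicative assay noise, and Gaussian-peak chromatograms. Ground truth
  is serialized next to every dataset.
- **`stabval.cli` / `stabval.reporting`** — a single `stabval` CLI and
  plain-text/JSON report rendering with provenance.

## CLI

```sh
# generate a full synthetic study with known ground truth
stabval simulate --out study/ --seed 42 --noise-rsd 0.5

# run the validation battery (exit 0 iff all criteria pass)
stabval validate --calibration study/calibration.csv --method study/method.csv \
    --accuracy study/accuracy.csv --robustness study/robustness.csv --out val/

# fit degradation kinetics and build the stability table
stabval stability --degradation study/degradation.csv --target-temp 25 --out stab/

# merge both into one text report
stabval report --validation val/validation_report.json \
    --stability stab/stability_table.csv --out report.txt
```

Custom acceptance criteria go in a YAML/JSON file passed via
`--criteria` (keys: `r_min`, `r2_min`, `recovery_low`, `recovery_high`,
`rsd_max`, `residual_max`, `abs_diff_max`,
`require_ci_beta0_contains_zero`, `require_ci_beta1_contains_one`).

CSV schemas: calibration `level_ug_ml,replicate,area,kind`; degradation
`sample_id,condition,temperature_c,time_h,replicate,recovery_pct` (or raw
`area` + `area_ref`); peak tables
`sample_id,role,label,t_r_min,width_s,area`.

## Conventions

- Rates are natural-log basis (recovery = 100·e^(−kt)); fitting in log10 is
  available and t90 is invariant to the choice.
- Recovery defaults to 100·A_sample/A_std; the reciprocal orientation is
  available behind a flag.
- Retention times in minutes, peak widths in seconds, temperatures in °C
  (Kelvin internally for Arrhenius).
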