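# nirpls

Multivariate calibration of near-infrared (NIR) spectra for herbaceous
bioenergy feedstocks: predict **composition** (glucan, xylan, lignin, ash —
wt% dry basis) and **pretreatment reactivity** (glucose/xylose release in
g/g, glucan/xylan yield as a fraction of theoretical) from diffuse-reflectance
spectra, without running wet chemistry on every sample.

The package is aimed at chemometricians and biomass analysts who need a
transparent, scriptable replacement for point-and-click chemometrics
software: every stage of the standard NIR/PLS workflow is a tested library
function, and a synthetic-spectra generator lets the whole pipeline be
exercised (and its statistics audited) end to end without instrument data.

## What it computes

Given a calibration set of spectra **X** (samples × wavenumbers) and
reference values **Y**:

1. **Preprocessing** — standard normal variate (SNV) per spectrum, then a
   Savitzky–Golay first derivative (2nd-order polynomial, 21-point window),
   then range reduction to 4,000–8,998 cm⁻¹. Predictor columns are weighted
   by 1/SD per wavenumber.
2. **Sample selection** — Kennard–Stone max–min selection over the scores of
   the first two principal components picks the calibration subset; the
   remainder is the external validation set.
3. **PLS regression** — NIPALS latent-variable regression, PLS-1 (single
   response) or PLS-2 (multi-response), fitted on centred, weighted data.
   For factors *a* = 1…A: wᵃ ∝ Xᵀu, tᵃ = Xwᵃ, pᵃ = Xᵀtᵃ/tᵃᵀtᵃ,
   cᵃ = Yᵀtᵃ/tᵃᵀtᵃ, with X-deflation; B = W(PᵀW)⁻¹Cᵀ.
4. **Validation statistics** — leave-one-out cross-validation recomputing
   centres and weights inside every fold; RMSEC, RMSECV, RMSEP, R² (squared
   Pearson correlation), and the predicted-vs-measured line.
5. **Outlier screening** — per-sample normalized errors
   |y_ref − y_pred| / RMSEC; composition models flag samples whose
   glucan/xylan/lignin average exceeds 1.5 (ash screened separately at 1.5),
   release/yield models flag any constituent error above 2.0; flagged
   samples are removed and the model refitted.
6. **Reactivity arithmetic** — release (g sugar / g dry biomass) and
   anhydro-corrected yields: G.Yield = (G.Release × 162.14/180.16) /
   (glucan + sucrose × 162.14/342.30), X.Yield = (X.Release × 132.11/150.13)
   / xylan; combined GX quantities sum the releases and pool the yields.

## Worked example

```bash
nirpls run --seed 7 --out demo_run --preset composition
```

simulates a 279-sample six-feedstock population (duplicate scans,
multiplicative/additive scatter, instrument noise on a 12,000–3,300 cm⁻¹
grid), selects 245 calibration samples by Kennard–Stone, screens outliers,
fits the 9-factor PLS-2 composition model with leave-one-out
cross-validation, and prints:

```
report written to demo_run
  glucan: RMSEC=0.545 RMSECV=0.627 R2=0.985
  xylan: RMSEC=0.58 RMSECV=0.693 R2=0.961
  lignin: RMSEC=0.523 RMSECV=0.624 R2=0.972
  ash: RMSEC=0.445 RMSECV=0.622 R2=0.960
```

RMSEC/RMSECV are in wt% dry basis — the cross-validated precision of the
model — and R² is the squared correlation between the leave-one-out
predictions and the reference values. `demo_run/` contains the split,
outlier assessments, the serialized model, and calibration/validation report
CSVs with the schema `Constituent, Samples, Factors, RMSEC, RMSECV, R2,
Slope, Intercept` (validation: `RMSEP` in place of RMSEC/RMSECV).

The same study is available programmatically:

```python
from nirpls import WorkflowConfig, run_calibration_workflow

report = run_calibration_workflow(WorkflowConfig(preset="composition", seed=7))
```

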