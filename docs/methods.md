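# Methods

## The calibration problem

NIR diffuse-reflectance spectra of milled biomass contain overlapping
overtone and combination bands of O–H, C–H and N–H vibrations. No single
wavenumber quantifies glucan, xylan, lignin or ash; the information is
spread across the spectrum and confounded by light-scattering effects of
particle size and packing. The package therefore treats calibration as a
latent-variable regression problem: find a small number of spectral factors
that jointly explain predictor and response variance, and regress reference
values on them.

## Preprocessing

**SNV.** Each spectrum is centred and scaled to unit sample standard
deviation (n−1 denominator). For a spectrum corrupted as a·x + b
(multiplicative scatter a > 0, constant baseline offset b), SNV returns
exactly the same vector as for x, which is why it is the canonical scatter
correction for particulate solids. Consequence worth noting: SNV is a
*projective* transform — dividing by a composition-dependent row SD — so a
strictly linear Beer–Lambert mixture becomes mildly nonlinear in the
constituents after SNV. PLS absorbs this with extra factors; it is the
dominant error source in the synthetic studies (see below).

**Savitzky–Golay derivative.** First derivative from a local 2nd-order
least-squares fit over a 21-point window, expressed per cm⁻¹ (divided by
the grid spacing, sign-correct for decreasing instrument axes). The filter
is exact for polynomials up to the fit order, which the tests exploit as an
analytic oracle. Edges are handled by trimming the half-window (10 points)
at each end rather than fitting asymmetric windows: deterministic, and the
subsequent range reduction discards those regions anyway.

**Range reduction.** Retains 4,000–8,998 cm⁻¹ inclusive — the region
informative for composition — from the full 12,000–3,300 cm⁻¹ grid
(3.857 cm⁻¹ spacing), dropping the noisy extremes.

**1/SD column weighting.** Predictor columns are weighted by the inverse
sample SD computed on calibration rows only; stored weights are reused for
prediction. Inside cross-validation, weights and centres are recomputed in
every fold so the held-out sample leaks no information into its own
prediction.

## PLS (NIPALS)

Both PLS-1 and PLS-2 use the same NIPALS iteration with X-deflation;
convergence tolerance 1e-12 on the loading-weight vector, at most 500
iterations (single-response fits converge immediately). X and Y are
mean-centred, then optionally column-weighted; regression coefficients are
back-transformed so predictions are in original units. Sign ambiguity is
resolved by making the largest-magnitude element of each loading-weight
vector positive, so serialized models are reproducible bit for bit. If the
requested factor count exceeds the effective rank (X or Y residual
numerically exhausted, relative threshold 1e-12), extraction stops early and
a warning is recorded on the model rather than raising.

Truncating a fitted A-factor model to a < A factors reproduces, bit for
bit, a fresh fit with a factors (deflation is sequential; the coefficient
solve is repeated on contiguous copies of the leading columns). The
leave-one-out routine exploits this — one NIPALS pass per fold, predictions
at every factor count — and is tested for exact agreement with a naive loop
that refits from scratch at every (fold, factor count).

## Validation statistics and factor choice

RMSEC/RMSECV/RMSEP are root-mean-square errors of the calibration fit, the
leave-one-out predictions, and the external set. R² is the squared Pearson
correlation of predicted and measured; slope and intercept come from
regressing predicted (ordinate) on measured (abscissa). For the 0-factor
(mean) model the LOO error has the closed form (n/(n−1))·population SD,
used as a test oracle.

Factor choice in practice is a judgement call made from explained-variance
and RMSECV curves. The automated stand-in (`select_factors`) returns the
smallest factor count whose cross-validated explained response variance
(averaged over the model's constituents, referenced to the LOO mean model)
is within 0.5 percentage points of its maximum; workflows may instead fix
the count (the presets default to 9 for composition, 9/11/8 for the
reactivity models).

## Outlier screening

Samples are scored against the base model by |y_ref − y_pred|/RMSEC per
constituent. Composition: the glucan/xylan/lignin errors are averaged and
compared to 1.5, with ash screened separately at the same cutoff;
release/yield: each modelled constituent is compared to 2.0 (a sample is
flagged if any exceeds it). Flagged samples are always removed — the rule
is mechanical, with no discretionary exceptions — and the model refitted;
one pass by default, optionally iterated.

Two properties matter in practice. First, with approximately Gaussian
residuals the separate ash screen alone flags ≈13% of samples (P(|z|>1.5)),
so the synthetic composition workflow removes ~40–46 of 245 — the rule's
behaviour under Gaussian noise, not a bug. Second, a base model with many
factors partially *absorbs* gross reference errors (PLS chases response
outliers through noise directions of X), shrinking their normalized errors;
screening is therefore most reliable with a parsimonious base model, and
the planted-outlier tests use one matched to the data rank.

## Reactivity arithmetic

Release is grams of monomeric sugar (pretreatment + enzymatic hydrolysis,
3.0 g dry sample loading in the emulated assay) per gram dry biomass.
Yields convert monomer mass to anhydro (polymer-equivalent) mass — glucose
× 162.14/180.16, xylose × 132.11/150.13 — and divide by the structural
carbohydrate base. Sucrose contributes its glucosyl moiety (× 162.14/342.30)
to the glucan base; fructose is not tracked. The combined GX.Release is the
plain sum; GX.Yield is the pooled ratio (summed corrected releases over
summed bases) rather than the sum of two fractions — a sum of two yields
could exceed 1 for any sample with both components well converted, which
contradicts yield's meaning as a fraction of theoretical. The pooled ratio
lies between the component yields and equals them when they agree.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the pipeline assumes:

* **Composition** — independent truncated normals per constituent
  (glucan 33.2 ± 6.3 wt% on [21.4, 47.8]; xylan 17.8 ± 3.4 on [9.5, 28.7];
  lignin 15.2 ± 3.8 on [6.7, 29.0]; ash 6.7 ± 3.6 on [0.9, 16.4]),
  emulating a broad six-feedstock herbaceous population. Rows summing above
  100 wt% are redrawn; the remainder is an unmodelled "other" fraction with
  its own spectrum. Truncation shifts the realised means slightly above the
  nominal ones (ash ≈ 7.1). An optional second mixture component per
  constituent produces bimodal stress-test populations, since real
  multispecies sets are rarely normal.
* **Spectra** — Beer–Lambert mixtures of Gaussian-band pure-component
  spectra on the 12,000–3,300 cm⁻¹ instrument grid, times per-sample
  multiplicative scatter (SD 0.10), plus a per-sample constant offset
  (SD 0.05 AU) and white noise (SD 1e-3 AU) independent per replicate scan;
  two replicate scans per sample, averaged by the pipeline. The default
  band table is shaped for realistic difficulty: the carbohydrate matrix
  dominates absorbance, xylan and lignin are weak signals under the glucan
  bands, and ash (mineral, no NIR overtones) is nearly spectrally silent.
  With these defaults a well-built model reaches a cross-validated
  precision of ≈0.6–0.8 wt% — the order of reference-method uncertainty —
  rather than an unrealistically exact optimum dominated by float noise.
* **Reactivity** — releases linear in composition with lignin entering
  negatively (recalcitrance), plus noise, clipped at zero; population means
  ≈0.24 g/g (glucose) and ≈0.13 g/g (xylose). Yields are computed exactly
  by the release/yield arithmetic from the simulated releases, so the
  yield columns are internally consistent by construction.

Not emulated: real band assignments and line shapes, instrument drift,
moisture/temperature effects, non-constant baseline tilts, correlated
reference-method errors, and genuinely non-normal multispecies composition
distributions (beyond the optional two-mode stress switch). Passing the
end-to-end tests therefore demonstrates that the *pipeline machinery* is
correct and well-behaved at realistic noise levels — not that any
particular real feedstock model will reach these statistics.

## Problem sizes and numerical choices

The end-to-end studies use the full stated scale: 279 simulated samples
(558 duplicate scans, 2,256-point grid), Kennard–Stone selection of 245,
leave-one-out CV at up to 9 (composition) or 11 (reactivity) factors; a
complete composition study runs in well under a minute on one CPU.
Degenerate inputs fail loudly with the offending sample or wavenumber
named: zero-variance spectra (SNV), zero-variance columns (1/SD weights),
non-uniform axes (tolerance 1e-6 relative), constant references (R²),
non-positive RMSEC. Kennard–Stone ties break to the lowest sample index;
PCA and PLS signs follow the largest-element-positive convention. CSV and
JSON serialization render floats at 17 significant digits, so round-trips
are bit-exact; spectra headers print wavenumbers at 3 decimals when that is
lossless (instrument grids are), full precision otherwise.

## Known limitations

* PLS-2 multi-response fits use one shared latent space; constituents with
  very different spectral leverage can be better served by separate PLS-1
  models (the reactivity preset does this for the summed constituents).
* The outlier rule's false-positive rate under Gaussian residuals (~13-18%
  of samples for the composition+ash screens jointly) means "removed"
  counts on clean synthetic data are substantially higher than what a
  curated laboratory population would show.
* `select_factors` is a deliberate simplification of a human judgement;
  for real data, inspect the RMSECV / explained-variance curves.
* The generator's band table is a stand-in, not spectroscopy: it supports
  verification of the statistics, never interpretation of loadings.
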