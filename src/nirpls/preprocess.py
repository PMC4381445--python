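"""Spectral pretreatment: SNV scatter correction, Savitzky-Golay derivative,
range reduction, and inverse-standard-deviation column weighting.

The standard chain for diffuse-reflectance NIR of milled solids is applied in
the order SNV -> first derivative -> range restriction.  SNV removes the
per-spectrum multiplicative/additive scatter caused by particle-size and
packing variation; the 21-point, 2nd-order, 1st-derivative Savitzky-Golay
filter corrects residual baseline variation; the range is then cut to
4,000-8,998 cm^-1 where the signal is informative for composition.
Column weights (1 / sample SD per wavenumber) are fitted on calibration
spectra only and reused, unchanged, for prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .spectra_io import SpectraMatrix, SpectraError

__all__ = [
    "snv",
    "sg_derivative",
    "restrict_range",
    "column_weights",
    "PreprocessChain",
    "apply_chain",
]


def snv(spectra: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: centre and scale each spectrum to SD 1.

    Uses the sample standard deviation (n-1 denominator).  Affine-invariant:
    ``snv(a*x + b) == snv(x)`` for any scalars ``a > 0``, ``b`` — which is
    exactly why it removes multiplicative and constant-offset scatter.
    """
    X = spectra.absorbance
    sd = X.std(axis=1, ddof=1)
    if np.any(sd == 0):
        i = int(np.argmax(sd == 0))
        raise SpectraError(
            f"SNV undefined for zero-variance spectrum {spectra.sample_ids[i]!r}"
        )
    out = (X - X.mean(axis=1, keepdims=True)) / sd[:, None]
    return SpectraMatrix(list(spectra.sample_ids), spectra.wavenumbers.copy(), out)


def sg_derivative(
    spectra: SpectraMatrix,
    window: int = 21,
    polyorder: int = 2,
    deriv_order: int = 1,
) -> SpectraMatrix:
    """Savitzky-Golay derivative along the wavenumber axis.

    Each point is replaced by the derivative of the local least-squares
    polynomial fit, expressed per cm^-1 (exact for polynomials of degree
    <= ``polyorder``).  The half-window at each edge, where the centred fit
    is undefined, is trimmed from the output axis.
    """
    if window % 2 == 0 or window <= polyorder:
        raise SpectraError(
            f"window must be odd and > polyorder (got window={window}, polyorder={polyorder})"
        )
    if deriv_order > polyorder:
        raise SpectraError("deriv_order must be <= polyorder")
    p = spectra.wavenumbers.size
    if p < window:
        raise SpectraError(f"need >= {window} wavenumbers for a {window}-point filter")
    # savgol_filter differentiates w.r.t. sample index; divide by the signed
    # spacing to express the derivative per cm^-1 whatever the axis direction.
    d_index = savgol_filter(
        spectra.absorbance, window_length=window, polyorder=polyorder,
        deriv=deriv_order, delta=1.0, axis=1, mode="interp",
    )
    out = d_index / spectra.spacing ** deriv_order
    half = (window - 1) // 2
    return SpectraMatrix(
        list(spectra.sample_ids),
        spectra.wavenumbers[half:p - half].copy(),
        out[:, half:p - half],
    )


def restrict_range(spectra: SpectraMatrix, lo: float = 4000.0, hi: float = 8998.0) -> SpectraMatrix:
    """Keep only wavenumbers with ``lo <= nu <= hi`` (inclusive, order kept)."""
    if not lo < hi:
        raise SpectraError(f"invalid range: lo={lo} must be < hi={hi}")
    mask = (spectra.wavenumbers >= lo) & (spectra.wavenumbers <= hi)
    if mask.sum() < 2:
        raise SpectraError(f"range [{lo}, {hi}] keeps fewer than 2 wavenumbers")
    return SpectraMatrix(
        list(spectra.sample_ids),
        spectra.wavenumbers[mask].copy(),
        spectra.absorbance[:, mask],
    )


def column_weights(spectra: SpectraMatrix) -> np.ndarray:
    """1/SD weight per wavenumber column (sample SD across calibration rows)."""
    sd = spectra.absorbance.std(axis=0, ddof=1)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        raise SpectraError(
            f"zero variance across samples at wavenumber {spectra.wavenumbers[j]:.3f}"
        )
    return 1.0 / sd


@dataclass
class PreprocessChain:
    """Ordered pretreatment with fit-once column weighting.

    ``fit_transform`` runs the steps on calibration spectra and stores the
    1/SD column weights of the result; ``transform`` runs the same steps on
    new spectra and never refits the weights.  The weights are applied by the
    regression step (as predictor weighting), not multiplied into the
    returned spectra.
    """

    snv: bool = True
    sg_window: int = 21
    sg_polyorder: int = 2
    sg_deriv: int = 1
    range_lo: float = 4000.0
    range_hi: float = 8998.0
    weight_columns: bool = True
    fitted_column_weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.sg_window is not None:
            if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
                raise SpectraError("SG window must be odd and > polyorder")
            if self.sg_deriv > self.sg_polyorder:
                raise SpectraError("SG deriv order must be <= polyorder")
        if self.range_lo is not None and not self.range_lo < self.range_hi:
            raise SpectraError("range lo must be < hi")

    def apply_steps(self, spectra: SpectraMatrix) -> SpectraMatrix:
        out = spectra
        if self.snv:
            out = snv(out)
        if self.sg_window is not None:
            out = sg_derivative(out, self.sg_window, self.sg_polyorder, self.sg_deriv)
        if self.range_lo is not None:
            out = restrict_range(out, self.range_lo, self.range_hi)
        return out

    def fit_transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        out = self.apply_steps(spectra)
        if self.weight_columns:
            self.fitted_column_weights = column_weights(out)
        return out

    def transform(self, spectra: SpectraMatrix) -> SpectraMatrix:
        if self.weight_columns and self.fitted_column_weights is None:
            raise SpectraError("chain not fitted: call fit_transform on calibration data first")
        return self.apply_steps(spectra)

    def describe(self) -> dict:
        """Provenance record stored alongside fitted models."""
        return {
            "snv": self.snv,
            "sg_window": self.sg_window,
            "sg_polyorder": self.sg_polyorder,
            "sg_deriv": self.sg_deriv,
            "range_lo": self.range_lo,
            "range_hi": self.range_hi,
            "weight_columns": self.weight_columns,
        }


def apply_chain(chain: PreprocessChain, spectra: SpectraMatrix) -> SpectraMatrix:
    """Apply the chain's steps (SNV -> SG derivative -> range restriction)."""
    return chain.apply_steps(spectra)
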