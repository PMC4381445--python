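"""Leave-one-out cross-validation, factor selection and summary statistics.

RMSEC is the root-mean-square error of the calibration fit; RMSECV the
root-mean-square error of leave-one-out cross-validation, in which each
sample in turn is removed and the entire model — column means, 1/SD
weights and the PLS decomposition — is rebuilt from the remaining samples;
RMSEP is the same error measure on an external validation set.  R^2 is the
squared Pearson correlation of predicted and reference values; slope and
intercept describe the least-squares line of predicted (ordinate) on
measured (abscissa).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import pls_core
from .pls_core import PLSError, PLSModel, fit_pls, predict

__all__ = [
    "CVResult",
    "SummaryStats",
    "loo_cv",
    "summary_stats",
    "select_factors",
    "validate_external",
]


@dataclass
class SummaryStats:
    """RMSE, R^2 and best-fit line for one (reference, predicted) pairing."""

    n_samples: int
    n_factors: int
    rmse: float
    r2: float
    slope: float
    intercept: float


@dataclass
class CVResult:
    """Per-factor-count calibration and LOO-CV errors.

    ``factors`` runs from 0 (the mean-only model) to ``max_factors``; all
    arrays are aligned with it.  ``loo_predictions[i, :, f]`` is the
    prediction for sample ``i`` at ``factors[f]`` latent variables from the
    model fitted without sample ``i``.
    """

    factors: np.ndarray               # (K+1,) = 0..max_factors
    constituent_names: list[str]
    rmsec: np.ndarray                 # (K+1, m)
    rmsecv: np.ndarray                # (K+1, m)
    explained_variance_cal: np.ndarray   # (K+1, m), % of Y variance, calibration
    explained_variance_cv: np.ndarray    # (K+1, m), % of Y variance, cross-validated
    explained_variance_x: np.ndarray     # (K+1,), % of X variance, calibration
    loo_predictions: np.ndarray       # (n, m, K+1)
    fitted_predictions: np.ndarray    # (n, m, K+1)


def _weights_for(A: np.ndarray, option: str | None) -> np.ndarray | None:
    if option in (None, "none"):
        return None
    if option == "inv_sd":
        sd = A.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise PLSError("inv_sd weighting undefined: zero-variance column")
        return 1.0 / sd
    raise PLSError(f"unknown weighting option {option!r}")


def _fit_and_predict_all_factors(
    X_fit: np.ndarray,
    Y_fit: np.ndarray,
    X_eval: np.ndarray,
    max_factors: int,
    x_weighting: str | None,
    y_weighting: str | None,
) -> tuple[PLSModel, np.ndarray]:
    """One NIPALS pass; predictions for ``X_eval`` at every factor count 0..K.

    Returns predictions with shape ``(n_eval, m, K+1)``; factor counts beyond
    the effective rank repeat the last attainable prediction.
    """
    model = fit_pls(
        X_fit, Y_fit, max_factors,
        x_weights=_weights_for(X_fit, x_weighting),
        y_weights=_weights_for(Y_fit, y_weighting),
    )
    n_eval = np.atleast_2d(X_eval).shape[0]
    m = model.n_responses
    preds = np.empty((n_eval, m, max_factors + 1))
    preds[:, :, 0] = model.y_center  # 0 factors: the (fold) mean
    for f in range(1, max_factors + 1):
        if f <= model.n_factors:
            preds[:, :, f] = predict(model, X_eval, n_factors=f)
        else:
            preds[:, :, f] = preds[:, :, f - 1]
    return model, preds


def loo_cv(
    X: np.ndarray,
    Y: np.ndarray,
    max_factors: int,
    x_weighting: str | None = "inv_sd",
    y_weighting: str | None = None,
    constituent_names: list[str] | None = None,
) -> CVResult:
    """Leave-one-out cross-validation over factor counts 0..``max_factors``.

    Centring and any 1/SD weights are recomputed inside every fold so that
    no information about the held-out sample leaks into its prediction.
    """
    X = np.asarray(X, dtype=float)
    Y2 = np.asarray(Y, dtype=float)
    if Y2.ndim == 1:
        Y2 = Y2[:, None]
    n, m = Y2.shape[0], Y2.shape[1]
    if n < 3:
        raise PLSError("leave-one-out CV needs at least 3 samples")
    if constituent_names is None:
        constituent_names = [f"y{j}" for j in range(m)]

    cal_model, fitted = _fit_and_predict_all_factors(
        X, Y2, X, max_factors, x_weighting, y_weighting
    )
    loo = np.empty((n, m, max_factors + 1))
    for i in range(n):
        keep = np.arange(n) != i
        _, pred_i = _fit_and_predict_all_factors(
            X[keep], Y2[keep], X[i:i + 1], max_factors, x_weighting, y_weighting
        )
        loo[i] = pred_i[0]

    err_cal = fitted - Y2[:, :, None]
    err_cv = loo - Y2[:, :, None]
    rmsec = np.sqrt(np.mean(err_cal ** 2, axis=0)).T       # (K+1, m)
    rmsecv = np.sqrt(np.mean(err_cv ** 2, axis=0)).T
    ss_tot = np.sum((Y2 - Y2.mean(axis=0)) ** 2, axis=0)
    ss_tot = np.maximum(ss_tot, np.finfo(float).tiny)
    press_cal = np.sum(err_cal ** 2, axis=0).T             # (K+1, m)
    press_cv = np.sum(err_cv ** 2, axis=0).T
    # cross-validated explained variance is referenced to the LOO mean model
    # (factor count 0), the CV analogue of the total sum of squares
    ev_cal = 100.0 * (1.0 - press_cal / ss_tot)
    ev_cv = 100.0 * (1.0 - press_cv / np.maximum(press_cv[0], np.finfo(float).tiny))

    ev = pls_core.explained_variance(cal_model)
    ev_x = np.empty(max_factors + 1)
    kk = cal_model.n_factors
    ev_x[:kk + 1] = ev["x"]
    ev_x[kk + 1:] = ev["x"][-1]

    return CVResult(
        factors=np.arange(max_factors + 1),
        constituent_names=list(constituent_names),
        rmsec=rmsec, rmsecv=rmsecv,
        explained_variance_cal=ev_cal,
        explained_variance_cv=ev_cv,
        explained_variance_x=ev_x,
        loo_predictions=loo,
        fitted_predictions=fitted,
    )


def loo_cv_naive(
    X: np.ndarray,
    Y: np.ndarray,
    max_factors: int,
    x_weighting: str | None = "inv_sd",
    y_weighting: str | None = None,
) -> np.ndarray:
    """Reference LOO-RMSECV by refitting from scratch at every (fold, factor).

    Independent of :func:`loo_cv`'s single-pass shortcut; used as its oracle.
    Returns an array of shape ``(max_factors + 1, m)``.
    """
    X = np.asarray(X, dtype=float)
    Y2 = np.asarray(Y, dtype=float)
    if Y2.ndim == 1:
        Y2 = Y2[:, None]
    n, m = Y2.shape
    loo = np.empty((n, m, max_factors + 1))
    for i in range(n):
        keep = np.arange(n) != i
        Xf, Yf = X[keep], Y2[keep]
        loo[i, :, 0] = Yf.mean(axis=0)
        for f in range(1, max_factors + 1):
            model = fit_pls(
                Xf, Yf, f,
                x_weights=_weights_for(Xf, x_weighting),
                y_weights=_weights_for(Yf, y_weighting),
            )
            if model.n_factors < f:
                loo[i, :, f] = loo[i, :, f - 1]
            else:
                loo[i, :, f] = predict(model, X[i:i + 1])[0]
    return np.sqrt(np.mean((loo - Y2[:, :, None]) ** 2, axis=0)).T


def summary_stats(y_ref: np.ndarray, y_pred: np.ndarray,
                  n_factors: int = 0) -> SummaryStats:
    """RMSE, squared Pearson correlation and predicted-vs-measured line."""
    y_ref = np.asarray(y_ref, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_ref.size != y_pred.size or y_ref.size < 2:
        raise PLSError("y_ref and y_pred must have equal length >= 2")
    if np.ptp(y_ref) == 0:
        raise PLSError("R^2 undefined: reference values are constant")
    rmse = float(np.sqrt(np.mean((y_ref - y_pred) ** 2)))
    sxx = float(np.sum((y_ref - y_ref.mean()) ** 2))
    sxy = float(np.sum((y_ref - y_ref.mean()) * (y_pred - y_pred.mean())))
    syy = float(np.sum((y_pred - y_pred.mean()) ** 2))
    r2 = 0.0 if syy == 0 else sxy * sxy / (sxx * syy)
    slope = sxy / sxx
    intercept = float(y_pred.mean() - slope * y_ref.mean())
    return SummaryStats(
        n_samples=int(y_ref.size), n_factors=int(n_factors),
        rmse=rmse, r2=float(r2), slope=float(slope), intercept=intercept,
    )


def select_factors(cv: CVResult, tolerance: float = 0.5) -> int:
    """Smallest factor count whose cross-validated explained response variance
    (averaged over constituents) is within ``tolerance`` percentage points of
    its maximum over 1..max_factors.

    This is an explicit stand-in for the judgement call of reading RMSECV /
    explained-variance curves; a manual override is always available by
    fixing the factor count in the workflow configuration.
    """
    ev = cv.explained_variance_cv.mean(axis=1)  # (K+1,)
    candidates = ev[1:]
    best = float(candidates.max())
    for f, value in enumerate(candidates, start=1):
        if value >= best - tolerance:
            return f
    return int(cv.factors[-1])  # unreachable


def validate_external(
    model: PLSModel,
    X_val: np.ndarray,
    Y_val: np.ndarray,
    validation_ids: list[str] | None = None,
    constituent_names: list[str] | None = None,
) -> dict[str, SummaryStats]:
    """Predict an external set and summarise per constituent (RMSEP etc.).

    Fails if any validation id also appears in the model's calibration ids:
    external validation is only meaningful on disjoint samples.
    """
    if validation_ids is not None and model.calibration_ids is not None:
        overlap = set(validation_ids) & set(model.calibration_ids)
        if overlap:
            raise PLSError(
                f"validation samples overlap calibration set: {sorted(overlap)[:5]}"
            )
    Y_val = np.asarray(Y_val, dtype=float)
    if Y_val.ndim == 1:
        Y_val = Y_val[:, None]
    pred = predict(model, X_val)
    m = Y_val.shape[1]
    if constituent_names is None:
        constituent_names = [f"y{j}" for j in range(m)]
    return {
        name: summary_stats(Y_val[:, j], pred[:, j], n_factors=model.n_factors)
        for j, name in enumerate(constituent_names)
    }
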