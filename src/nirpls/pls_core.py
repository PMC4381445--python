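"""Partial least squares regression (NIPALS), single- and multi-response.

PLS-1 relates the predictors to one response; PLS-2 fits several responses
simultaneously in a shared latent-variable space.  Both are handled by the
same NIPALS iteration with X-deflation per factor: for one response column
the inner loop converges immediately, reproducing classical PLS-1.

Data handling follows standard chemometric practice: X and Y are
mean-centred, then optionally column-weighted (typically by 1/SD).
Weighting is implemented as column scaling before the fit; predictions are
returned in the original, unweighted, uncentred response units.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "fit_pls", "predict", "explained_variance", "PLSError"]

#: inner NIPALS loop: convergence tolerance on the loading-weight vector
NIPALS_TOL = 1e-12
NIPALS_MAX_ITER = 500

#: a latent score with sum of squares below this fraction of the initial
#: X sum of squares is treated as numerically zero (rank exhausted)
RANK_EPS = 1e-12


class PLSError(ValueError):
    """Raised for invalid PLS inputs (dimensions, factor counts, rank)."""


@dataclass
class PLSModel:
    """A fitted latent-variable regression.

    Attributes
    ----------
    n_factors
        Number of latent variables actually extracted ("Factors").
    x_center, y_center
        Column means removed before fitting.
    x_weights_applied, y_weights_applied
        Column scaling applied after centring (``None`` means unweighted).
    loading_weights, loadings, y_loadings
        NIPALS W (p, k), P (p, k) and C (m, k) matrices.
    scores
        Training score matrix T (n, k); successive columns orthogonal.
    regression_coefficients
        B (p, m) on the centred/weighted scale, at ``n_factors``.
    """

    n_factors: int
    x_center: np.ndarray
    y_center: np.ndarray
    x_weights_applied: np.ndarray | None
    y_weights_applied: np.ndarray | None
    loading_weights: np.ndarray
    loadings: np.ndarray
    y_loadings: np.ndarray
    scores: np.ndarray
    regression_coefficients: np.ndarray
    x_ss_residual: np.ndarray  # (k+1,), centred-weighted X SS after 0..k factors
    y_ss_residual: np.ndarray  # (k+1, m), per response
    calibration_ids: list[str] | None = None
    preprocess_provenance: dict | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def n_predictors(self) -> int:
        return self.x_center.size

    @property
    def n_responses(self) -> int:
        return self.y_center.size

    def coefficients_at(self, n_factors: int) -> np.ndarray:
        """Regression coefficients using only the first ``n_factors`` factors."""
        if not 1 <= n_factors <= self.n_factors:
            raise PLSError(f"n_factors must be in [1, {self.n_factors}]")
        # contiguous copies so the arithmetic (and hence the bits) matches a
        # fresh fit truncated at n_factors
        W = np.ascontiguousarray(self.loading_weights[:, :n_factors])
        P = np.ascontiguousarray(self.loadings[:, :n_factors])
        C = np.ascontiguousarray(self.y_loadings[:, :n_factors])
        return W @ np.linalg.solve(P.T @ W, C.T)

    def predict(self, X_new: np.ndarray, n_factors: int | None = None) -> np.ndarray:
        return predict(self, X_new, n_factors=n_factors)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        def arr(a):
            return None if a is None else np.asarray(a).tolist()

        return {
            "n_factors": self.n_factors,
            "x_center": arr(self.x_center),
            "y_center": arr(self.y_center),
            "x_weights_applied": arr(self.x_weights_applied),
            "y_weights_applied": arr(self.y_weights_applied),
            "loading_weights": arr(self.loading_weights),
            "loadings": arr(self.loadings),
            "y_loadings": arr(self.y_loadings),
            "scores": arr(self.scores),
            "regression_coefficients": arr(self.regression_coefficients),
            "x_ss_residual": arr(self.x_ss_residual),
            "y_ss_residual": arr(self.y_ss_residual),
            "calibration_ids": self.calibration_ids,
            "preprocess_provenance": self.preprocess_provenance,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        def arr(x):
            return None if x is None else np.asarray(x, dtype=float)

        return cls(
            n_factors=int(d["n_factors"]),
            x_center=arr(d["x_center"]),
            y_center=arr(d["y_center"]),
            x_weights_applied=arr(d["x_weights_applied"]),
            y_weights_applied=arr(d["y_weights_applied"]),
            loading_weights=arr(d["loading_weights"]),
            loadings=arr(d["loadings"]),
            y_loadings=arr(d["y_loadings"]),
            scores=arr(d["scores"]),
            regression_coefficients=arr(d["regression_coefficients"]),
            x_ss_residual=arr(d["x_ss_residual"]),
            y_ss_residual=arr(d["y_ss_residual"]),
            calibration_ids=d.get("calibration_ids"),
            preprocess_provenance=d.get("preprocess_provenance"),
            warnings=list(d.get("warnings", [])),
        )


def _as_2d(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    return Y[:, None] if Y.ndim == 1 else Y


def fit_pls(
    X: np.ndarray,
    Y: np.ndarray,
    n_factors: int,
    x_weights: np.ndarray | None = None,
    y_weights: np.ndarray | None = None,
    calibration_ids: list[str] | None = None,
    preprocess_provenance: dict | None = None,
) -> PLSModel:
    """Fit a PLS model by NIPALS with X-deflation.

    If the requested factor count exceeds the effective rank of X the
    extraction stops early and a warning is recorded on the model.
    """
    X = np.asarray(X, dtype=float)
    Y2 = _as_2d(Y)
    n, p = X.shape
    if Y2.shape[0] != n:
        raise PLSError(f"X has {n} rows but Y has {Y2.shape[0]}")
    m = Y2.shape[1]
    max_ok = min(n - 1, p)
    if not 1 <= n_factors <= max_ok:
        raise PLSError(f"n_factors={n_factors} outside [1, min(n-1, p)] = [1, {max_ok}]")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(Y2))):
        raise PLSError("X and Y must be finite (no missing values)")

    x_center = X.mean(axis=0)
    y_center = Y2.mean(axis=0)
    Xc = X - x_center
    Yc = Y2 - y_center
    if x_weights is not None:
        x_weights = np.asarray(x_weights, dtype=float)
        Xc = Xc * x_weights
    if y_weights is not None:
        y_weights = np.asarray(y_weights, dtype=float)
        Yc = Yc * y_weights

    W = np.zeros((p, n_factors))
    P = np.zeros((p, n_factors))
    C = np.zeros((m, n_factors))
    T = np.zeros((n, n_factors))
    x_ss = np.zeros(n_factors + 1)
    y_ss = np.zeros((n_factors + 1, m))
    x_ss[0] = np.sum(Xc * Xc)
    y_ss[0] = np.sum(Yc * Yc, axis=0)
    warnings: list[str] = []

    Xd, Yd = Xc.copy(), Yc.copy()
    x_ss0 = max(x_ss[0], np.finfo(float).tiny)
    y_ss0 = max(float(y_ss[0].sum()), np.finfo(float).tiny)
    k_done = 0
    for k in range(n_factors):
        if float(np.sum(Yd * Yd)) <= RANK_EPS * y_ss0:
            warnings.append(f"stopped at {k} factors: response variance exhausted")
            break
        # start from the residual-Y column with the largest sum of squares
        u = Yd[:, int(np.argmax(np.sum(Yd * Yd, axis=0)))].copy()
        w = np.zeros(p)
        for _ in range(NIPALS_MAX_ITER):
            w_new = Xd.T @ u / (u @ u)
            norm = np.linalg.norm(w_new)
            if norm == 0:
                break
            w_new /= norm
            t = Xd @ w_new
            tt = t @ t
            if tt == 0:
                w_new = np.zeros(p)
                break
            c = Yd.T @ t / tt
            cc = c @ c
            if cc == 0:
                break
            u = Yd @ c / cc
            if np.linalg.norm(w_new - w) < NIPALS_TOL:
                w = w_new
                break
            w = w_new
        if np.linalg.norm(w) == 0:
            warnings.append(f"stopped at {k} factors: predictor rank exhausted")
            break
        # deterministic sign: largest-|.| element of w made positive
        j = int(np.argmax(np.abs(w)))
        if w[j] < 0:
            w = -w
        t = Xd @ w
        tt = float(t @ t)
        if tt <= RANK_EPS * x_ss0:
            warnings.append(f"stopped at {k} factors: predictor rank exhausted")
            break
        pvec = Xd.T @ t / tt
        c = Yd.T @ t / tt
        Xd = Xd - np.outer(t, pvec)
        Yd = Yd - np.outer(t, c)
        W[:, k], P[:, k], C[:, k], T[:, k] = w, pvec, c, t
        x_ss[k + 1] = np.sum(Xd * Xd)
        y_ss[k + 1] = np.sum(Yd * Yd, axis=0)
        k_done = k + 1

    if k_done == 0:
        # constant Y (or rank-0 X): the model is the response mean
        model = PLSModel(
            n_factors=0,
            x_center=x_center, y_center=y_center,
            x_weights_applied=x_weights, y_weights_applied=y_weights,
            loading_weights=W[:, :0], loadings=P[:, :0], y_loadings=C[:, :0],
            scores=T[:, :0],
            regression_coefficients=np.zeros((p, m)),
            x_ss_residual=x_ss[:1], y_ss_residual=y_ss[:1],
            calibration_ids=calibration_ids,
            preprocess_provenance=preprocess_provenance,
            warnings=warnings,
        )
        return model

    W, P, C, T = W[:, :k_done], P[:, :k_done], C[:, :k_done], T[:, :k_done]
    B = W @ np.linalg.solve(P.T @ W, C.T)
    return PLSModel(
        n_factors=k_done,
        x_center=x_center, y_center=y_center,
        x_weights_applied=x_weights, y_weights_applied=y_weights,
        loading_weights=W, loadings=P, y_loadings=C, scores=T,
        regression_coefficients=B,
        x_ss_residual=x_ss[:k_done + 1], y_ss_residual=y_ss[:k_done + 1],
        calibration_ids=calibration_ids,
        preprocess_provenance=preprocess_provenance,
        warnings=warnings,
    )


def predict(model: PLSModel, X_new: np.ndarray, n_factors: int | None = None) -> np.ndarray:
    """Predict responses in original units; optionally truncate the factor count."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_predictors:
        raise PLSError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.n_predictors}"
        )
    Xc = X_new - model.x_center
    if model.x_weights_applied is not None:
        Xc = Xc * model.x_weights_applied
    if model.n_factors == 0:
        Yw = np.zeros((X_new.shape[0], model.n_responses))
    else:
        B = (model.regression_coefficients if n_factors is None
             else model.coefficients_at(n_factors))
        Yw = Xc @ B
    if model.y_weights_applied is not None:
        Yw = Yw / model.y_weights_applied
    return Yw + model.y_center


def explained_variance(
    model: PLSModel,
    X: np.ndarray | None = None,
    Y: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Cumulative percent variance explained per factor count (0..k).

    With no data arguments, the training residuals stored on the model are
    used.  With ``X``/``Y`` given, residuals are recomputed on that data in
    the model's centred/weighted scale.
    """
    if X is None and Y is None:
        x_ss = model.x_ss_residual
        y_ss = model.y_ss_residual
    else:
        X = np.asarray(X, dtype=float)
        Y2 = _as_2d(Y)
        Xc = X - model.x_center
        Yc = Y2 - model.y_center
        if model.x_weights_applied is not None:
            Xc = Xc * model.x_weights_applied
        if model.y_weights_applied is not None:
            Yc = Yc * model.y_weights_applied
        k = model.n_factors
        x_ss = np.zeros(k + 1)
        y_ss = np.zeros((k + 1, model.n_responses))
        x_ss[0] = np.sum(Xc * Xc)
        y_ss[0] = np.sum(Yc * Yc, axis=0)
        for f in range(1, k + 1):
            # project onto the first f factors via the model's W, P
            W = model.loading_weights[:, :f]
            P = model.loadings[:, :f]
            Tf = Xc @ W @ np.linalg.inv(P.T @ W)
            x_ss[f] = np.sum((Xc - Tf @ P.T) ** 2)
            y_ss[f] = np.sum((Yc - Tf @ model.y_loadings[:, :f].T) ** 2, axis=0)

    x0 = max(float(x_ss[0]), np.finfo(float).tiny)
    y0 = np.maximum(y_ss[0], np.finfo(float).tiny)
    return {
        "x": 100.0 * (1.0 - x_ss / x0),
        "y_per_response": 100.0 * (1.0 - y_ss / y0),
        "y": 100.0 * (1.0 - y_ss.sum(axis=1) / max(float(y_ss[0].sum()), np.finfo(float).tiny)),
    }
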