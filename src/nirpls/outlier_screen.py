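"""Outlier screening of calibration samples by normalized prediction error.

A base model is fitted on the full calibration set; each sample's absolute
prediction error per constituent is divided by that constituent's RMSEC,
giving a dimensionless error in "RMSEC units".  For composition models the
glucan/xylan/lignin errors are averaged and compared to a cutoff of 1.5,
with ash screened separately against the same cutoff; for release/yield
models each modelled constituent is screened against a cutoff of 2.0.
Flagged samples are removed and the model refitted (a single pass by
default).  The rule is applied mechanically: every flagged sample is
removed, and no unflagged sample ever is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .model_eval import _weights_for
from .pls_core import PLSError, PLSModel, fit_pls, predict

__all__ = [
    "OutlierAssessment",
    "normalized_error",
    "flag_outliers",
    "screen_and_refit",
    "CUTOFF_COMPOSITION",
    "CUTOFF_REACTIVITY",
]

CUTOFF_COMPOSITION = 1.5
CUTOFF_REACTIVITY = 2.0

#: constituents whose normalized errors are averaged in composition mode
COMPOSITION_AVERAGED = ("glucan", "xylan", "lignin")


@dataclass
class OutlierAssessment:
    """Per-sample screening record under one mode/cutoff."""

    sample_id: str
    y_ref: dict[str, float]
    y_pred: dict[str, float]
    rmsec: dict[str, float]
    normalized_errors: dict[str, float]
    aggregate_error: float
    flagged: bool
    cutoff_used: float
    mode: str = ""
    extra: dict = field(default_factory=dict)


def normalized_error(y_ref, y_pred, rmsec):
    """``|y_ref - y_pred| / rmsec`` — prediction error in RMSEC units."""
    rmsec = np.asarray(rmsec, dtype=float)
    if np.any(rmsec <= 0):
        raise PLSError("rmsec must be > 0")
    out = np.abs(np.asarray(y_ref, dtype=float) - np.asarray(y_pred, dtype=float)) / rmsec
    return float(out) if out.ndim == 0 else out


def _aggregate(errors: dict[str, float], mode: str) -> tuple[float, float]:
    """Aggregate error and cutoff for one sample under the given mode."""
    if mode == "composition":
        missing = [c for c in COMPOSITION_AVERAGED if c not in errors]
        if missing:
            raise PLSError(f"composition mode needs {missing} errors")
        return float(np.mean([errors[c] for c in COMPOSITION_AVERAGED])), CUTOFF_COMPOSITION
    if mode == "ash":
        if "ash" not in errors:
            raise PLSError("ash mode needs an 'ash' error")
        return float(errors["ash"]), CUTOFF_COMPOSITION
    if mode == "reactivity":
        if not errors:
            raise PLSError("reactivity mode needs at least one constituent error")
        return float(max(errors.values())), CUTOFF_REACTIVITY
    raise PLSError(f"unknown screening mode {mode!r}")


def flag_outliers(
    assessments_errors: Sequence[dict[str, float]],
    mode: str,
    cutoff: float | None = None,
) -> np.ndarray:
    """Boolean mask over samples; True where the mode's aggregate rule exceeds
    the cutoff (strictly greater than)."""
    flags = np.zeros(len(assessments_errors), dtype=bool)
    for i, errors in enumerate(assessments_errors):
        agg, default_cutoff = _aggregate(errors, mode)
        flags[i] = agg > (default_cutoff if cutoff is None else cutoff)
    return flags


def assess_samples(
    model: PLSModel,
    X: np.ndarray,
    Y: np.ndarray,
    sample_ids: Sequence[str],
    constituent_names: Sequence[str],
    mode: str,
    cutoff: float | None = None,
) -> list[OutlierAssessment]:
    """Score every sample against a fitted base model."""
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    pred = predict(model, X)
    rmsec = np.sqrt(np.mean((Y - pred) ** 2, axis=0))
    if np.any(rmsec <= 0):
        raise PLSError("base model fits a constituent exactly; RMSEC is 0")
    out = []
    for i, sid in enumerate(sample_ids):
        errs = {
            name: normalized_error(Y[i, j], pred[i, j], rmsec[j])
            for j, name in enumerate(constituent_names)
        }
        agg, default_cutoff = _aggregate(errs, mode)
        used = default_cutoff if cutoff is None else cutoff
        out.append(OutlierAssessment(
            sample_id=str(sid),
            y_ref={n: float(Y[i, j]) for j, n in enumerate(constituent_names)},
            y_pred={n: float(pred[i, j]) for j, n in enumerate(constituent_names)},
            rmsec={n: float(rmsec[j]) for j, n in enumerate(constituent_names)},
            normalized_errors=errs,
            aggregate_error=agg,
            flagged=agg > used,
            cutoff_used=used,
            mode=mode,
        ))
    return out


def screen_and_refit(
    X: np.ndarray,
    Y: np.ndarray,
    sample_ids: Sequence[str],
    constituent_names: Sequence[str],
    n_factors: int,
    mode: str | Sequence[str],
    cutoff: float | None = None,
    max_rounds: int = 1,
    x_weighting: str | None = "inv_sd",
    y_weighting: str | None = None,
):
    """Fit a base model, remove flagged outliers, refit.

    ``mode`` may be a single mode or a sequence (e.g. ``("composition",
    "ash")``) whose flag masks are unioned before removal.  With
    ``max_rounds > 1`` the rule is re-applied to each refitted model until no
    sample is flagged or the round budget is exhausted.

    Returns ``(kept_ids, refitted_model, assessments)`` where ``assessments``
    covers every screening round (flagged samples appear with their round's
    base-model numbers).
    """
    modes = (mode,) if isinstance(mode, str) else tuple(mode)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    keep = np.ones(X.shape[0], dtype=bool)
    ids = [str(s) for s in sample_ids]
    all_assessments: list[OutlierAssessment] = []

    def _fit(Xs, Ys):
        return fit_pls(
            Xs, Ys, n_factors,
            x_weights=_weights_for(Xs, x_weighting),
            y_weights=_weights_for(Ys, y_weighting),
            calibration_ids=[s for s, k in zip(ids, keep) if k],
        )

    model = _fit(X[keep], Y[keep])
    for round_no in range(max_rounds):
        Xk, Yk = X[keep], Y[keep]
        kept_ids = [s for s, k in zip(ids, keep) if k]
        flagged_any = np.zeros(Xk.shape[0], dtype=bool)
        for md in modes:
            assessments = assess_samples(
                model, Xk, Yk, kept_ids, constituent_names, md, cutoff
            )
            for a in assessments:
                a.extra["round"] = round_no
            all_assessments.extend(assessments)
            flagged_any |= np.array([a.flagged for a in assessments])
        if not flagged_any.any():
            break
        if flagged_any.all():
            raise PLSError("outlier screen flagged every calibration sample")
        for s, f in zip(kept_ids, flagged_any):
            if f:
                keep[ids.index(s)] = False
        model = _fit(X[keep], Y[keep])

    kept_ids = [s for s, k in zip(ids, keep) if k]
    return kept_ids, model, all_assessments
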