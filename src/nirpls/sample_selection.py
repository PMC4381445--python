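"""Calibration/validation splitting: PCA scores + Kennard-Stone selection.

The calibration subset is chosen to span the spectral variation of the
population: preprocessed spectra are projected onto their leading principal
components and the Kennard-Stone algorithm greedily picks, first, the two
most distant samples, then repeatedly the sample farthest (in max-min
distance) from everything already selected.  The unselected remainder
becomes the external validation set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra_io import SpectraError

__all__ = ["SplitResult", "pca_scores", "kennard_stone"]


@dataclass
class SplitResult:
    """Disjoint calibration/validation id lists plus the PC scores used."""

    calibration_ids: list[str]
    validation_ids: list[str]
    scores: np.ndarray
    n_pc: int
    calibration_indices: list[int] | None = None
    validation_indices: list[int] | None = None


def pca_scores(X: np.ndarray, n_pc: int = 2) -> np.ndarray:
    """Scores of the top ``n_pc`` principal components of mean-centred ``X``.

    Components are ordered by decreasing explained variance, with a
    deterministic sign convention (largest-magnitude loading element
    positive, first index on ties).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n_pc < 1:
        raise SpectraError("n_pc must be >= 1")
    if n <= n_pc:
        raise SpectraError(f"need more than n_pc={n_pc} samples (got {n})")
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int(np.sum(S > S[0] * max(n, X.shape[1]) * np.finfo(float).eps)) if S.size else 0
    if n_pc > rank:
        raise SpectraError(f"n_pc={n_pc} exceeds data rank {rank}")
    scores = U[:, :n_pc] * S[:n_pc]
    for k in range(n_pc):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            scores[:, k] = -scores[:, k]
    return scores


def kennard_stone(
    scores: np.ndarray,
    n_select: int,
    sample_ids: list[str] | None = None,
) -> SplitResult:
    """Greedy max-min-distance selection of ``n_select`` calibration samples.

    Euclidean distances are taken in the (unscaled) score space.  The first
    two selections are the pair at maximum distance; each subsequent
    selection maximises its minimum distance to the already-selected set.
    Ties are broken deterministically by the lowest sample index.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    n = scores.shape[0]
    if n < 2:
        raise SpectraError("Kennard-Stone needs at least 2 samples")
    if not 2 <= n_select <= n:
        raise SpectraError(f"n_select={n_select} outside [2, {n}]")
    if sample_ids is None:
        sample_ids = [str(i) for i in range(n)]
    if len(sample_ids) != n:
        raise SpectraError("sample_ids length does not match scores")

    diff = scores[:, None, :] - scores[None, :, :]
    D = np.sqrt(np.sum(diff * diff, axis=2))

    # initial pair: maximum distance; ties -> smallest (i, j) in row-major order
    flat = np.argmax(D)  # argmax returns the first (lowest flat index) maximum
    i0, j0 = divmod(int(flat), n)
    selected = [min(i0, j0), max(i0, j0)]
    in_set = np.zeros(n, dtype=bool)
    in_set[selected] = True
    min_dist = np.minimum(D[selected[0]], D[selected[1]])

    while len(selected) < n_select:
        min_dist[in_set] = -np.inf
        nxt = int(np.argmax(min_dist))  # first index wins ties
        selected.append(nxt)
        in_set[nxt] = True
        min_dist = np.minimum(min_dist, D[nxt])

    validation = [i for i in range(n) if not in_set[i]]
    return SplitResult(
        calibration_ids=[sample_ids[i] for i in selected],
        validation_ids=[sample_ids[i] for i in validation],
        scores=scores,
        n_pc=scores.shape[1],
        calibration_indices=selected,
        validation_indices=validation,
    )
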