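"""Coding-overlap statistic for pairs of cue features or task events.

For each feature and post-event window, the stepwise-GLM selections are
recoded into a binary vector over units (1 = the feature was a significant
predictor in that unit's final model).  Two such vectors are compared by
their Pearson correlation, which for binary data is the phi coefficient.
Correlating feature A's vector at each of the 6 fully-post-event windows
with feature B's vector at each of the 6 windows yields a 6 x 6 matrix (36
correlations); the mean of its non-degenerate entries is the overlap
statistic.

Significance comes from a unit-permutation null: the unit ordering of one
feature's vectors is shuffled (the same permutation across that feature's 6
windows within a shuffle, preserving its temporal structure), the mean of
the 36 correlations is recomputed, and the observed mean is z-scored
against 100 such shuffles.  z < -1.96 labels the two codes as carried by
*separate* populations, z > 1.96 by a *joint* population, and anything in
between by overlapping but *independent* populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .glm import SelectionMatrix

LABELS = {"separate": "z < -1.96", "independent": "|z| <= 1.96", "joint": "z > 1.96"}


def recode_selection(selection: SelectionMatrix, predictor: str,
                     center: float) -> np.ndarray:
    """Binary significance indicator over units for one predictor/window."""
    return selection.selected_vector(predictor, center)


def overlap_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Phi coefficient of two binary vectors; NaN when either is constant."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 units")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return np.nan
    a = a - a.mean()
    b = b - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def _stack_vectors(selection: SelectionMatrix, predictor: str,
                   centers) -> np.ndarray:
    return np.column_stack([recode_selection(selection, predictor, c)
                            for c in centers])


def overlap_matrix(selection_a: SelectionMatrix, predictor_a: str,
                   selection_b: SelectionMatrix, predictor_b: str,
                   centers=None) -> np.ndarray:
    """6 x 6 matrix of phi correlations over the post-event windows.

    Entry ``(i, j)`` correlates feature A at window i with feature B at
    window j.  The two selection matrices may come from different alignment
    events (persistence comparisons) or be the same one (feature overlap at
    one event); they must cover the same units.
    """
    centers_a = centers or selection_a.grid.post_event_centers()
    centers_b = centers or selection_b.grid.post_event_centers()
    if selection_a.unit_ids != selection_b.unit_ids:
        raise ValueError("selection matrices cover different unit sets")
    A = _stack_vectors(selection_a, predictor_a, centers_a)
    B = _stack_vectors(selection_b, predictor_b, centers_b)
    return _cross_phi(A, B)


def _cross_phi(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Pairwise phi between columns of two binary matrices (NaN if constant)."""
    out = np.empty((A.shape[1], B.shape[1]))
    Ac = A - A.mean(axis=0)
    Bc = B - B.mean(axis=0)
    na = np.sqrt(np.sum(Ac * Ac, axis=0))
    nb = np.sqrt(np.sum(Bc * Bc, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (Ac.T @ Bc) / np.outer(na, nb)
    out[na == 0, :] = np.nan
    out[:, nb == 0] = np.nan
    return out


@dataclass
class OverlapResult:
    """Mean phi overlap, permutation z, and the population label."""

    pair: tuple                   # ((predictor_a, event_a), (predictor_b, event_b))
    matrix: np.ndarray            # 6 x 6 phi correlations
    mean_r: float
    shuffle_mean: float
    shuffle_sd: float
    z: float
    label: str                    # separate | independent | joint | not assessable


def classify_overlap(selection_a: SelectionMatrix, predictor_a: str,
                     selection_b: SelectionMatrix, predictor_b: str,
                     rng: np.random.Generator, *, n_shuffle: int = 100,
                     centers=None) -> OverlapResult:
    """Label an overlap comparison against a unit-permutation null."""
    centers_a = centers or selection_a.grid.post_event_centers()
    centers_b = centers or selection_b.grid.post_event_centers()
    if selection_a.unit_ids != selection_b.unit_ids:
        raise ValueError("selection matrices cover different unit sets")
    A = _stack_vectors(selection_a, predictor_a, centers_a)
    B = _stack_vectors(selection_b, predictor_b, centers_b)
    return classify_overlap_vectors(A, B, rng, n_shuffle=n_shuffle,
                                    pair=((predictor_a, selection_a.event),
                                          (predictor_b, selection_b.event)))


def classify_overlap_vectors(A: np.ndarray, B: np.ndarray,
                             rng: np.random.Generator, *, n_shuffle: int = 100,
                             pair=(("a", ""), ("b", ""))) -> OverlapResult:
    """Overlap classification from raw binary unit x window matrices.

    ``A`` and ``B`` are (n_units, n_windows) binary indicator matrices.
    The permutation null shuffles the unit order of ``B`` with one
    permutation per shuffle, applied to all its windows.
    """
    matrix = _cross_phi(A, B)
    if np.all(np.isnan(matrix)):
        return OverlapResult(pair=pair, matrix=matrix, mean_r=np.nan,
                             shuffle_mean=np.nan, shuffle_sd=np.nan,
                             z=np.nan, label="not assessable")
    mean_r = float(np.nanmean(matrix))
    n = A.shape[0]
    shuffle_means = np.empty(n_shuffle)
    for s in range(n_shuffle):
        perm = rng.permutation(n)
        shuffle_means[s] = np.nanmean(_cross_phi(A, B[perm]))
    sm = float(shuffle_means.mean())
    sd = float(shuffle_means.std(ddof=1))
    if sd > 0:
        z = (mean_r - sm) / sd
    else:
        z = 0.0 if mean_r == sm else float(np.copysign(np.inf, mean_r - sm))
    if z < -1.96:
        label = "separate"
    elif z > 1.96:
        label = "joint"
    else:
        label = "independent"
    return OverlapResult(pair=pair, matrix=matrix, mean_r=mean_r,
                         shuffle_mean=sm, shuffle_sd=sd, z=float(z), label=label)
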