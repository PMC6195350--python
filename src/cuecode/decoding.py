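"""Pseudoensemble linear-discriminant decoding of cue features.

Units recorded in different sessions are combined into a pseudoensemble by
aligning trials within condition labels: for each class of the target
feature, every unit's trials are subsampled without replacement down to the
minimum per-class trial count across units, and the i-th sampled trial of
each unit forms one pseudotrial row.  An LDA classifier (least-squares
solver with Ledoit-Wolf shrinkage, so near-singular pooled covariances are
handled) is evaluated with stratified 10-fold cross-validation; the
ensemble is rebuilt and re-subsampled on every iteration.  Chance level is
assessed with a per-unit shuffle: each column of the pseudoensemble matrix
is permuted independently, destroying the label alignment of that unit
while preserving its rate distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold

from .screening import windowed_rates

FEATURE_COLUMNS = {"identity": "identity", "location": "location", "outcome": "outcome"}


@dataclass
class Pseudoensemble:
    """Pseudotrial x unit firing-rate matrix with aligned class labels."""

    rates: np.ndarray          # (n_pseudotrials, n_units)
    labels: np.ndarray         # (n_pseudotrials,)
    unit_ids: list
    per_class: int             # balanced trial count per class

    @property
    def classes(self):
        return np.unique(self.labels)


@dataclass
class DecodingResult:
    """Observed and shuffle-null accuracy for one feature and window."""

    feature: str
    window: tuple
    accuracies: np.ndarray     # per iteration
    shuffle_accuracies: np.ndarray
    z: float
    sd_zero: bool = False

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    @property
    def significant(self) -> bool:
        return self.z > 1.96


def unit_feature_rates(units: dict, trials: pd.DataFrame, feature: str,
                       window: tuple, event: str = "cue_onset"):
    """Per-unit (labels, rates) pairs for one window around ``event``.

    For a single simulated session all units share the same trials; the
    pseudoensemble builder below does not rely on that and accepts
    per-unit label/rate pairs from different sessions.
    """
    col = FEATURE_COLUMNS[feature]
    time_col = {"cue_onset": "t_cue_onset", "nosepoke": "t_nosepoke",
                "outcome": "t_outcome"}[event]
    sub = trials.dropna(subset=[time_col])
    labels = sub[col].to_numpy()
    events = sub[time_col].to_numpy(float)
    return {uid: (labels, windowed_rates(spk, events, window))
            for uid, spk in units.items()}


def build_pseudoensemble(unit_data: dict, rng: np.random.Generator,
                         min_per_class: int = 2) -> Pseudoensemble:
    """Subsample each unit to the minimum per-class count and align rows.

    ``unit_data`` maps unit id to ``(labels, rates)``.  Units missing a
    class entirely are dropped with a warning-free skip (recorded in the
    returned ensemble only implicitly by absence).
    """
    all_classes = np.unique(np.concatenate([np.unique(lab) for lab, _ in unit_data.values()]))
    usable = {}
    for uid, (lab, rates) in unit_data.items():
        counts = {c: int(np.sum(lab == c)) for c in all_classes}
        if all(v >= min_per_class for v in counts.values()):
            usable[uid] = (lab, rates, counts)
    if not usable:
        raise ValueError("no unit has enough trials in every class")
    per_class = min(min(counts.values()) for _, _, counts in usable.values())
    unit_ids = sorted(usable)
    blocks, labels = [], []
    for c in all_classes:
        cols = []
        for uid in unit_ids:
            lab, rates, _ = usable[uid]
            idx = np.flatnonzero(lab == c)
            take = rng.choice(idx, size=per_class, replace=False)
            cols.append(rates[take])
        blocks.append(np.column_stack(cols))
        labels.extend([c] * per_class)
    return Pseudoensemble(rates=np.vstack(blocks), labels=np.asarray(labels),
                          unit_ids=unit_ids, per_class=per_class)


def _lda():
    return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")


def _kfold_accuracy(rates: np.ndarray, labels: np.ndarray, k: int,
                    seed: int) -> float:
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    correct = 0
    for train, test in skf.split(rates, labels):
        clf = _lda().fit(rates[train], labels[train])
        correct += int(np.sum(clf.predict(rates[test]) == labels[test]))
    return correct / len(labels)


def lda_crossval(unit_data: dict, rng: np.random.Generator, *, k: int = 10,
                 iterations: int = 100) -> np.ndarray:
    """Cross-validated accuracy distribution over rebuilt pseudoensembles.

    Each iteration re-subsamples the pseudoensemble and runs one stratified
    ``k``-fold pass; the returned array holds one mean held-out accuracy per
    iteration.
    """
    ens0 = build_pseudoensemble(unit_data, rng)
    if len(ens0.classes) < 2:
        raise ValueError("decoding needs at least two classes")
    if ens0.per_class < k:
        raise ValueError(f"need at least {k} pseudotrials per class")
    accs = np.empty(iterations)
    for i in range(iterations):
        ens = build_pseudoensemble(unit_data, rng)
        accs[i] = _kfold_accuracy(ens.rates, ens.labels, k,
                                  seed=int(rng.integers(2**31 - 1)))
    return accs


def decode_with_null(unit_data: dict, rng: np.random.Generator, *,
                     feature: str = "", window: tuple = (0.0, 0.5),
                     k: int = 10, iterations: int = 100,
                     n_shuffle: int = 100) -> DecodingResult:
    """Observed accuracy vs a per-unit column-shuffle null.

    Each shuffle builds a fresh pseudoensemble, independently permutes every
    column (unit) of the rate matrix, and runs one ``k``-fold pass.
    ``z = (mean observed - shuffle mean) / shuffle SD``.
    """
    accs = lda_crossval(unit_data, rng, k=k, iterations=iterations)
    shuffle_accs = np.empty(n_shuffle)
    for s in range(n_shuffle):
        ens = build_pseudoensemble(unit_data, rng)
        shuffled = rng.permuted(ens.rates, axis=0)    # per-column permutation
        shuffle_accs[s] = _kfold_accuracy(shuffled, ens.labels, k,
                                          seed=int(rng.integers(2**31 - 1)))
    sd = shuffle_accs.std(ddof=1)
    if sd > 0:
        z = float((accs.mean() - shuffle_accs.mean()) / sd)
        flag = False
    else:
        diff = accs.mean() - shuffle_accs.mean()
        z = 0.0 if diff == 0 else float(np.copysign(np.inf, diff))
        flag = diff != 0
    return DecodingResult(feature=feature, window=window, accuracies=accs,
                          shuffle_accuracies=shuffle_accs, z=z, sd_zero=flag)


def sliding_decode(units: dict, trials: pd.DataFrame, feature: str,
                   grid, rng: np.random.Generator, *, event: str = "cue_onset",
                   k: int = 10, iterations: int = 100,
                   n_shuffle: int = 100) -> pd.DataFrame:
    """Run :func:`decode_with_null` for every window of a grid."""
    rows = []
    for (lo, hi), c in zip(grid.windows(), grid.centers):
        data = unit_feature_rates(units, trials, feature, (lo, hi), event)
        res = decode_with_null(data, rng, feature=feature, window=(lo, hi),
                               k=k, iterations=iterations, n_shuffle=n_shuffle)
        rows.append({"feature": feature, "window_center": c,
                     "mean_accuracy": res.mean_accuracy,
                     "shuffle_mean": float(res.shuffle_accuracies.mean()),
                     "shuffle_sd": float(res.shuffle_accuracies.std(ddof=1)),
                     "z": res.z, "significant": res.significant})
    return pd.DataFrame(rows)
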