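"""Sliding-window forward-stepwise Poisson GLMs with shuffle nulls.

For each unit and each 500 ms window (stepped by 100 ms, 11 windows centred
-0.25 s ... +0.75 s around an event), the spike count per trial is regressed
on task predictors -- cue identity, cue location (4 arms), cue outcome,
approach behaviour, trial length, trial number, and trial history (outcome
on the previous two trials) -- by forward selection: starting from the
intercept-only model, the candidate block whose addition gives the smallest
chi-square p-value for its deviance drop is added while that p-value is
below ``alpha_enter`` (default .01).  Categorical predictors enter as whole
blocks of indicator columns.  There is no removal step.

Variance attribution uses the deviance pseudo-R-squared
``R2 = 1 - D(model)/D(intercept-only)``; the partial R-squared of a selected
predictor is ``R2(final) - R2(final minus predictor)``, floored at zero.

Population-level significance of the proportion of units selecting a
predictor is assessed against a shuffle null: each shuffle independently
permutes every unit's per-trial counts within each window (the design is
left untouched), the whole stepwise sweep is rerun, and the observed
proportion is z-scored against the shuffled proportions (|z| > 1.96).

The Poisson fits use an in-package batched IRLS solver so that a full sweep
(units x windows x candidate models, repeated per shuffle) stays cheap; the
solver is cross-checked against statsmodels in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .screening import windowed_counts

PREDICTOR_ORDER = ["identity", "location", "outcome", "approach",
                   "trial_length", "trial_number", "history"]

_ETA_CAP = 30.0          # caps linear predictor; guards perfect separation
_RIDGE = 1e-9            # jitter on the normal matrix for near-singular steps


@dataclass(frozen=True)
class WindowGrid:
    """Sliding-window grid around an alignment event."""

    width: float = 0.5
    step: float = 0.1
    centers: tuple = tuple(np.round(np.arange(-0.25, 0.7501, 0.1), 10))

    def windows(self):
        half = self.width / 2.0
        return [(c - half, c + half) for c in self.centers]

    def post_event_centers(self):
        """Centers whose windows lie fully after the event."""
        half = self.width / 2.0
        return [c for c in self.centers if c - half >= 0.0]


@dataclass
class DesignInfo:
    """Design matrix (no intercept column) plus predictor block layout."""

    X: np.ndarray                    # (n_trials_included, P)
    blocks: list                     # [(name, np.ndarray of column indices)]
    event_times: np.ndarray          # (n_trials_included,)
    trial_index: np.ndarray          # original trial numbers of included rows
    dropped: list = field(default_factory=list)   # constant predictors removed

    def block_names(self):
        return [name for name, _ in self.blocks]


def build_design(trials: pd.DataFrame, event: str = "cue_onset", *,
                 approach_only: bool = False) -> DesignInfo:
    """Assemble the predictor design aligned to ``event``.

    ``cue_onset`` uses every trial (or approach trials only when
    ``approach_only``); ``nosepoke`` and ``outcome`` use approach trials.
    Continuous predictors are standardized over the included trials;
    history is block-relative with a missing indicator on each block's
    first two trials.  Predictors constant over the included trials are
    dropped from the candidate set with a warning.
    """
    if event == "cue_onset":
        mask = np.ones(len(trials), dtype=bool)
        if approach_only:
            mask &= (trials["behaviour"] == "approach").to_numpy()
        time_col = "t_cue_onset"
    elif event in ("nosepoke", "outcome"):
        mask = (trials["behaviour"] == "approach").to_numpy()
        time_col = "t_nosepoke" if event == "nosepoke" else "t_outcome"
    else:
        raise ValueError(f"unknown event {event!r}")

    # history is defined on the full trial table (block-relative), then masked
    n = len(trials)
    avail = (trials["outcome"] == "available").to_numpy().astype(float)
    block = trials["block"].to_numpy()
    prev1 = np.zeros(n); prev2 = np.zeros(n); missing = np.zeros(n)
    for i in range(n):
        if i >= 1 and block[i - 1] == block[i]:
            prev1[i] = avail[i - 1]
        else:
            missing[i] = 1.0
        if i >= 2 and block[i - 2] == block[i]:
            prev2[i] = avail[i - 2]
        else:
            missing[i] = 1.0

    sub = trials[mask]
    columns = {}
    columns["identity"] = [(sub["identity"] == "sound").to_numpy(float)]
    columns["location"] = [(sub["location"] == arm).to_numpy(float) for arm in (2, 3, 4)]
    columns["outcome"] = [(sub["outcome"] == "available").to_numpy(float)]
    columns["approach"] = [(sub["behaviour"] == "approach").to_numpy(float)]
    columns["trial_length"] = [_standardize(sub["trial_length"].to_numpy(float))]
    columns["trial_number"] = [_standardize(sub["trial"].to_numpy(float))]
    columns["history"] = [prev1[mask], prev2[mask], missing[mask]]

    X_cols, blocks, dropped = [], [], []
    for name in PREDICTOR_ORDER:
        cols = [c for c in columns[name] if np.ptp(c) > 0]
        if not cols:
            dropped.append(name)
            warnings.warn(f"predictor {name!r} constant over included trials; dropped",
                          stacklevel=2)
            continue
        idx = np.arange(len(X_cols), len(X_cols) + len(cols))
        blocks.append((name, idx))
        X_cols.extend(cols)
    X = np.column_stack(X_cols) if X_cols else np.empty((mask.sum(), 0))
    return DesignInfo(X=X, blocks=blocks,
                      event_times=sub[time_col].to_numpy(float),
                      trial_index=sub["trial"].to_numpy(), dropped=dropped)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


# ---------------------------------------------------------------------------
# batched Poisson IRLS
# ---------------------------------------------------------------------------

def poisson_deviance(Y: np.ndarray, MU: np.ndarray) -> np.ndarray:
    """Poisson deviance per response column; ``Y`` and ``MU`` are (n, B)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = Y * np.log(Y / MU)
    term = np.where(Y > 0, term, 0.0)
    return 2.0 * np.sum(term - (Y - MU), axis=0)


def fit_poisson_batch(X: np.ndarray, Y: np.ndarray, *, max_iter: int = 50,
                      tol: float = 1e-9):
    """IRLS fit of ``B`` Poisson log-link regressions sharing one design.

    ``X`` is (n, p) including the intercept column; ``Y`` is (n, B).
    Returns ``(beta (B, p), deviance (B,), converged (B,))``.
    """
    n, p = X.shape
    Y = np.asarray(Y, dtype=float)
    B = Y.shape[1]
    beta = np.zeros((B, p))
    beta[:, 0] = np.log(np.maximum(Y.mean(axis=0), 1e-12))
    dev = np.full(B, np.inf)
    converged = np.zeros(B, dtype=bool)
    eye = np.eye(p) * _RIDGE
    for _ in range(max_iter):
        eta = np.clip(X @ beta.T, -_ETA_CAP, _ETA_CAP)
        mu = np.exp(eta)
        new_dev = poisson_deviance(Y, mu)
        converged = np.abs(dev - new_dev) < tol * (np.abs(new_dev) + 0.1)
        dev = new_dev
        if converged.all():
            break
        W = mu                                   # Poisson working weights
        Z = eta + (Y - mu) / mu                  # working response
        XtWX = np.einsum("np,nb,nq->bpq", X, W, X, optimize=True) + eye
        XtWz = np.einsum("np,nb->bp", X, W * Z, optimize=True)
        try:
            beta = np.linalg.solve(XtWX, XtWz[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            beta = np.linalg.solve(XtWX + np.eye(p) * 1e-6, XtWz[:, :, None])[:, :, 0]
    return beta, dev, converged


def fit_poisson(X: np.ndarray, y: np.ndarray, **kw):
    """Single-response convenience wrapper around :func:`fit_poisson_batch`."""
    beta, dev, ok = fit_poisson_batch(X, np.asarray(y, float)[:, None], **kw)
    return beta[0], float(dev[0]), bool(ok[0])


def _null_deviance(Y: np.ndarray) -> np.ndarray:
    mu = np.maximum(Y.mean(axis=0), 1e-12)
    return poisson_deviance(Y, np.broadcast_to(mu, Y.shape))


# ---------------------------------------------------------------------------
# forward stepwise selection
# ---------------------------------------------------------------------------

@dataclass
class StepwiseFit:
    """Final model of one forward-stepwise fit."""

    selected: tuple                 # block names in entry order
    coefficients: dict              # block name -> np.ndarray of coefficients
    intercept: float
    deviance: float
    null_deviance: float
    partial_r2: dict                # block name -> float (selected blocks only)
    converged: bool = True

    @property
    def pseudo_r2(self) -> float:
        if self.null_deviance <= 0:
            return np.nan
        return 1.0 - self.deviance / self.null_deviance


def _design_with(X: np.ndarray, blocks: dict, names) -> np.ndarray:
    cols = [np.ones(X.shape[0])]
    for name in names:
        cols.append(X[:, blocks[name]])
    return np.column_stack(cols)


def stepwise_batch(X: np.ndarray, blocks: list, Y: np.ndarray,
                   alpha_enter: float = 0.01, compute_partial: bool = True):
    """Forward-stepwise Poisson selection for many responses sharing a design.

    ``blocks`` is ``[(name, column indices)]`` in the canonical tie-break
    order; ``Y`` is (n, B).  Responses with identical current selections are
    fitted in one batched IRLS call per candidate.  Returns a list of
    :class:`StepwiseFit`, one per response column.
    """
    n, B = Y.shape[0], Y.shape[1]
    block_map = {name: idx for name, idx in blocks}
    order = [name for name, _ in blocks]
    dev_null = _null_deviance(Y)
    sel = [tuple() for _ in range(B)]
    dev_cur = dev_null.copy()
    active = np.ones(B, dtype=bool)
    all_ok = np.ones(B, dtype=bool)

    while active.any():
        groups = {}
        for b in np.where(active)[0]:
            groups.setdefault(sel[b], []).append(b)
        any_added = False
        for key, idx_list in groups.items():
            idx = np.array(idx_list)
            candidates = [nm for nm in order if nm not in key]
            if not candidates:
                active[idx] = False
                continue
            P = np.ones((len(idx), len(candidates)))
            D = np.zeros((len(idx), len(candidates)))
            for j, cand in enumerate(candidates):
                Xc = _design_with(X, block_map, list(key) + [cand])
                _, dev, ok = fit_poisson_batch(Xc, Y[:, idx])
                drop = np.maximum(dev_cur[idx] - dev, 0.0)
                pj = stats.chi2.sf(drop, df=len(block_map[cand]))
                pj = np.where(ok, pj, 1.0)      # nonconverged candidate skipped
                all_ok[idx] &= ok | (pj >= alpha_enter)
                P[:, j] = pj
                D[:, j] = dev
            best = np.argmin(P, axis=1)          # ties -> first (canonical order)
            rows = np.arange(len(idx))
            add = P[rows, best] < alpha_enter
            for r, b in enumerate(idx):
                if add[r]:
                    sel[b] = tuple(list(sel[b]) + [candidates[best[r]]])
                    dev_cur[b] = D[r, best[r]]
                    any_added = True
                else:
                    active[b] = False
        if not any_added:
            break

    # final refits (coefficients, partial R2), grouped by final selection
    fits: list = [None] * B
    groups = {}
    for b in range(B):
        groups.setdefault(sel[b], []).append(b)
    for key, idx_list in groups.items():
        idx = np.array(idx_list)
        Xf = _design_with(X, block_map, list(key))
        beta, dev, ok = fit_poisson_batch(Xf, Y[:, idx])
        partial = {nm: np.zeros(len(idx)) for nm in key}
        if compute_partial:
            for nm in key:
                rest = [m for m in key if m != nm]
                Xm = _design_with(X, block_map, rest)
                _, dev_m, _ = fit_poisson_batch(Xm, Y[:, idx])
                partial[nm] = np.maximum(dev_m - dev, 0.0)
        col_of = {}
        pos = 1
        for nm in key:
            col_of[nm] = np.arange(pos, pos + len(block_map[nm]))
            pos += len(block_map[nm])
        for r, b in enumerate(idx):
            nd = dev_null[b]
            fits[b] = StepwiseFit(
                selected=key,
                coefficients={nm: beta[r, col_of[nm]] for nm in key},
                intercept=float(beta[r, 0]),
                deviance=float(dev[r]),
                null_deviance=float(nd),
                partial_r2={nm: (float(partial[nm][r] / nd) if nd > 0 else np.nan)
                            for nm in key},
                converged=bool(all_ok[b] and ok[r]),
            )
    return fits


def forward_stepwise_poisson(counts: np.ndarray, design: DesignInfo,
                             alpha_enter: float = 0.01) -> StepwiseFit:
    """Forward-stepwise Poisson regression of one count vector.

    Starts from the intercept-only model; at each round the candidate block
    with the smallest deviance-drop chi-square p-value enters if that
    p-value is below ``alpha_enter``; stops otherwise.
    """
    counts = np.asarray(counts)
    if counts.shape[0] < 10:
        raise ValueError("need at least 10 trials")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("counts must be nonnegative integers")
    return stepwise_batch(design.X, design.blocks, counts[:, None].astype(float),
                          alpha_enter=alpha_enter)[0]


def partial_r2(fit: StepwiseFit, predictor: str) -> float:
    """Deviance pseudo-R2 attributable to one selected predictor."""
    if predictor not in fit.selected:
        raise ValueError(f"{predictor!r} not in the final model")
    return fit.partial_r2[predictor]


# ---------------------------------------------------------------------------
# sliding sweep and shuffle null
# ---------------------------------------------------------------------------

@dataclass
class SelectionMatrix:
    """Long-form unit x window x predictor selection results."""

    table: pd.DataFrame              # unit, window_center, predictor, selected, ...
    event: str
    grid: WindowGrid
    unit_ids: list
    predictors: list

    def selected_vector(self, predictor: str, center: float) -> np.ndarray:
        """Binary selection indicator over units (sorted by unit id)."""
        if predictor not in self.predictors:
            raise ValueError(f"predictor {predictor!r} not in selection matrix")
        sub = self.table[(self.table["predictor"] == predictor)
                         & np.isclose(self.table["window_center"], center)]
        sub = sub.set_index("unit").loc[self.unit_ids]
        return sub["selected"].to_numpy(int)


def _window_counts(units: dict, design: DesignInfo, grid: WindowGrid):
    """Counts (n_trials, n_units * n_windows); columns ordered unit-major."""
    unit_ids = sorted(units)
    cols = []
    meta = []
    for uid in unit_ids:
        spk = units[uid]
        for (lo, hi), c in zip(grid.windows(), grid.centers):
            cols.append(windowed_counts(spk, design.event_times, (lo, hi)))
            meta.append((uid, c))
    return np.column_stack(cols).astype(float), meta, unit_ids


def run_sliding_glm(units: dict, trials: pd.DataFrame, event: str = "cue_onset",
                    grid: WindowGrid | None = None, *, alpha_enter: float = 0.01,
                    approach_only: bool = False,
                    compute_partial: bool = True) -> SelectionMatrix:
    """One forward-stepwise Poisson fit per unit per window.

    ``units`` maps unit id to sorted spike times (normally the screened
    cue-modulated set).  Returns a :class:`SelectionMatrix` whose table has
    one row per (unit, window, predictor) with the selection indicator, the
    coefficient (single-column predictors), the partial R-squared, and the
    final-model deviance of that window's fit.
    """
    grid = grid or WindowGrid()
    design = build_design(trials, event, approach_only=approach_only)
    Y, meta, unit_ids = _window_counts(units, design, grid)
    fits = stepwise_batch(design.X, design.blocks, Y, alpha_enter=alpha_enter,
                          compute_partial=compute_partial)
    predictors = design.block_names()
    rows = []
    for (uid, center), fit in zip(meta, fits):
        for name in predictors:
            in_model = name in fit.selected
            coef = fit.coefficients[name] if in_model else None
            rows.append({
                "unit": uid, "event": event, "window_center": center,
                "predictor": name, "selected": int(in_model),
                "coefficient": float(coef[0]) if in_model and len(coef) == 1 else np.nan,
                "partial_r2": fit.partial_r2.get(name, np.nan) if in_model else np.nan,
                "deviance": fit.deviance,
            })
    return SelectionMatrix(table=pd.DataFrame(rows), event=event, grid=grid,
                           unit_ids=unit_ids, predictors=predictors)


def _proportions(fits, meta, unit_ids, predictors, centers) -> np.ndarray:
    """Selection proportion per (predictor, window) over units."""
    out = np.zeros((len(predictors), len(centers)))
    cindex = {c: j for j, c in enumerate(centers)}
    pindex = {p: i for i, p in enumerate(predictors)}
    for (uid, center), fit in zip(meta, fits):
        j = cindex[center]
        for name in fit.selected:
            out[pindex[name], j] += 1
    return out / len(unit_ids)


def shuffle_proportion_test(units: dict, trials: pd.DataFrame,
                            event: str = "cue_onset", grid: WindowGrid | None = None,
                            *, n_shuffle: int = 100, alpha_enter: float = 0.01,
                            approach_only: bool = False,
                            rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Shuffle null for the proportion of units selecting each predictor.

    Each shuffle independently permutes every unit's per-trial counts within
    each window (design rows fixed) and reruns the full stepwise sweep.
    ``z = (observed - shuffle mean) / shuffle SD`` (sample SD); cells where
    the shuffle SD is zero carry a signed-infinity sentinel and a flag.
    """
    rng = rng or np.random.default_rng()
    grid = grid or WindowGrid()
    design = build_design(trials, event, approach_only=approach_only)
    Y, meta, unit_ids = _window_counts(units, design, grid)
    predictors = design.block_names()
    centers = list(grid.centers)

    fits = stepwise_batch(design.X, design.blocks, Y, alpha_enter, compute_partial=False)
    observed = _proportions(fits, meta, unit_ids, predictors, centers)

    shuffled = np.zeros((n_shuffle, len(predictors), len(centers)))
    for s in range(n_shuffle):
        Ys = rng.permuted(Y, axis=0)     # independent permutation per column
        sfits = stepwise_batch(design.X, design.blocks, Ys, alpha_enter,
                               compute_partial=False)
        shuffled[s] = _proportions(sfits, meta, unit_ids, predictors, centers)

    mean = shuffled.mean(axis=0)
    sd = shuffled.std(axis=0, ddof=1)
    rows = []
    for i, name in enumerate(predictors):
        for j, c in enumerate(centers):
            if sd[i, j] > 0:
                z = (observed[i, j] - mean[i, j]) / sd[i, j]
                flag = False
            else:
                diff = observed[i, j] - mean[i, j]
                z = 0.0 if diff == 0 else np.copysign(np.inf, diff)
                flag = diff != 0
            rows.append({"predictor": name, "window_center": c,
                         "observed": observed[i, j], "shuffle_mean": mean[i, j],
                         "shuffle_sd": sd[i, j], "z": z,
                         "significant": abs(z) > 1.96, "sd_zero": flag})
    return pd.DataFrame(rows)
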