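"""Population-level PETH structure and split-half block comparisons.

Spike trains are convolved with a Gaussian kernel (sigma = 100 ms by
default); peri-event time histograms (PETHs) average the convolved rate
over trials of a condition.  Population heatmaps z-score each unit's PETH
and order units by the time of their peak (or trough) firing; applying one
condition's ordering to another condition visualizes how much temporal
structure is shared.

The split-half analysis asks whether across-condition PETH correlations are
lower than within-condition ones: each condition's trials are shuffled
(controlling for time-in-session), split into halves, half-PETHs computed,
and the 6 pairwise correlations among the 4 half-PETHs recorded per unit.
A linear mixed model with comparison type as the fixed effect and unit as a
random intercept, compared against the no-comparison-type null by a
likelihood-ratio test, summarizes whether the population discriminates the
conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

COMPARISONS = ["within_a", "within_b", "a1b1", "a1b2", "a2b1", "a2b2"]


def smooth_spike_train(spike_times: np.ndarray, t_grid: np.ndarray,
                       sigma: float = 0.1) -> np.ndarray:
    """Gaussian-convolved firing rate evaluated on ``t_grid`` (Hz).

    The kernel integrates to one, so the time-integral of the returned rate
    equals the spike count, up to truncation for spikes near the grid edges.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    rate = np.zeros_like(t_grid)
    if len(spike_times) == 0:
        return rate
    lo, hi = t_grid[0] - 6 * sigma, t_grid[-1] + 6 * sigma
    spk = spike_times[(spike_times >= lo) & (spike_times <= hi)]
    norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
    for s in spk:        # few spikes per window; direct evaluation is exact
        rate += norm * np.exp(-0.5 * ((t_grid - s) / sigma) ** 2)
    return rate


def peth(spike_times: np.ndarray, event_times: np.ndarray,
         span: tuple = (-1.0, 2.0), *, sigma: float = 0.1,
         dt: float = 0.02) -> tuple:
    """Trial-averaged smoothed rate around an event.

    Returns ``(t_rel, rate)`` where ``t_rel`` is time relative to the event.
    """
    if dt > sigma / 2:
        raise ValueError("dt must be <= sigma/2")
    events = np.asarray(event_times, dtype=float)
    if events.size == 0:
        raise ValueError("peth needs at least one trial")
    t_rel = np.arange(span[0], span[1] + dt / 2, dt)
    acc = np.zeros_like(t_rel)
    for e in events:
        sel = spike_times[(spike_times >= e + span[0] - 6 * sigma)
                          & (spike_times <= e + span[1] + 6 * sigma)]
        acc += smooth_spike_train(sel - e, t_rel, sigma)
    return t_rel, acc / events.size


@dataclass
class PethMatrix:
    """Unit x timebin (optionally z-scored) rates for one condition."""

    data: np.ndarray
    times: np.ndarray
    unit_ids: list
    condition: str
    normalization: str = "raw"          # raw | zscored
    sort_order: np.ndarray | None = None
    sort_source: str | None = None
    flat_units: np.ndarray | None = None


def condition_peths(units: dict, trials: pd.DataFrame, condition_mask,
                    condition_name: str, *, event_col: str = "t_cue_onset",
                    span: tuple = (-1.0, 2.0), sigma: float = 0.1,
                    dt: float = 0.02) -> PethMatrix:
    """PETH matrix over all units for the trials selected by the mask."""
    events = trials.loc[condition_mask, event_col].dropna().to_numpy(float)
    unit_ids = sorted(units)
    rows = []
    for uid in unit_ids:
        t_rel, rate = peth(units[uid], events, span, sigma=sigma, dt=dt)
        rows.append(rate)
    return PethMatrix(data=np.asarray(rows), times=t_rel, unit_ids=unit_ids,
                      condition=condition_name)


def zscore_rows(matrices: list, pooled: bool = True) -> list:
    """z-score each unit's PETH; with ``pooled`` the mean/SD per unit is taken
    over the time bins of all given conditions so they share one scale.

    Flat rows (SD 0) are left at zero and flagged.
    """
    stack = np.concatenate([m.data for m in matrices], axis=1) if pooled else None
    out = []
    for m in matrices:
        ref = stack if pooled else m.data
        mu = ref.mean(axis=1, keepdims=True)
        sd = ref.std(axis=1, keepdims=True)
        flat = sd[:, 0] == 0
        safe = np.where(sd == 0, 1.0, sd)
        z = (m.data - mu) / safe
        z[flat] = 0.0
        out.append(PethMatrix(data=z, times=m.times, unit_ids=m.unit_ids,
                              condition=m.condition, normalization="zscored",
                              flat_units=flat))
    return out


def sort_heatmap(target: PethMatrix, order_source: PethMatrix | None = None,
                 by: str = "max") -> PethMatrix:
    """Order units by the time of their rate extremum.

    The ordering is derived from ``order_source`` (default: the target
    itself) and applied to the target, supporting cross-condition sorting.
    Flat rows sort last.
    """
    src = order_source or target
    if by == "max":
        extremum_bin = np.argmax(src.data, axis=1)
    elif by == "min":
        extremum_bin = np.argmin(src.data, axis=1)
    else:
        raise ValueError("by must be 'max' or 'min'")
    key = extremum_bin.astype(float)
    if src.flat_units is not None:
        key[src.flat_units] = np.inf
    order = np.argsort(key, kind="stable")
    return PethMatrix(data=target.data[order], times=target.times,
                      unit_ids=[target.unit_ids[i] for i in order],
                      condition=target.condition,
                      normalization=target.normalization,
                      sort_order=order, sort_source=src.condition,
                      flat_units=(target.flat_units[order]
                                  if target.flat_units is not None else None))


# ---------------------------------------------------------------------------
# split-half analysis
# ---------------------------------------------------------------------------

def split_half_correlations(units: dict, trials: pd.DataFrame,
                            feature: str, rng: np.random.Generator, *,
                            conditions: tuple | None = None,
                            event_col: str = "t_cue_onset",
                            span: tuple = (-1.0, 2.0), sigma: float = 0.1,
                            dt: float = 0.05) -> pd.DataFrame:
    """Within- vs across-condition split-half PETH correlations.

    For each unit and each of the two conditions, trials are shuffled and
    split into halves (odd counts: the extra trial joins the first half);
    the 6 pairwise Pearson correlations among the 4 half-PETHs are
    recorded: within-A, within-B, and the four across pairings.  Returns a
    long table (unit, comparison, r) with 6 rows per unit.
    """
    levels = conditions or tuple(pd.unique(trials[feature]))[:2]
    if len(levels) != 2:
        raise ValueError("split-half comparison needs exactly two conditions")
    halves = {}
    for name, level in zip(("a", "b"), levels):
        events = trials.loc[trials[feature] == level, event_col].dropna().to_numpy(float)
        if events.size < 2:
            raise ValueError(f"condition {level!r} has fewer than 2 trials")
        perm = rng.permutation(events.size)
        cut = (events.size + 1) // 2           # extra trial -> first half
        halves[name + "1"] = events[perm[:cut]]
        halves[name + "2"] = events[perm[cut:]]
    rows = []
    for uid in sorted(units):
        spk = units[uid]
        series = {}
        for key, ev in halves.items():
            _, series[key] = peth(spk, ev, span, sigma=sigma, dt=dt)
        for comp, (x, y) in {
                "within_a": ("a1", "a2"), "within_b": ("b1", "b2"),
                "a1b1": ("a1", "b1"), "a1b2": ("a1", "b2"),
                "a2b1": ("a2", "b1"), "a2b2": ("a2", "b2")}.items():
            sx, sy = series[x], series[y]
            if sx.std() == 0 or sy.std() == 0:
                r = np.nan                      # flat half; flagged as missing
            else:
                r = float(np.corrcoef(sx, sy)[0, 1])
            rows.append({"unit": uid, "comparison": comp, "r": r,
                         "within": comp.startswith("within")})
    return pd.DataFrame(rows)


@dataclass
class LmeComparison:
    """Mixed-model summary of the split-half comparison-type effect."""

    fixed_effects: dict
    llf_full: float
    llf_null: float
    lrt_stat: float
    lrt_df: int
    p_value: float
    mean_within: float
    mean_across: float
    fallback_ols: bool = False


def lme_block_comparison(table: pd.DataFrame) -> LmeComparison:
    """Comparison-type fixed effect with a per-unit random intercept.

    Both the full model (``r ~ comparison``) and the null (``r ~ 1``) are
    fitted by maximum likelihood and compared by a likelihood-ratio test.
    A singular random-effect fit falls back to fixed-effects-only OLS with
    a warning.
    """
    df = table.dropna(subset=["r"]).copy()
    types = sorted(df["comparison"].unique())
    if len(types) < 2 or df["unit"].nunique() < 2:
        raise ValueError("need >= 2 comparison types and >= 2 units")
    # reference level: a within-block comparison
    ref = "within_a" if "within_a" in types else types[0]
    df["comparison"] = pd.Categorical(
        df["comparison"], categories=[ref] + [t for t in types if t != ref])
    fallback = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            full = smf.mixedlm("r ~ C(comparison)", df, groups=df["unit"]).fit(reml=False)
            null = smf.mixedlm("r ~ 1", df, groups=df["unit"]).fit(reml=False)
        if not (np.isfinite(full.llf) and np.isfinite(null.llf)):
            raise ValueError("singular mixed fit")
        llf_full, llf_null = full.llf, null.llf
        params = {k: float(v) for k, v in full.fe_params.items()}
    except Exception:
        fallback = True
        warnings.warn("singular mixed-model fit; falling back to OLS", stacklevel=2)
        full = smf.ols("r ~ C(comparison)", df).fit()
        null = smf.ols("r ~ 1", df).fit()
        llf_full, llf_null = full.llf, null.llf
        params = {k: float(v) for k, v in full.params.items()}
    lrt = max(0.0, 2.0 * (llf_full - llf_null))
    dof = len(types) - 1
    p = float(stats.chi2.sf(lrt, dof))
    return LmeComparison(
        fixed_effects=params, llf_full=float(llf_full), llf_null=float(llf_null),
        lrt_stat=float(lrt), lrt_df=dof, p_value=p,
        mean_within=float(df.loc[df["within"], "r"].mean()),
        mean_across=float(df.loc[~df["within"], "r"].mean()),
        fallback_ols=fallback)
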