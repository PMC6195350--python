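"""Behavioural statistics: discrimination, learning criterion, mixed models.

Discrimination within a block is a Pearson chi-square on the 2 x 2 table of
approach/skip by reward-available/unavailable (1 df, no continuity
correction by default).  The learning criterion is the earliest day on
which both blocks are significant (p < .05) for three consecutive days.
Session-level approach proportions are modelled with a linear mixed model
(cue outcome and cue identity as fixed effects, rat as a random intercept);
the contribution of a term is a likelihood-ratio test against the model
with that term removed, and an optional block-half term probes
within-session learning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf


def discrimination_chi_square(table, *, alpha: float = 0.05,
                              correction: bool = False) -> tuple:
    """Pearson chi-square on a 2 x 2 approach x outcome count table.

    Rows: (approached, skipped); columns: (available, unavailable).
    Returns ``(statistic, p, significant)``; a zero margin yields
    ``(nan, nan, None)`` (not assessable).
    """
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        return np.nan, np.nan, None
    stat, p, _, _ = stats.chi2_contingency(table, correction=correction)
    return float(stat), float(p), bool(p < alpha)


def block_table(trials: pd.DataFrame, block: str) -> np.ndarray:
    """2 x 2 approach/skip x available/unavailable counts for one block."""
    sub = trials[trials["block"] == block]
    out = np.zeros((2, 2))
    for j, outcome in enumerate(("available", "unavailable")):
        s = sub[sub["outcome"] == outcome]
        out[0, j] = (s["behaviour"] == "approach").sum()
        out[1, j] = (s["behaviour"] == "skip").sum()
    return out


def behaviour_summary(trials: pd.DataFrame, *, alpha: float = 0.05) -> pd.DataFrame:
    """Per-block approach counts, proportions, and chi-square discrimination."""
    rows = []
    for block in pd.unique(trials["block"]):
        tab = block_table(trials, block)
        stat, p, flag = discrimination_chi_square(tab, alpha=alpha)
        for j, outcome in enumerate(("available", "unavailable")):
            n = tab[:, j].sum()
            rows.append({
                "block": block, "outcome": outcome,
                "n_trials": int(n), "n_approach": int(tab[0, j]),
                "prop_approach": tab[0, j] / n if n else np.nan,
                "chi_square": stat, "p": p, "discriminating": flag,
            })
    return pd.DataFrame(rows)


def learning_criterion(flags_by_block: dict, n_consecutive: int = 3):
    """Earliest day starting a run of ``n_consecutive`` days significant in
    every block; ``None`` if the criterion is never met.

    ``flags_by_block`` maps block name to a boolean sequence over days
    (aligned across blocks).  Days are numbered from 1.
    """
    flags = [np.asarray(v, dtype=bool) for v in flags_by_block.values()]
    n_days = min(len(v) for v in flags)
    if n_days < n_consecutive:
        raise ValueError(f"need at least {n_consecutive} days of data")
    both = np.all([v[:n_days] for v in flags], axis=0)
    for d in range(n_days - n_consecutive + 1):
        if both[d:d + n_consecutive].all():
            return d + 1
    return None


@dataclass
class ApproachLme:
    """Mixed-model summary of approach proportions."""

    fixed_effects: dict
    p_outcome: float
    p_identity: float
    p_block_half: float | None
    fallback_ols: bool = False


def _lrt(llf_full: float, llf_null: float, dof: int) -> float:
    if not (np.isfinite(llf_full) and np.isfinite(llf_null)):
        return 1.0          # degenerate (e.g. zero-variance) fit: no evidence
    return float(stats.chi2.sf(max(0.0, 2.0 * (llf_full - llf_null)), dof))


def _fit_ml(formula: str, df: pd.DataFrame, mixed: bool):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if mixed:
            return smf.mixedlm(formula, df, groups=df["rat"]).fit(reml=False)
        return smf.ols(formula, df).fit()


def approach_lme(sessions: pd.DataFrame, *, block_half: bool = False) -> ApproachLme:
    """Model session-level approach proportion per cue.

    ``sessions`` needs columns ``rat``, ``session``, ``identity``,
    ``outcome``, ``prop_approach`` (one row per cue per session; with
    ``block_half`` also a ``half`` column in {1, 2}).  Likelihood-ratio
    tests compare the full model to the model with the term of interest
    removed.  A singular random-effect fit falls back to OLS.
    """
    if sessions["rat"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    base = "prop_approach ~ C(outcome) + C(identity)"
    fallback = False
    try:
        full = _fit_ml(base, sessions, mixed=True)
        no_outcome = _fit_ml("prop_approach ~ C(identity)", sessions, mixed=True)
        no_identity = _fit_ml("prop_approach ~ C(outcome)", sessions, mixed=True)
        mixed = True
        # zero-variance random effect degenerates the profiled likelihood
        if not all(np.isfinite(m.llf) for m in (full, no_outcome, no_identity)):
            raise ValueError("singular mixed fit")
    except Exception:
        fallback = True
        warnings.warn("singular mixed fit; fixed-effects-only fallback", stacklevel=2)
        full = _fit_ml(base, sessions, mixed=False)
        no_outcome = _fit_ml("prop_approach ~ C(identity)", sessions, mixed=False)
        no_identity = _fit_ml("prop_approach ~ C(outcome)", sessions, mixed=False)
        mixed = False
    p_half = None
    if block_half:
        try:
            with_half = _fit_ml(base + " + C(half)", sessions, mixed=mixed)
            base_llf = full.llf
        except Exception:       # singular augmented fit: OLS pair for the LRT
            with_half = _fit_ml(base + " + C(half)", sessions, mixed=False)
            base_llf = _fit_ml(base, sessions, mixed=False).llf
        p_half = _lrt(with_half.llf, base_llf, 1)
    params = full.fe_params if mixed else full.params
    return ApproachLme(
        fixed_effects={k: float(v) for k, v in params.items()},
        p_outcome=_lrt(full.llf, no_outcome.llf, 1),
        p_identity=_lrt(full.llf, no_identity.llf, 1),
        p_block_half=p_half,
        fallback_ols=fallback)


def session_proportions(trials: pd.DataFrame, rat: str, session: int) -> pd.DataFrame:
    """Per-cue approach proportions of one session, shaped for the LME."""
    rows = []
    for (ident, outcome), sub in trials.groupby(["identity", "outcome"]):
        rows.append({"rat": rat, "session": session, "identity": ident,
                     "outcome": outcome,
                     "prop_approach": float((sub["behaviour"] == "approach").mean())})
    return pd.DataFrame(rows)
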