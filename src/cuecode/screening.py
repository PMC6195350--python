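"""Unit-inclusion funnel: spike-count floor, drift exclusion, cue modulation.

The funnel mirrors the analysis pipeline applied to the recorded data:

1. keep units with at least ``min_spikes`` (default 200) spikes in the session;
2. exclude units whose post-cue firing drifts within either block
   (Mann-Whitney U, first vs second half of the block's trials);
3. call the survivors *cue-modulated* when 1 s pre- vs post-cue firing
   differs (Wilcoxon signed-rank, p < .01), with a direction given by the
   sign of the mean post-minus-pre difference;
4. classify each unit as FSI (no interspike interval > 2 s) or MSN.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic import SpikeTrainSet


def windowed_rates(spike_times: np.ndarray, event_times: np.ndarray,
                   window: tuple) -> np.ndarray:
    """Per-event firing rate (Hz) in ``[event + lo, event + hi)``.

    The window is half-open on the right: a spike exactly at ``event + hi``
    is not counted.
    """
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError(f"degenerate window [{lo}, {hi})")
    events = np.asarray(event_times, dtype=float)
    counts = (np.searchsorted(spike_times, events + hi, side="left")
              - np.searchsorted(spike_times, events + lo, side="left"))
    return counts / (hi - lo)


def windowed_counts(spike_times: np.ndarray, event_times: np.ndarray,
                    window: tuple) -> np.ndarray:
    """Integer spike counts in ``[event + lo, event + hi)``."""
    lo, hi = float(window[0]), float(window[1])
    if hi <= lo:
        raise ValueError(f"degenerate window [{lo}, {hi})")
    events = np.asarray(event_times, dtype=float)
    return (np.searchsorted(spike_times, events + hi, side="left")
            - np.searchsorted(spike_times, events + lo, side="left"))


def drift_exclusion(spike_times: np.ndarray, trials: pd.DataFrame,
                    alpha_drift: float = 0.05) -> tuple:
    """Within-block drift check on post-cue (1 s) firing rates.

    For each block, compares rates on the first vs second half of trials
    with a two-sided Mann-Whitney U test; the unit is excluded if either
    block is significant at ``alpha_drift``.

    Returns ``(excluded, {block: p})``.
    """
    pvals = {}
    for block, sub in trials.groupby("block", sort=False):
        rates = windowed_rates(spike_times, sub["t_cue_onset"].to_numpy(), (0.0, 1.0))
        half = len(rates) // 2
        first, second = rates[:half], rates[half:]
        if len(first) == 0 or len(second) == 0:
            raise ValueError("a block half has zero trials")
        if np.all(first == first[0]) and np.all(second == second[0]) and first[0] == second[0]:
            pvals[block] = 1.0
            continue
        pvals[block] = float(stats.mannwhitneyu(first, second,
                                                alternative="two-sided").pvalue)
    excluded = any(p < alpha_drift for p in pvals.values())
    return excluded, pvals


def cue_modulation_test(spike_times: np.ndarray, trials: pd.DataFrame,
                        alpha_cue: float = 0.01) -> tuple:
    """Paired pre- vs post-cue comparison pooled over all trials.

    Wilcoxon signed-rank on 1 s pre-cue vs 1 s post-cue rates; direction is
    the sign of ``mean(post - pre)``.  Returns ``(modulated, p, direction)``.
    """
    events = trials["t_cue_onset"].to_numpy()
    pre = windowed_rates(spike_times, events, (-1.0, 0.0))
    post = windowed_rates(spike_times, events, (0.0, 1.0))
    diffs = post - pre
    if np.all(diffs == 0):
        return False, 1.0, "none"
    p = float(stats.wilcoxon(pre, post).pvalue)
    modulated = p < alpha_cue
    if not modulated:
        return False, p, "none"
    return True, p, "increase" if diffs.mean() > 0 else "decrease"


def classify_cell_type(spike_times: np.ndarray, isi_threshold: float = 2.0) -> str:
    """FSI iff the unit has no interspike interval above ``isi_threshold``."""
    if len(spike_times) < 2:
        raise ValueError("cell-type classification needs at least 2 spikes")
    return "FSI" if np.max(np.diff(spike_times)) <= isi_threshold else "MSN"


def screen_units(spiketrains: SpikeTrainSet, trials: pd.DataFrame, *,
                 min_spikes: int = 200, alpha_drift: float = 0.05,
                 alpha_cue: float = 0.01) -> pd.DataFrame:
    """Run the full funnel; one row per unit (UnitScreenResult fields).

    The funnel is monotone: the cue-modulation test only runs on units that
    passed the spike floor and the drift exclusion.
    """
    rows = []
    for uid in spiketrains.unit_ids():
        spk = spiketrains[uid]
        row = {
            "unit_id": uid,
            "n_spikes": len(spk),
            "passed_min_spikes": len(spk) >= min_spikes,
            "drift_p_light": np.nan, "drift_p_sound": np.nan,
            "excluded_for_drift": False,
            "cue_modulation_p": np.nan, "cue_modulated": False,
            "direction": "none",
            "cell_class": classify_cell_type(spk) if len(spk) >= 2 else "MSN",
        }
        if row["passed_min_spikes"]:
            excluded, pvals = drift_exclusion(spk, trials, alpha_drift)
            row["drift_p_light"] = pvals.get("light", np.nan)
            row["drift_p_sound"] = pvals.get("sound", np.nan)
            row["excluded_for_drift"] = excluded
            if not excluded:
                mod, p, direction = cue_modulation_test(spk, trials, alpha_cue)
                row["cue_modulation_p"] = p
                row["cue_modulated"] = mod
                row["direction"] = direction
        rows.append(row)
    return pd.DataFrame(rows)
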