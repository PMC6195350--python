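"""Synthetic session generator for the cue-discrimination task.

A *session* consists of two behavioural blocks (a light block and a sound
block) of ``n_trials_per_block`` trials each.  On every trial the animal,
progressing clockwise around a four-arm track, receives a cue that signals
either reward availability ("available") or unavailability ("unavailable")
and then either approaches the reward receptacle (nosepoke) or skips to the
next trial.  Outcome sequences are pseudorandom with no more than two equal
outcomes in a row and near-equal available/unavailable counts on every arm.

Spike trains are inhomogeneous-Poisson with piecewise-constant rates keyed
to trial events.  Four epochs carry tuning: pre-cue ``[t_cue-1, t_cue)``,
post-cue ``[t_cue, t_cue+1)``, nosepoke-hold ``[t_nosepoke, t_outcome)`` and
post-outcome ``[t_outcome, t_outcome+1)``.  Within an epoch the rate is
``baseline x drift(trial) x prod(active effect factors)``; between epochs
only ``baseline x drift`` applies.  Ground-truth tuning is carried along so
downstream stages (screening, GLMs, decoding, overlap) have a known answer
to recover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

IDENTITIES = ("light", "sound")
OUTCOMES = ("available", "unavailable")
EPOCHS = ("pre_cue", "post_cue", "nosepoke_hold", "post_outcome")
FEATURES = ("cue_any", "identity", "location", "outcome")

TRIAL_COLUMNS = [
    "trial", "block", "identity", "outcome", "location", "behaviour",
    "t_cue_onset", "t_nosepoke", "t_outcome", "t_next_trial", "trial_length",
]


class ConfigurationError(ValueError):
    """Raised when a session configuration is internally inconsistent."""


@dataclass(frozen=True)
class DistributionSpec:
    """A positive-duration distribution: ``shift + lognormal(mu, sigma)``.

    ``kind`` may be ``"lognormal"`` or ``"constant"`` (then ``mu`` is the
    value and ``sigma`` is ignored).  ``shift`` guarantees a hard minimum.
    """

    kind: str = "lognormal"
    mu: float = 1.0          # log-scale median for lognormal, value for constant
    sigma: float = 0.35
    shift: float = 0.0

    def sample(self, rng: np.random.Generator, size: int | None = None):
        if self.kind == "constant":
            out = np.full(size if size is not None else 1, float(self.mu))
        elif self.kind == "lognormal":
            out = rng.lognormal(np.log(self.mu), self.sigma, size=size if size is not None else 1)
        else:
            raise ConfigurationError(f"unknown distribution kind {self.kind!r}")
        out = out + self.shift
        return out if size is not None else float(out[0])


def _default_approach_probabilities() -> dict:
    # Empirical approach percentages from well-trained animals on this task.
    return {
        ("light", "available"): 0.97,
        ("light", "unavailable"): 0.34,
        ("sound", "available"): 0.91,
        ("sound", "unavailable"): 0.35,
    }


@dataclass
class SessionConfig:
    """Parameters of one simulated session."""

    n_trials_per_block: int = 100
    block_order: tuple = ("light", "sound")
    n_arms: int = 4
    reward_delay: float = 1.0
    approach_probabilities: Mapping = field(default_factory=_default_approach_probabilities)
    nosepoke_latency: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("lognormal", mu=1.8, sigma=0.3, shift=0.5))
    inter_trial_interval: DistributionSpec = field(
        default_factory=lambda: DistributionSpec("lognormal", mu=3.0, sigma=0.4, shift=1.5))
    session_start: float = 10.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_trials_per_block < 4:
            raise ConfigurationError("n_trials_per_block must be >= 4")
        if sorted(self.block_order) != sorted(IDENTITIES):
            raise ConfigurationError("block_order must contain 'light' and 'sound' once each")
        if self.reward_delay <= 0:
            raise ConfigurationError("reward_delay must be > 0")
        for ident in IDENTITIES:
            for out in OUTCOMES:
                if (ident, out) not in self.approach_probabilities:
                    raise ConfigurationError(f"missing approach probability for {(ident, out)}")
                p = self.approach_probabilities[(ident, out)]
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"approach probability {p} not in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["approach_probabilities"] = {
            f"{k[0]}|{k[1]}": v for k, v in self.approach_probabilities.items()}
        d["block_order"] = list(self.block_order)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SessionConfig":
        d = dict(d)
        if "approach_probabilities" in d:
            ap = {}
            for k, v in d["approach_probabilities"].items():
                ident, out = k.split("|") if isinstance(k, str) else k
                ap[(ident, out)] = float(v)
            d["approach_probabilities"] = ap
        if "block_order" in d:
            d["block_order"] = tuple(d["block_order"])
        for key in ("nosepoke_latency", "inter_trial_interval"):
            if key in d and isinstance(d[key], Mapping):
                d[key] = DistributionSpec(**d[key])
        return cls(**d)


@dataclass
class TuningSpec:
    """Ground-truth tuning of one simulated unit.

    ``epoch_effects`` maps ``(epoch, feature)`` to a multiplicative rate
    factor applied when the trial matches the unit's ``preferred`` level of
    that feature (``cue_any`` applies on every trial).  ``drift_slope`` is
    the fractional rate change per trial within a block (multiplicative,
    linear in within-block trial index).
    """

    unit_id: int
    baseline_rate: float = 3.0
    cell_class: str = "MSN"          # "MSN" or "FSI"
    epoch_effects: dict = field(default_factory=dict)   # (epoch, feature) -> factor
    preferred: dict = field(default_factory=lambda: {
        "identity": "sound", "location": 3, "outcome": "available"})
    drift_slope: float = 0.0
    fsi_floor_rate: float = 8.0

    def __post_init__(self):
        if self.baseline_rate <= 0:
            raise ConfigurationError("baseline_rate must be > 0")
        for key, fac in self.epoch_effects.items():
            if tuple(key)[0] not in EPOCHS or tuple(key)[1] not in FEATURES:
                raise ConfigurationError(f"unknown epoch/feature key {key}")
            if fac <= 0:
                raise ConfigurationError("rate factors must be > 0")
        if self.cell_class not in ("MSN", "FSI"):
            raise ConfigurationError("cell_class must be MSN or FSI")

    @property
    def direction(self) -> str:
        """Sign of the planted cue response (post-cue cue_any factor)."""
        fac = self.epoch_effects.get(("post_cue", "cue_any"), 1.0)
        if fac > 1.0:
            return "increase"
        if fac < 1.0:
            return "decrease"
        return "none"

    def to_dict(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "baseline_rate": self.baseline_rate,
            "cell_class": self.cell_class,
            "epoch_effects": {f"{e}|{f}": v for (e, f), v in self.epoch_effects.items()},
            "preferred": dict(self.preferred),
            "drift_slope": self.drift_slope,
            "fsi_floor_rate": self.fsi_floor_rate,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TuningSpec":
        d = dict(d)
        d["epoch_effects"] = {tuple(k.split("|")): v for k, v in d.get("epoch_effects", {}).items()}
        return cls(**d)


@dataclass
class SpikeTrainSet:
    """Per-unit sorted spike timestamps on the session clock."""

    spikes: dict                                   # unit_id -> np.ndarray (sorted)
    session_bounds: tuple                          # (t0, t1)
    tuning: dict | None = None                     # unit_id -> TuningSpec (synthetic only)

    def unit_ids(self):
        return sorted(self.spikes)

    def __getitem__(self, unit_id):
        return self.spikes[unit_id]


# ---------------------------------------------------------------------------
# trial sequence
# ---------------------------------------------------------------------------

def _block_outcome_sequence(n: int, n_arms: int, rng: np.random.Generator,
                            max_attempts: int = 500) -> np.ndarray:
    """Outcome labels for one block: run length <= 2, per-arm near-balance.

    Sequential constrained sampling with per-arm quotas; dead ends are rare
    and handled by restarting the block.
    """
    arm_of = np.arange(n) % n_arms
    counts = np.bincount(arm_of, minlength=n_arms)
    for _ in range(max_attempts):
        quota_avail = counts // 2 + (rng.random(n_arms) < 0.5) * (counts % 2)
        rem = {"available": quota_avail.astype(float).copy(),
               "unavailable": (counts - quota_avail).astype(float).copy()}
        seq: list = []
        ok = True
        for i in range(n):
            a = arm_of[i]
            options = []
            for o in OUTCOMES:
                if rem[o][a] <= 0:
                    continue
                if len(seq) >= 2 and seq[-1] == seq[-2] == o:
                    continue
                options.append(o)
            if not options:
                ok = False
                break
            if len(options) == 1:
                choice = options[0]
            else:
                w = np.array([rem[o].sum() for o in options])
                choice = options[rng.choice(len(options), p=w / w.sum())]
            seq.append(choice)
            rem[choice][a] -= 1
        if ok:
            return np.array(seq)
    raise ConfigurationError("could not satisfy outcome-sequence constraints")


def generate_trial_sequence(config: SessionConfig,
                            rng: np.random.Generator) -> pd.DataFrame:
    """Generate trial labels (no behaviour or event times yet).

    Locations cycle deterministically 1 -> 2 -> ... -> n_arms -> 1 across the
    whole session; cue identity equals the block; outcomes are pseudorandom
    under the run-length and per-arm balance constraints.
    """
    config.validate()
    rows = []
    trial = 0
    for block in config.block_order:
        outcomes = _block_outcome_sequence(config.n_trials_per_block, config.n_arms, rng)
        for i in range(config.n_trials_per_block):
            rows.append({
                "trial": trial,
                "block": block,
                "identity": block,
                "outcome": outcomes[i],
                "location": (trial % config.n_arms) + 1,
            })
            trial += 1
    df = pd.DataFrame(rows)
    for col in ("behaviour",):
        df[col] = pd.NA
    for col in ("t_cue_onset", "t_nosepoke", "t_outcome", "t_next_trial", "trial_length"):
        df[col] = np.nan
    return df


def generate_behaviour(trials: pd.DataFrame, config: SessionConfig,
                       rng: np.random.Generator) -> pd.DataFrame:
    """Draw approach/skip behaviour and fill in all event timestamps.

    Approach trials: nosepoke after a sampled latency, outcome revealed
    ``reward_delay`` later, next trial after a 1 s post-outcome dwell plus an
    inter-trial interval.  Skip trials: the animal proceeds directly to the
    next trial after an inter-trial interval; trial length is then the time
    to the next cue onset.
    """
    config.validate()
    df = trials.copy()
    t = float(config.session_start)
    for idx in df.index:
        ident = df.at[idx, "identity"]
        out = df.at[idx, "outcome"]
        p = config.approach_probabilities[(ident, out)]
        approach = bool(rng.random() < p)
        df.at[idx, "behaviour"] = "approach" if approach else "skip"
        df.at[idx, "t_cue_onset"] = t
        if approach:
            t_np = t + config.nosepoke_latency.sample(rng)
            t_out = t_np + config.reward_delay
            t_next = t_out + 1.0 + config.inter_trial_interval.sample(rng)
            df.at[idx, "t_nosepoke"] = t_np
            df.at[idx, "t_outcome"] = t_out
            df.at[idx, "trial_length"] = t_np - t
        else:
            t_next = t + config.inter_trial_interval.sample(rng)
            df.at[idx, "trial_length"] = t_next - t
        df.at[idx, "t_next_trial"] = t_next
        t = t_next
    return df


# ---------------------------------------------------------------------------
# spike trains
# ---------------------------------------------------------------------------

def _effect_factor(spec: TuningSpec, epoch: str, row) -> float:
    fac = 1.0
    eff = spec.epoch_effects
    key = (epoch, "cue_any")
    if key in eff:
        fac *= eff[key]
    for feature, column in (("identity", "identity"), ("location", "location"),
                            ("outcome", "outcome")):
        key = (epoch, feature)
        if key in eff and row[column] == spec.preferred.get(feature):
            fac *= eff[key]
    return fac


def _unit_segments(spec: TuningSpec, trials: pd.DataFrame,
                   bounds: tuple) -> tuple:
    """Piecewise-constant (start, duration, rate) arrays for one unit.

    Epoch segments are laid down per trial; the remaining time runs at
    baseline x drift.  When the nosepoke occurs within 1 s of the cue the
    post-cue epoch is truncated at the nosepoke (hold tuning takes over).
    """
    n = len(trials)
    n_block = int((trials["block"] == trials["block"].iloc[0]).sum())
    starts, durs, rates = [], [], []
    t_prev_end = bounds[0]
    for _, row in trials.iterrows():
        i_in_block = int(row["trial"]) % n_block
        drift = max(1.0 + spec.drift_slope * i_in_block, 1e-12)
        base = spec.baseline_rate * drift
        tc = row["t_cue_onset"]
        # baseline gap up to the pre-cue epoch
        pre_start = tc - 1.0
        if pre_start > t_prev_end:
            starts.append(t_prev_end); durs.append(pre_start - t_prev_end); rates.append(base)
        seg_start = max(pre_start, t_prev_end)
        # pre-cue
        starts.append(seg_start); durs.append(tc - seg_start)
        rates.append(base * _effect_factor(spec, "pre_cue", row))
        if row["behaviour"] == "approach":
            t_np, t_out = row["t_nosepoke"], row["t_outcome"]
            post_end = min(tc + 1.0, t_np)
            starts.append(tc); durs.append(post_end - tc)
            rates.append(base * _effect_factor(spec, "post_cue", row))
            if t_np > post_end:
                starts.append(post_end); durs.append(t_np - post_end); rates.append(base)
            starts.append(t_np); durs.append(t_out - t_np)
            rates.append(base * _effect_factor(spec, "nosepoke_hold", row))
            starts.append(t_out); durs.append(1.0)
            rates.append(base * _effect_factor(spec, "post_outcome", row))
            t_prev_end = t_out + 1.0
        else:
            post_end = min(tc + 1.0, row["t_next_trial"])
            starts.append(tc); durs.append(post_end - tc)
            rates.append(base * _effect_factor(spec, "post_cue", row))
            t_prev_end = post_end
    if bounds[1] > t_prev_end:
        starts.append(t_prev_end); durs.append(bounds[1] - t_prev_end)
        rates.append(spec.baseline_rate)
    starts = np.asarray(starts); durs = np.asarray(durs); rates = np.asarray(rates)
    keep = durs > 0
    return starts[keep], durs[keep], rates[keep]


def generate_spike_trains(trials: pd.DataFrame, tuning: Sequence[TuningSpec],
                          rng: np.random.Generator) -> SpikeTrainSet:
    """Sample inhomogeneous-Poisson spike trains for every unit.

    FSI units run on ``max(rate, fsi_floor_rate)`` everywhere; any residual
    interspike interval > 2 s (vanishingly rare at the default floor) is
    closed by inserting a uniform spike, so the ISI-based class label is
    guaranteed by construction.
    """
    if trials["t_cue_onset"].isna().any():
        raise ValueError("trials must have event times; run generate_behaviour first")
    t0 = float(trials["t_cue_onset"].iloc[0]) - 2.0
    t1 = float(trials["t_next_trial"].iloc[-1]) + 2.0
    spikes = {}
    for spec in tuning:
        starts, durs, rates = _unit_segments(spec, trials, (t0, t1))
        if np.any(rates < 0):
            raise ConfigurationError("negative rate encountered")
        if spec.cell_class == "FSI":
            rates = np.maximum(rates, spec.fsi_floor_rate)
        counts = rng.poisson(rates * durs)
        rep_start = np.repeat(starts, counts)
        rep_dur = np.repeat(durs, counts)
        times = np.sort(rep_start + rng.random(rep_start.size) * rep_dur)
        if times.size:
            times = times[np.concatenate(([True], np.diff(times) > 0))]
        if spec.cell_class == "FSI":
            times = _close_long_gaps(times, (t0, t1), rng, max_isi=2.0)
        spikes[spec.unit_id] = times
    return SpikeTrainSet(spikes=spikes, session_bounds=(t0, t1),
                         tuning={s.unit_id: s for s in tuning})


def _close_long_gaps(times: np.ndarray, bounds: tuple, rng: np.random.Generator,
                     max_isi: float = 2.0) -> np.ndarray:
    """Insert spikes until no interspike interval exceeds ``max_isi``."""
    if times.size < 2:
        lo, hi = bounds
        extra = np.arange(lo + max_isi / 2, hi, max_isi / 2)
        return np.sort(np.concatenate([times, extra]))
    while True:
        gaps = np.diff(times)
        bad = np.where(gaps > max_isi)[0]
        if bad.size == 0:
            return times
        fillers = times[bad] + rng.random(bad.size) * gaps[bad]
        times = np.sort(np.concatenate([times, fillers]))


# ---------------------------------------------------------------------------
# populations and sessions
# ---------------------------------------------------------------------------

def make_tuning_population(n_units: int, rng: np.random.Generator, *,
                           fsi_fraction: float = 0.15,
                           baseline_msn: float = 3.0,
                           baseline_fsi: float = 10.0,
                           p_cue_responsive: float = 0.6,
                           p_decrease: float = 0.75,
                           identity_fraction: float = 0.3,
                           location_fraction: float = 0.3,
                           outcome_fraction: float = 0.25,
                           identity_factor: float = 1.5,
                           location_factor: float = 1.5,
                           outcome_factor: float = 1.5,
                           drift_fraction: float = 0.0,
                           drift_slope: float = 0.0) -> list:
    """A heterogeneous population echoing the recorded data's mix.

    Most cue-responsive units decrease firing after the cue; identity,
    location and outcome tuning are planted in random (independent) subsets
    at the post-cue, hold and post-outcome epochs.
    """
    specs = []
    for uid in range(n_units):
        is_fsi = rng.random() < fsi_fraction
        eff = {}
        if rng.random() < p_cue_responsive:
            fac = 0.5 if rng.random() < p_decrease else 2.0
            eff[("post_cue", "cue_any")] = fac
        for feature, frac, factor in (("identity", identity_fraction, identity_factor),
                                      ("location", location_fraction, location_factor),
                                      ("outcome", outcome_fraction, outcome_factor)):
            if rng.random() < frac:
                for epoch in ("post_cue", "nosepoke_hold", "post_outcome"):
                    eff[(epoch, feature)] = factor
        drift = drift_slope if rng.random() < drift_fraction else 0.0
        specs.append(TuningSpec(
            unit_id=uid,
            baseline_rate=baseline_fsi if is_fsi else baseline_msn,
            cell_class="FSI" if is_fsi else "MSN",
            epoch_effects=eff,
            preferred={"identity": rng.choice(IDENTITIES),
                       "location": int(rng.integers(1, 5)),
                       "outcome": rng.choice(OUTCOMES)},
            drift_slope=drift,
        ))
    return specs


def simulate_session(config: SessionConfig, tuning: Sequence[TuningSpec] | None = None,
                     rng: np.random.Generator | None = None):
    """Convenience wrapper: trial sequence -> behaviour -> spike trains.

    Returns ``(trials, spiketrains)``; ``spiketrains`` is ``None`` when no
    tuning specs are given (behaviour-only session).
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    trials = generate_trial_sequence(config, rng)
    trials = generate_behaviour(trials, config, rng)
    if tuning is None:
        return trials, None
    return trials, generate_spike_trains(trials, tuning, rng)


# ---------------------------------------------------------------------------
# session-bundle I/O
# ---------------------------------------------------------------------------

def write_bundle(out_dir, trials: pd.DataFrame, spiketrains: SpikeTrainSet | None,
                 config: SessionConfig) -> list:
    """Write ``trials.csv``, ``spikes.csv``, ``truth.json``, ``config.yaml``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    path = out / "trials.csv"
    trials.to_csv(path, index=False, float_format="%.6f")
    written.append(path)
    if spiketrains is not None:
        rows = [(uid, t) for uid in spiketrains.unit_ids() for t in spiketrains[uid]]
        spk = pd.DataFrame(rows, columns=["unit_id", "t_spike_s"])
        path = out / "spikes.csv"
        spk.to_csv(path, index=False, float_format="%.6f")
        written.append(path)
        if spiketrains.tuning is not None:
            path = out / "truth.json"
            path.write_text(json.dumps(
                {str(uid): s.to_dict() for uid, s in spiketrains.tuning.items()}, indent=1))
            written.append(path)
    path = out / "config.yaml"
    path.write_text(yaml.safe_dump(config.to_dict()))
    written.append(path)
    return written


def read_bundle(bundle_dir):
    """Read a session bundle back as ``(trials, spiketrains, config)``."""
    bundle = Path(bundle_dir)
    trials = pd.read_csv(bundle / "trials.csv")
    config = SessionConfig.from_dict(yaml.safe_load((bundle / "config.yaml").read_text()))
    spiketrains = None
    if (bundle / "spikes.csv").exists():
        spk = pd.read_csv(bundle / "spikes.csv")
        # CSV timestamps carry 1 us resolution; drop ties introduced by rounding
        spikes = {int(uid): np.unique(g["t_spike_s"].to_numpy())
                  for uid, g in spk.groupby("unit_id")}
        tuning = None
        if (bundle / "truth.json").exists():
            raw = json.loads((bundle / "truth.json").read_text())
            tuning = {int(uid): TuningSpec.from_dict(d) for uid, d in raw.items()}
        t0 = float(trials["t_cue_onset"].iloc[0]) - 2.0
        t1 = float(trials["t_next_trial"].iloc[-1]) + 2.0
        spiketrains = SpikeTrainSet(spikes=spikes, session_bounds=(t0, t1), tuning=tuning)
    return trials, spiketrains, config
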