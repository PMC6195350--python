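"""Pipeline orchestration: simulate -> screen -> glm -> decode -> overlap ->
population -> behaviour, driven by one YAML config with deterministic
seeding and a content-hashed manifest.

All randomness flows from a single root seed through named
``numpy.random.SeedSequence`` child streams (one per stage), so reruns with
the same config are bit-identical for every deterministic stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behaviour as beh
from . import decoding as dec
from . import overlap as ovl
from . import population as pop
from . import screening as scr
from . import synthetic as syn
from .glm import WindowGrid, run_sliding_glm, shuffle_proportion_test

log = logging.getLogger("cuecode")

STAGES = ["simulate", "screen", "glm", "decode", "overlap", "population", "behaviour"]

DEFAULTS = {
    "seed": 0,
    "stages": {s: True for s in STAGES},
    "session": {},                       # SessionConfig overrides
    "units": {"n_units": 20},            # make_tuning_population kwargs
    "screen": {"min_spikes": 200, "alpha_drift": 0.05, "alpha_cue": 0.01},
    "glm": {"event": "cue_onset", "n_shuffle": 20, "alpha_enter": 0.01,
            "approach_only": False},
    "decode": {"features": ["identity", "outcome"], "window": [0.0, 0.5],
               "iterations": 20, "n_shuffle": 20, "k": 10},
    "overlap": {"pairs": [["identity", "outcome"], ["identity", "location"],
                          ["location", "outcome"]], "n_shuffle": 100},
    "population": {"feature": "identity", "span": [-1.0, 2.0], "sigma": 0.1,
                   "dt": 0.05},
    "behaviour": {"n_rats": 2, "n_days": 4},
}


class PipelineError(RuntimeError):
    """A stage failed; partial outputs are retained with an incomplete marker."""


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see ``DEFAULTS`` for the schema)."""

    raw: dict = field(default_factory=dict)

    def __post_init__(self):
        merged = {}
        for key, val in DEFAULTS.items():
            if isinstance(val, dict):
                merged[key] = {**val, **self.raw.get(key, {})}
            else:
                merged[key] = self.raw.get(key, val)
        unknown = set(self.raw) - set(DEFAULTS)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        if not isinstance(merged["seed"], (int, np.integer)):
            raise PipelineError("seed must be an integer")
        for name, count_key in (("glm", "n_shuffle"), ("decode", "n_shuffle"),
                                ("overlap", "n_shuffle")):
            if merged[name][count_key] < 1:
                raise PipelineError(f"{name}.{count_key} must be >= 1")
        self.cfg = merged

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(yaml.safe_load(Path(path).read_text()) or {})

    def __getitem__(self, key):
        return self.cfg[key]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage_rngs(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(STAGES))
    return {name: np.random.default_rng(ss) for name, ss in zip(STAGES, children)}


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run the enabled stages in dependency order; return the manifest.

    The manifest maps each produced file to its SHA-256 hash and is written
    to ``manifest.json``.  A stage failure aborts the run but the manifest
    of files produced so far is retained with ``"incomplete": true``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rngs = _stage_rngs(int(config["seed"]))
    produced: list = []
    manifest = {"seed": int(config["seed"]), "incomplete": False, "files": {}}
    state: dict = {}
    try:
        for stage in STAGES:
            if not config["stages"].get(stage, True):
                log.info("stage=%s skipped", stage)
                continue
            runner = globals()[f"_stage_{stage}"]
            files = runner(config, out, rngs[stage], state)
            produced.extend(files)
            log.info("stage=%s files=%d", stage, len(files))
    except Exception as exc:
        manifest["incomplete"] = True
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_manifest(out, manifest, produced)
        raise PipelineError(f"stage failure: {exc}") from exc
    _write_manifest(out, manifest, produced)
    return manifest


def _write_manifest(out: Path, manifest: dict, produced: list) -> None:
    manifest["files"] = {str(p.relative_to(out)): _sha256(p) for p in produced}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))


# --- stages ----------------------------------------------------------------

def _stage_simulate(config, out, rng, state):
    sconf = syn.SessionConfig.from_dict(config["session"])
    tuning = syn.make_tuning_population(rng=rng, **config["units"])
    trials, spiketrains = syn.simulate_session(sconf, tuning, rng)
    state["trials"], state["spiketrains"], state["sconf"] = trials, spiketrains, sconf
    return syn.write_bundle(out / "session", trials, spiketrains, sconf)


def _require(state, key, stage):
    if key not in state:
        raise PipelineError(f"stage {stage!r} needs outputs of an earlier stage "
                            f"({key}); enable it or provide inputs")
    return state[key]


def _stage_screen(config, out, rng, state):
    trials = _require(state, "trials", "screen")
    spiketrains = _require(state, "spiketrains", "screen")
    screen = scr.screen_units(spiketrains, trials, **config["screen"])
    state["screen"] = screen
    state["modulated_units"] = {
        uid: spiketrains[uid]
        for uid in screen.loc[screen["cue_modulated"], "unit_id"]}
    path = out / "screen_results.csv"
    screen.to_csv(path, index=False)
    return [path]


def _stage_glm(config, out, rng, state):
    trials = _require(state, "trials", "glm")
    units = _require(state, "modulated_units", "glm")
    if not units:
        raise PipelineError("no cue-modulated units survived screening")
    cfg = config["glm"]
    grid = WindowGrid()
    sel = run_sliding_glm(units, trials, cfg["event"], grid,
                          alpha_enter=cfg["alpha_enter"],
                          approach_only=cfg["approach_only"])
    null = shuffle_proportion_test(units, trials, cfg["event"], grid,
                                   n_shuffle=cfg["n_shuffle"],
                                   alpha_enter=cfg["alpha_enter"],
                                   approach_only=cfg["approach_only"], rng=rng)
    state["selection"] = sel
    p1 = out / "selection_matrix.csv"
    sel.table.to_csv(p1, index=False)
    p2 = out / "proportion_null.csv"
    null.to_csv(p2, index=False)
    return [p1, p2]


def _stage_decode(config, out, rng, state):
    trials = _require(state, "trials", "decode")
    units = _require(state, "modulated_units", "decode")
    cfg = config["decode"]
    rows = []
    for feature in cfg["features"]:
        window = tuple(cfg["window"])
        data = dec.unit_feature_rates(units, trials, feature, window)
        res = dec.decode_with_null(data, rng, feature=feature, window=window,
                                   k=cfg["k"], iterations=cfg["iterations"],
                                   n_shuffle=cfg["n_shuffle"])
        rows.append({"feature": feature,
                     "window_center": float(np.mean(window)),
                     "mean_accuracy": res.mean_accuracy,
                     "shuffle_mean": float(res.shuffle_accuracies.mean()),
                     "shuffle_sd": float(res.shuffle_accuracies.std(ddof=1)),
                     "z": res.z, "significant": res.significant})
    path = out / "decoding_results.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [path]


def _stage_overlap(config, out, rng, state):
    sel = _require(state, "selection", "overlap")
    cfg = config["overlap"]
    rows, files = [], []
    for pa, pb in cfg["pairs"]:
        if pa not in sel.predictors or pb not in sel.predictors:
            log.warning("overlap pair (%s, %s) unavailable; skipped", pa, pb)
            continue
        res = ovl.classify_overlap(sel, pa, sel, pb, rng,
                                   n_shuffle=cfg["n_shuffle"])
        rows.append({"pair": f"{pa}@{sel.event}-vs-{pb}@{sel.event}",
                     "mean_r": res.mean_r, "shuffle_mean": res.shuffle_mean,
                     "shuffle_sd": res.shuffle_sd, "z": res.z, "label": res.label})
        mpath = out / f"overlap_matrix_{pa}_{pb}.csv"
        pd.DataFrame(res.matrix).to_csv(mpath, index=False)
        files.append(mpath)
    path = out / "overlap_results.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return files + [path]


def _stage_population(config, out, rng, state):
    trials = _require(state, "trials", "population")
    spiketrains = _require(state, "spiketrains", "population")
    cfg = config["population"]
    units = {uid: spiketrains[uid] for uid in spiketrains.unit_ids()}
    span, sigma, dt = tuple(cfg["span"]), cfg["sigma"], cfg["dt"]
    feature = cfg["feature"]
    levels = list(pd.unique(trials[feature]))[:2]
    mats = [pop.condition_peths(units, trials, trials[feature] == lev, str(lev),
                                span=span, sigma=sigma, dt=dt)
            for lev in levels]
    zmats = pop.zscore_rows(mats)
    files = []
    orders = {}
    for zm in zmats:
        sorted_m = pop.sort_heatmap(zm)
        orders[zm.condition] = sorted_m.sort_order
        path = out / f"peth_cue_onset_{zm.condition}.csv"
        df = pd.DataFrame(sorted_m.data, columns=np.round(sorted_m.times, 4))
        df.insert(0, "unit", sorted_m.unit_ids)
        df.to_csv(path, index=False)
        files.append(path)
    opath = out / "sort_orders.csv"
    pd.DataFrame(orders).to_csv(opath, index=False)
    files.append(opath)
    sh = pop.split_half_correlations(units, trials, feature, rng,
                                     span=span, sigma=sigma, dt=dt)
    spath = out / "split_half.csv"
    sh.to_csv(spath, index=False)
    files.append(spath)
    lme = pop.lme_block_comparison(sh)
    lpath = out / "lme_summary.json"
    lpath.write_text(json.dumps({
        "fixed_effects": lme.fixed_effects, "lrt_stat": lme.lrt_stat,
        "lrt_df": lme.lrt_df, "p_value": lme.p_value,
        "mean_within": lme.mean_within, "mean_across": lme.mean_across,
        "fallback_ols": lme.fallback_ols}, indent=1))
    files.append(lpath)
    return files


def _stage_behaviour(config, out, rng, state):
    sconf = state.get("sconf") or syn.SessionConfig.from_dict(config["session"])
    cfg = config["behaviour"]
    files = []
    if "trials" in state:
        summ = beh.behaviour_summary(state["trials"])
        path = out / "behaviour_summary.csv"
        summ.to_csv(path, index=False)
        files.append(path)
    # behaviour-only multi-day cohort for the learning criterion and the LME
    session_rows, flags = [], {"light": [], "sound": []}
    for r in range(cfg["n_rats"]):
        for d in range(cfg["n_days"]):
            trials, _ = syn.simulate_session(sconf, None, rng)
            session_rows.append(beh.session_proportions(trials, f"rat{r}", d))
            if r == 0:
                for block in ("light", "sound"):
                    _, _, flag = beh.discrimination_chi_square(
                        beh.block_table(trials, block))
                    flags[block].append(bool(flag))
    sessions = pd.concat(session_rows, ignore_index=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        lme = beh.approach_lme(sessions)
    day = beh.learning_criterion(flags) if cfg["n_days"] >= 3 else None
    path = out / "learning_criterion.json"
    path.write_text(json.dumps({"criterion_day": day, "daily_flags": flags}, indent=1))
    files.append(path)
    path = out / "behaviour_lme.json"
    path.write_text(json.dumps({
        "fixed_effects": lme.fixed_effects, "p_outcome": lme.p_outcome,
        "p_identity": lme.p_identity, "fallback_ols": lme.fallback_ols}, indent=1))
    files.append(path)
    return files


# --- bundle validation ------------------------------------------------------

def validate_session_bundle(bundle_dir) -> dict:
    """Check TrialTable and SpikeTrainSet invariants of a written bundle.

    Returns ``{"valid": bool, "violations": [messages with row references]}``.
    """
    trials, spiketrains, config = syn.read_bundle(bundle_dir)
    violations = []
    n_arms = config.n_arms
    loc = trials["location"].to_numpy()
    expected = (trials["trial"].to_numpy() % n_arms) + 1
    for i in np.where(loc != expected)[0]:
        violations.append(f"trial {trials['trial'].iloc[i]}: location {loc[i]} "
                          f"breaks the deterministic cycle (expected {expected[i]})")
    for block, sub in trials.groupby("block"):
        out = (sub["outcome"] == "available").to_numpy(int)
        run = 1
        for j in range(1, len(out)):
            run = run + 1 if out[j] == out[j - 1] else 1
            if run > 2:
                violations.append(f"trial {sub['trial'].iloc[j]}: outcome run "
                                  f"length > 2 in block {block}")
        for arm, asub in sub.groupby("location"):
            n_av = (asub["outcome"] == "available").sum()
            if abs(n_av - (len(asub) - n_av)) > 1:
                violations.append(f"block {block} arm {arm}: available/unavailable "
                                  f"counts differ by more than 1")
    app = trials["behaviour"] == "approach"
    bad = app & ~np.isclose(trials["t_outcome"],
                            trials["t_nosepoke"] + config.reward_delay)
    for i in np.where(bad.to_numpy())[0]:
        violations.append(f"trial {trials['trial'].iloc[i]}: t_outcome != "
                          f"t_nosepoke + reward_delay")
    tl = np.where(app, trials["t_nosepoke"] - trials["t_cue_onset"],
                  trials["t_next_trial"] - trials["t_cue_onset"])
    bad = ~np.isclose(trials["trial_length"].to_numpy(), tl, atol=1e-5)
    for i in np.where(bad)[0]:
        violations.append(f"trial {trials['trial'].iloc[i]}: trial_length inconsistent")
    if spiketrains is not None:
        for uid in spiketrains.unit_ids():
            spk = spiketrains[uid]
            if np.any(np.diff(spk) <= 0):
                violations.append(f"unit {uid}: spike times not strictly increasing")
            t0, t1 = spiketrains.session_bounds
            if len(spk) and (spk[0] < t0 - 1e-6 or spk[-1] > t1 + 1e-6):
                violations.append(f"unit {uid}: spikes outside session bounds")
    return {"valid": not violations, "violations": violations}
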