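"""Simulator contracts: trial structure, behaviour policy, spike statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cuecode as cc
from cuecode.synthetic import ConfigurationError, _block_outcome_sequence


def max_run_length(labels):
    best = run = 1
    for a, b in zip(labels, labels[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


class TestTrialSequence:
    def test_default_config_trial_counts(self):
        trials = cc.generate_trial_sequence(cc.SessionConfig(), np.random.default_rng(0))
        assert len(trials) == 200
        assert (trials.groupby("block").size() == 100).all()

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50)
    def test_sequence_constraints_hold_for_every_seed(self, seed):
        """Run length <= 2, cyclic locations, per-arm near-balance."""
        config = cc.SessionConfig(n_trials_per_block=20)
        trials = cc.generate_trial_sequence(config, np.random.default_rng(seed))
        assert (trials["location"] == trials["trial"] % 4 + 1).all()
        for _, block in trials.groupby("block"):
            assert max_run_length(list(block["outcome"])) <= 2
            for _, arm in block.groupby("location"):
                n_av = (arm["outcome"] == "available").sum()
                assert abs(2 * n_av - len(arm)) <= 1

    def test_identity_constant_within_block_and_order_respected(self):
        config = cc.SessionConfig(block_order=("sound", "light"))
        trials = cc.generate_trial_sequence(config, np.random.default_rng(3))
        assert (trials["identity"] == trials["block"]).all()
        assert trials["block"].iloc[0] == "sound" and trials["block"].iloc[-1] == "light"

    def test_per_arm_available_counts_near_split(self):
        """At 100 trials/block, each arm gets 25 trials and 12-13 available."""
        counts = set()
        for seed in range(300):
            seq = _block_outcome_sequence(100, 4, np.random.default_rng(seed))
            arm = np.arange(100) % 4
            for a in range(4):
                counts.add(int(np.sum(seq[arm == a] == "available")))
        assert counts <= {12, 13}

    def test_too_few_trials_rejected(self):
        with pytest.raises(ConfigurationError):
            cc.generate_trial_sequence(cc.SessionConfig(n_trials_per_block=2),
                                       np.random.default_rng(0))


class TestBehaviour:
    def _forced(self, p):
        probs = {(i, o): p for i in ("light", "sound")
                 for o in ("available", "unavailable")}
        config = cc.SessionConfig(n_trials_per_block=20, approach_probabilities=probs)
        rng = np.random.default_rng(5)
        return cc.generate_behaviour(cc.generate_trial_sequence(config, rng), config, rng)

    def test_all_approach_when_probability_one(self):
        trials = self._forced(1.0)
        assert (trials["behaviour"] == "approach").all()
        assert trials["t_nosepoke"].notna().all() and trials["t_outcome"].notna().all()
        assert np.allclose(trials["t_outcome"], trials["t_nosepoke"] + 1.0)
        assert np.allclose(trials["trial_length"],
                           trials["t_nosepoke"] - trials["t_cue_onset"])

    def test_no_approach_when_probability_zero(self):
        trials = self._forced(0.0)
        assert (trials["behaviour"] == "skip").all()
        assert trials["t_nosepoke"].isna().all()
        assert np.allclose(trials["trial_length"],
                           trials["t_next_trial"] - trials["t_cue_onset"])

    def test_approach_fractions_match_policy(self):
        """Empirical approach rates stay within 3 binomial SDs of the policy."""
        p_av, p_un = 0.95, 0.35
        probs = {(i, "available"): p_av for i in ("light", "sound")}
        probs.update({(i, "unavailable"): p_un for i in ("light", "sound")})
        config = cc.SessionConfig(n_trials_per_block=50, approach_probabilities=probs)
        rng = np.random.default_rng(7)
        n_sessions = 60
        hits = {"available": 0, "unavailable": 0}
        tot = {"available": 0, "unavailable": 0}
        for _ in range(n_sessions):
            trials, _ = cc.simulate_session(config, None, rng)
            for out, sub in trials.groupby("outcome"):
                hits[out] += (sub["behaviour"] == "approach").sum()
                tot[out] += len(sub)
        for out, p in (("available", p_av), ("unavailable", p_un)):
            se = np.sqrt(p * (1 - p) / tot[out])
            assert abs(hits[out] / tot[out] - p) < 3 * se

    def test_missing_probability_is_configuration_error(self):
        config = cc.SessionConfig(approach_probabilities={("light", "available"): 1.0})
        with pytest.raises(ConfigurationError):
            cc.generate_trial_sequence(config, np.random.default_rng(0))


class TestSpikeTrains:
    def test_poisson_mean_count_matches_rate(self):
        """Untuned 5 Hz unit: post-cue 1 s counts average 5 within 3 SE."""
        config = cc.SessionConfig(n_trials_per_block=100, rng_seed=9)
        rng = np.random.default_rng(9)
        specs = [cc.TuningSpec(unit_id=u, baseline_rate=5.0) for u in range(20)]
        trials, sts = cc.simulate_session(config, specs, rng)
        counts = np.concatenate([
            cc.windowed_counts(sts[u], trials["t_cue_onset"].to_numpy(), (0.0, 1.0))
            for u in range(20)])
        se = np.sqrt(5.0 / counts.size)
        assert abs(counts.mean() - 5.0) < 3 * se
        # dispersion: Poisson counts have variance/mean ~ 1
        assert 0.9 < counts.var() / counts.mean() < 1.1

    def test_identity_factor_scales_post_cue_rate(self):
        """Planted identity factor 1.5 appears as the post-cue rate ratio."""
        config = cc.SessionConfig(rng_seed=13)
        rng = np.random.default_rng(13)
        specs = [cc.TuningSpec(unit_id=u, baseline_rate=8.0,
                               epoch_effects={("post_cue", "identity"): 1.5},
                               preferred={"identity": "sound", "location": 1,
                                          "outcome": "available"})
                 for u in range(10)]
        trials, sts = cc.simulate_session(config, specs, rng)
        ev = {i: trials.loc[trials["identity"] == i, "t_cue_onset"].to_numpy()
              for i in ("light", "sound")}
        means = {i: np.mean([cc.windowed_rates(sts[u], ev[i], (0.0, 1.0)).mean()
                             for u in range(10)]) for i in ("light", "sound")}
        assert abs(means["sound"] / means["light"] - 1.5) < 0.1

    def test_near_silent_unit_fails_spike_floor(self):
        config = cc.SessionConfig(n_trials_per_block=10, rng_seed=1)
        rng = np.random.default_rng(1)
        trials, sts = cc.simulate_session(
            config, [cc.TuningSpec(unit_id=0, baseline_rate=0.001)], rng)
        assert len(sts[0]) < 200

    def test_fsi_has_no_long_isi_and_msn_does(self):
        config = cc.SessionConfig(rng_seed=17)
        rng = np.random.default_rng(17)
        specs = [cc.TuningSpec(unit_id=0, baseline_rate=10.0, cell_class="FSI"),
                 cc.TuningSpec(unit_id=1, baseline_rate=0.8, cell_class="MSN")]
        trials, sts = cc.simulate_session(config, specs, rng)
        assert np.max(np.diff(sts[0])) <= 2.0
        assert np.max(np.diff(sts[1])) > 2.0

    def test_timestamps_strictly_increasing(self, small_session):
        _, sts = small_session
        for uid in sts.unit_ids():
            assert np.all(np.diff(sts[uid]) > 0)

    def test_negative_rate_is_specification_error(self):
        with pytest.raises(ConfigurationError):
            cc.TuningSpec(unit_id=0, baseline_rate=5.0,
                          epoch_effects={("post_cue", "cue_any"): -1.0})


class TestBundleIO:
    def test_round_trip_preserves_tables(self, tmp_path, small_session, small_config):
        trials, sts = small_session
        cc.write_bundle(tmp_path / "b", trials, sts, small_config)
        trials2, sts2, config2 = cc.read_bundle(tmp_path / "b")
        assert config2.n_trials_per_block == small_config.n_trials_per_block
        pd.testing.assert_series_equal(trials["outcome"], trials2["outcome"])
        assert np.allclose(trials["t_cue_onset"], trials2["t_cue_onset"], atol=1e-5)
        for uid in sts.unit_ids():
            assert np.allclose(sts[uid], sts2[uid], atol=1e-5)
        assert sts2.tuning[0].baseline_rate == sts.tuning[0].baseline_rate
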