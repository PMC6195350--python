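"""Stepwise Poisson engine: design, IRLS fits, selection path, shuffle null."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

import cuecode as cc
from cuecode.glm import DesignInfo, WindowGrid, stepwise_batch


@pytest.fixture(scope="module")
def design(default_session):
    trials, _, _ = default_session
    return cc.build_design(trials, "cue_onset")


class TestDesign:
    def test_cue_onset_uses_every_trial(self, default_session, design):
        trials, _, _ = default_session
        assert design.X.shape[0] == len(trials) == 200

    def test_nosepoke_uses_approach_trials_only(self, default_session):
        trials, _, _ = default_session
        d = cc.build_design(trials, "nosepoke")
        assert d.X.shape[0] == (trials["behaviour"] == "approach").sum()
        # approach is constant there and must be dropped from candidates
        assert "approach" in d.dropped

    def test_history_missing_indicator_on_block_starts(self, default_session, design):
        trials, _, _ = default_session
        hist_cols = dict(design.blocks)["history"]
        missing = design.X[:, hist_cols[-1]]
        starts = np.flatnonzero(trials["block"].ne(trials["block"].shift()).to_numpy())
        expected = np.zeros(len(trials))
        expected[starts] = 1
        expected[starts + 1] = 1
        assert np.array_equal(missing, expected)

    def test_continuous_predictors_standardized(self, design):
        for name in ("trial_length", "trial_number"):
            col = design.X[:, dict(design.blocks)[name][0]]
            assert abs(col.mean()) < 1e-12 and abs(col.std() - 1) < 1e-12


class TestPoissonFit:
    def test_matches_statsmodels_glm(self, default_session, design):
        """The in-package IRLS solver agrees with an independent fitter."""
        trials, sts, _ = default_session
        y = cc.windowed_counts(sts[0], design.event_times, (0.0, 0.5)).astype(float)
        X = np.column_stack([np.ones(len(y)), design.X])
        beta, dev, ok = cc.fit_poisson(X, y)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert ok
        assert np.allclose(beta, ref.params, atol=1e-6)
        assert abs(dev - ref.deviance) < 1e-8


class TestStepwise:
    def test_constant_counts_give_intercept_only(self, design):
        fit = cc.forward_stepwise_poisson(np.full(design.X.shape[0], 4), design)
        assert fit.selected == ()

    def test_planted_binary_effect_selected(self):
        """A rate-ratio-2 identity effect is found; null predictors stay rare."""
        rng = np.random.default_rng(31)
        config = cc.SessionConfig(rng_seed=31)
        specs = [cc.TuningSpec(unit_id=u, baseline_rate=5.0,
                               epoch_effects={("post_cue", "identity"): 2.0})
                 for u in range(25)]
        trials, sts = cc.simulate_session(config, specs, rng)
        d = cc.build_design(trials, "cue_onset")
        hits, others = [], []
        for u in range(25):
            y = cc.windowed_counts(sts[u], d.event_times, (0.0, 0.5))
            fit = cc.forward_stepwise_poisson(y, d)
            hits.append("identity" in fit.selected)
            others.append(len([s for s in fit.selected if s != "identity"]))
        assert np.mean(hits) > 0.95
        assert np.mean(others) < 0.5

    def test_deviance_never_increases_along_path(self, default_session, design):
        trials, sts, _ = default_session
        for u in range(5):
            y = cc.windowed_counts(sts[u], design.event_times, (0.25, 0.75))
            fit = cc.forward_stepwise_poisson(y, design)
            assert fit.deviance <= fit.null_deviance + 1e-8

    def test_alignment_audit(self, default_session, design):
        """Permuting trials of counts and design together changes nothing."""
        trials, sts, _ = default_session
        rng = np.random.default_rng(2)
        y = cc.windowed_counts(sts[1], design.event_times, (0.0, 0.5))
        perm = rng.permutation(len(y))
        d2 = DesignInfo(X=design.X[perm], blocks=design.blocks,
                        event_times=design.event_times[perm],
                        trial_index=design.trial_index[perm])
        f1 = cc.forward_stepwise_poisson(y, design)
        f2 = cc.forward_stepwise_poisson(y[perm], d2)
        assert f1.selected == f2.selected
        assert abs(f1.deviance - f2.deviance) < 1e-6

    def test_reference_level_invariance(self, default_session):
        """Recoding the location dummies' reference arm leaves the path alone."""
        trials, sts, _ = default_session
        d1 = cc.build_design(trials, "cue_onset")
        d2 = cc.build_design(trials, "cue_onset")
        loc_cols = dict(d2.blocks)["location"]
        X2 = d2.X.copy()
        # re-reference: arms {1,3,4} vs arm 2
        sub = trials["location"].to_numpy()
        X2[:, loc_cols] = np.column_stack([(sub == a).astype(float) for a in (1, 3, 4)])
        d2 = DesignInfo(X=X2, blocks=d2.blocks, event_times=d2.event_times,
                        trial_index=d2.trial_index)
        y = cc.windowed_counts(sts[2], d1.event_times, (0.0, 0.5))
        f1 = cc.forward_stepwise_poisson(y, d1)
        f2 = cc.forward_stepwise_poisson(y, d2)
        assert f1.selected == f2.selected
        assert abs(f1.deviance - f2.deviance) < 1e-6

    def test_small_design_matches_exhaustive_oracle(self):
        """Forward path = exhaustive subset enumeration on orthogonal designs."""
        agree = 0
        n_designs = 15
        for seed in range(n_designs):
            X, blocks, y = _random_small_design(seed)
            fit = stepwise_batch(X, blocks, y[:, None].astype(float))[0]
            oracle = _exhaustive_admissible(X, blocks, y)
            assert len(oracle) == 1
            agree += set(fit.selected) == oracle[0]
        assert agree == n_designs


def _random_small_design(seed, n=200, alpha=0.01):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 2, size=(n, 3)).astype(float)
    blocks = [(f"x{j}", np.array([j])) for j in range(3)]
    beta = rng.choice([0.0, np.log(1.6)], size=3)
    y = rng.poisson(np.exp(np.log(3.0) + X @ beta))
    return X, blocks, y


def _exhaustive_admissible(X, blocks, y, alpha=0.01):
    """All subsets where every member is significant given the rest and no
    non-member significantly improves the subset (statsmodels fits)."""
    names = [b[0] for b in blocks]
    cols = dict(blocks)

    def dev(subset):
        M = np.column_stack([np.ones(len(y))] + [X[:, cols[s]] for s in subset])
        return sm.GLM(y, M, family=sm.families.Poisson()).fit().deviance

    def p_add(subset, j):
        drop = dev(subset) - dev(subset + [j])
        return stats.chi2.sf(max(drop, 0.0), df=len(cols[j]))

    admissible = []
    for r in range(len(names) + 1):
        for S in itertools.combinations(names, r):
            S = list(S)
            if all(p_add([s for s in S if s != j], j) < alpha for j in S) and \
               all(p_add(S, j) >= alpha for j in names if j not in S):
                admissible.append(set(S))
    return admissible


class TestPartialR2:
    def test_sole_strong_predictor_claims_full_r2(self):
        rng = np.random.default_rng(41)
        n = 400
        x = rng.integers(0, 2, n).astype(float)
        y = rng.poisson(np.exp(1.0 + 1.2 * x))
        blocks = [("x", np.array([0]))]
        fit = stepwise_batch(x[:, None], blocks, y[:, None].astype(float))[0]
        assert fit.selected == ("x",)
        assert abs(cc.partial_r2(fit, "x") - fit.pseudo_r2) < 1e-12

    def test_unselected_predictor_rejected(self, design):
        fit = cc.forward_stepwise_poisson(np.full(design.X.shape[0], 2), design)
        with pytest.raises(ValueError):
            cc.partial_r2(fit, "identity")

    def test_partial_r2_grows_with_effect_size(self):
        """Mean identity partial R2 increases over rate ratios 1.1/1.5/2.0."""
        means = []
        for i, ratio in enumerate((1.1, 1.5, 2.0)):
            rng = np.random.default_rng(43 + i)
            config = cc.SessionConfig(rng_seed=43 + i)
            specs = [cc.TuningSpec(unit_id=u, baseline_rate=5.0,
                                   epoch_effects={("post_cue", "identity"): ratio})
                     for u in range(15)]
            trials, sts = cc.simulate_session(config, specs, rng)
            d = cc.build_design(trials, "cue_onset")
            vals = []
            for u in range(15):
                y = cc.windowed_counts(sts[u], d.event_times, (0.0, 0.5))
                fit = cc.forward_stepwise_poisson(y, d)
                vals.append(fit.partial_r2.get("identity", 0.0))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]


class TestSlidingSweep:
    def test_eleven_windows_per_unit(self, default_session):
        trials, sts, _ = default_session
        sel = cc.run_sliding_glm({0: sts[0]}, trials)
        assert sel.table["window_center"].nunique() == 11
        assert len(sel.grid.post_event_centers()) == 6

    def test_post_cue_effect_confined_to_post_windows(self):
        """An outcome effect planted post-cue is not selected pre-cue."""
        rng = np.random.default_rng(47)
        config = cc.SessionConfig(rng_seed=47)
        specs = [cc.TuningSpec(unit_id=u, baseline_rate=6.0,
                               epoch_effects={("post_cue", "outcome"): 2.0})
                 for u in range(15)]
        trials, sts = cc.simulate_session(config, specs, rng)
        sel = cc.run_sliding_glm({u: sts[u] for u in range(15)}, trials)
        tab = sel.table[sel.table["predictor"] == "outcome"]
        pre = tab[tab["window_center"] <= -0.26]
        post = tab[tab["window_center"] >= 0.24]
        assert pre.empty or pre["selected"].mean() < 0.15
        assert post["selected"].mean() > 0.6


class TestShuffleNull:
    def test_zero_sd_sentinel_and_zero_difference(self):
        """obs == shuffle mean -> z = 0; sd == 0 with a difference -> inf."""
        rng = np.random.default_rng(51)
        config = cc.SessionConfig(n_trials_per_block=30, rng_seed=51)
        specs = [cc.TuningSpec(unit_id=u, baseline_rate=4.0) for u in range(3)]
        trials, sts = cc.simulate_session(config, specs, rng)
        null = cc.shuffle_proportion_test({u: sts[u] for u in range(3)}, trials,
                                          n_shuffle=3, rng=rng)
        zero_sd = null[null["shuffle_sd"] == 0]
        same = zero_sd[zero_sd["observed"] == zero_sd["shuffle_mean"]]
        assert (same["z"] == 0).all() and (~same["sd_zero"]).all()
        diff = zero_sd[zero_sd["observed"] != zero_sd["shuffle_mean"]]
        assert np.isinf(diff["z"]).all() and diff["sd_zero"].all()

    def test_strong_population_signal_flagged(self):
        """Half the units with a 2x identity effect drive z > 1.96 post-cue."""
        rng = np.random.default_rng(53)
        config = cc.SessionConfig(rng_seed=53)
        specs = [cc.TuningSpec(unit_id=u, baseline_rate=5.0,
                               epoch_effects=({("post_cue", "identity"): 2.0}
                                              if u < 10 else {}))
                 for u in range(20)]
        trials, sts = cc.simulate_session(config, specs, rng)
        null = cc.shuffle_proportion_test({u: sts[u] for u in range(20)}, trials,
                                          n_shuffle=20, rng=rng)
        post = null[(null["predictor"] == "identity")
                    & (null["window_center"] >= 0.24)]
        assert (post["z"] > 1.96).all()
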