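"""PSTH estimation, kinematic matching, and reward-modulation testing."""
import dataclasses

import numpy as np
import pandas as pd
import pytest

from rewardglm.psth import (Psth, compute_psth, match_kinematics,
                            modulation_test_from_rates,
                            population_normalized_psth,
                            reward_modulation_test)
from rewardglm.session import (KINEMATICS_COLUMNS, Session, TaskConfig, Trial)
from rewardglm.simulate import (SimulationConfig, default_neuron_specs,
                                simulate_session)
from rewardglm.util import wrap_angle


def _poisson_session(rate_hz, n_trials, seed=0, rate_hz_unrewarded=None):
    """Hand-built session with homogeneous Poisson spiking per condition."""
    rng = np.random.default_rng(seed)
    trials, spike_rows, kin_rows = [], [], []
    for tid in range(n_trials):
        rewarded = tid % 2 == 0
        reward_onset = 2.0
        span = 3.7
        trials.append(Trial(
            trial_id=tid, true_target=0.5, cue_angles=np.full(5, 0.5),
            cue_condition="narrow", dispersion=0.0, go_cue_time=1.0,
            movement_onset_time=1.2, reward_onset_time=reward_onset,
            reach_endpoint=0.5, error_magnitude=0.0, success=rewarded,
            rewarded=rewarded, withheld=False, previous_outcome=1,
            return_direction=float(wrap_angle(0.5 + np.pi))))
        hz = rate_hz if (rewarded or rate_hz_unrewarded is None) \
            else rate_hz_unrewarded
        n = rng.poisson(hz * span)
        spike_rows.append(pd.DataFrame({
            "neuron_id": 0, "trial_id": tid,
            "spike_time": np.sort(rng.random(n) * span)}))
        t = np.arange(0.0, span, 0.01)
        kin_rows.append(pd.DataFrame({
            "trial_id": tid, "time": t, "x": 0.0, "y": 0.0,
            "vx": np.where((t > 1.2) & (t < 1.6), 20.0, 0.0), "vy": 0.0,
            "ax": 0.0, "ay": 0.0}))
    return Session(config=TaskConfig(), trials=trials,
                   spikes=pd.concat(spike_rows, ignore_index=True),
                   kinematics=pd.concat(kin_rows, ignore_index=True),
                   neuron_ids=[0], region_labels={0: "PMd"})


class TestComputePsth:
    def test_homogeneous_poisson_rate_recovered(self):
        s = _poisson_session(20.0, 200, seed=4)
        p = compute_psth(s, 0, [t.trial_id for t in s.trials])
        assert len(p.bin_centers) == 80          # 2 s / 25 ms
        ok = np.abs(p.rate - 20.0) <= 3 * np.maximum(p.sem, 1e-9)
        assert ok.mean() > 0.95

    def test_single_spike_arithmetic(self):
        s = _poisson_session(20.0, 2, seed=0)
        s.spikes = pd.DataFrame({"neuron_id": [0], "trial_id": [0],
                                 "spike_time": [2.31]})  # 0.31 s after reward
        p = compute_psth(s, 0, [0, 1])
        b = np.argmin(np.abs(p.bin_centers - 0.3125))
        assert np.isclose(p.rate[b], 20.0)       # 1 spike / 0.025 / 2 trials
        assert np.isclose(p.rate.sum(), 20.0)

    def test_rebinning_conserves_spike_mass(self):
        s = _poisson_session(25.0, 50, seed=7)
        ids = [t.trial_id for t in s.trials]
        p1 = compute_psth(s, 0, ids, bin_width=0.025)
        p2 = compute_psth(s, 0, ids, bin_width=0.050)
        assert len(p2.bin_centers) == len(p1.bin_centers) // 2
        assert np.isclose(p1.rate.sum() * 0.025, p2.rate.sum() * 0.050)

    def test_requires_two_trials(self):
        s = _poisson_session(20.0, 3)
        with pytest.raises(ValueError):
            compute_psth(s, 0, [0])


class TestMatching:
    def test_identical_kinematics_match_perfectly(self):
        s = _poisson_session(20.0, 40)
        rew = [t.trial_id for t in s.trials if t.rewarded]
        unrew = [t.trial_id for t in s.trials if not t.rewarded]
        rep = match_kinematics(s, rew, unrew)
        assert len(rep.pairs) == 20
        assert rep.mean_speed_diff == 0.0
        assert rep.p_balance > 0.9

    def test_disjoint_speed_ranges_detected_and_discarded(self):
        s = _poisson_session(20.0, 40)
        # per-trial speed scales, disjoint between conditions (unrewarded 2x+)
        rng = np.random.default_rng(8)
        kin = s.kinematics.copy()
        unrew = {t.trial_id for t in s.trials if not t.rewarded}
        for tid in kin.trial_id.unique():
            scale = rng.uniform(2.0, 3.0) if tid in unrew \
                else rng.uniform(0.8, 1.2)
            kin.loc[kin.trial_id == tid, "vx"] *= scale
        s = dataclasses.replace(s, kinematics=kin)
        rew_ids = [t.trial_id for t in s.trials if t.rewarded]
        unrew_ids = sorted(unrew)
        rep = match_kinematics(s, rew_ids, unrew_ids)
        assert rep.p_balance_pre < 1e-6
        assert rep.discarded_rewarded > 0

    def test_matching_symmetric_under_label_swap(self):
        s = simulate_session(SimulationConfig(n_trials=80, seed=31))
        rew = s.trial_ids(rewarded=True)
        unrew = s.trial_ids(rewarded=False)
        a = match_kinematics(s, rew, unrew)
        b = match_kinematics(s, unrew, rew)
        assert set(a.pairs) == {(r, u) for u, r in b.pairs}


class TestModulation:
    def test_known_effect_direction_and_swap_symmetry(self):
        rng = np.random.default_rng(0)
        rew = rng.normal(20, 3, size=100)
        unrew = rng.normal(30, 3, size=100)
        res = modulation_test_from_rates(rew, unrew, n_neurons_for_correction=200)
        assert res.direction == "up_unrewarded"
        assert res.p < 0.05 / 200
        swapped = modulation_test_from_rates(unrew, rew, 200)
        assert swapped.direction == "up_rewarded"
        assert np.isclose(swapped.p, res.p)

    def test_null_rates_not_significant_on_average(self):
        rng = np.random.default_rng(5)
        n_sig = 0
        for _ in range(200):
            a = rng.poisson(30, size=50) / 1.5
            b = rng.poisson(30, size=50) / 1.5
            res = modulation_test_from_rates(a, b, n_neurons_for_correction=100)
            n_sig += res.significant
        assert n_sig / 200 <= 0.02  # Bonferroni leaves almost nothing

    def test_zero_variance_degenerates_to_none_with_warning(self):
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            res = modulation_test_from_rates(np.full(10, 5.0), np.full(10, 5.0), 1)
        assert res.direction == "none" and np.isnan(res.p)

    def test_session_level_test_on_simulated_effect_neuron(self):
        s = _poisson_session(20.0, 120, seed=9, rate_hz_unrewarded=30.0)
        rew = [t.trial_id for t in s.trials if t.rewarded]
        unrew = [t.trial_id for t in s.trials if not t.rewarded]
        rep = match_kinematics(s, rew, unrew)
        res = reward_modulation_test(s, 0, rep, n_neurons_for_correction=200)
        assert res.direction == "up_unrewarded"
        assert res.mean_rate_unrewarded > res.mean_rate_rewarded


class TestPopulation:
    def _pair(self, scale, n_bins=80):
        t = np.linspace(-0.4875, 1.4875, n_bins)
        base = np.exp(-((t - 0.5) / 0.3) ** 2)
        mk = lambda r, cond: Psth(bin_centers=t, rate=r,
                                  sem=np.zeros(n_bins), n_trials=10,
                                  condition=cond)
        return {"rewarded": mk(10 * base, "rewarded"),
                "unrewarded": mk(scale * base, "unrewarded")}

    def test_single_neuron_joint_peak_is_one(self):
        pop = population_normalized_psth({0: self._pair(25.0)})
        assert np.isclose(pop.mean["unrewarded"].max(), 1.0)
        assert pop.mean["rewarded"].max() < 1.0  # joint, not per-condition, peak
        assert np.allclose(pop.sem["rewarded"], 0.0)

    def test_identical_neurons_have_zero_sem(self):
        pop = population_normalized_psth({i: self._pair(25.0) for i in range(5)})
        assert np.allclose(pop.sem["unrewarded"], 0.0)
        assert pop.n_neurons == 5

    def test_all_zero_neuron_excluded_with_warning(self):
        pair0 = self._pair(0.0)
        pair0["rewarded"].rate = np.zeros(80)
        with pytest.warns(RuntimeWarning, match="all-zero"):
            pop = population_normalized_psth({0: pair0, 1: self._pair(25.0)})
        assert pop.n_neurons == 1

    def test_simulated_population_shows_unrewarded_dominance(self):
        cfg = SimulationConfig(n_trials=150,
                               neuron_specs=default_neuron_specs(6), seed=41)
        s = simulate_session(cfg)
        rew = s.trial_ids(rewarded=True)
        unrew = s.trial_ids(rewarded=False)
        pairs = {n: {"rewarded": compute_psth(s, n, rew, condition="rewarded"),
                     "unrewarded": compute_psth(s, n, unrew,
                                                condition="unrewarded")}
                 for n in s.neuron_ids}
        pop = population_normalized_psth(pairs)
        # window covering the generative reward kernel's support
        post = (pop.bin_centers > 0.1) & (pop.bin_centers < 0.9)
        frac = np.mean(pop.mean["unrewarded"][post] > pop.mean["rewarded"][post])
        assert frac > 0.8
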