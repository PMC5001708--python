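"""Simulator: task sampling, reach kinematics, outcome logic, spike generation."""
import numpy as np
import pytest
from scipy.special import iv

from rewardglm.design import build_design_matrix
from rewardglm.session import GroundTruthWeights, TaskConfig
from rewardglm.simulate import (SimulationConfig, benchmark_weights,
                                default_neuron_specs, generate_spikes,
                                null_weights, sample_target_and_cue,
                                simulate_session, weight_vector_for)
from rewardglm.util import circ_dist, circular_mean, resultant_length


class TestTargetAndCue:
    def test_degenerate_kappa_pins_cues_to_target(self, rng):
        task = TaskConfig(cue_kappas=(1e6, 5.0))
        tgt, cues, disp = sample_target_and_cue(task, "narrow", rng)
        assert np.all(circ_dist(cues, tgt) < 0.02)
        assert disp < 0.04

    def test_cue_moments_match_von_mises_kappa_50(self, rng):
        # draw many cues around a fixed target and check the circular moment
        task = TaskConfig(cue_kappas=(50.0, 5.0), n_cue_segments=5)
        all_cues, tgts = [], []
        for _ in range(2000):
            tgt, cues, _ = sample_target_and_cue(task, "narrow", rng)
            all_cues.append(cues - tgt)
        d = np.concatenate(all_cues)          # 10^4 deviations from the target
        se = 1.0 / np.sqrt(len(d) * 50.0)
        assert abs(circular_mean(d)) < 3 * se
        r_expected = iv(1, 50.0) / iv(0, 50.0)  # E[R] for von Mises kappa=50
        assert abs(resultant_length(d) - r_expected) < 0.01

    def test_mean_dispersion_decreases_with_kappa(self, rng):
        task = TaskConfig(cue_kappas=(50.0, 5.0))
        d_narrow = [sample_target_and_cue(task, "narrow", rng)[2]
                    for _ in range(1000)]
        d_broad = [sample_target_and_cue(task, "broad", rng)[2]
                   for _ in range(1000)]
        assert np.mean(d_broad) > np.mean(d_narrow)


class TestReachKinematics:
    def _session(self, **kw):
        kw.setdefault("n_trials", 5)
        kw.setdefault("seed", 2)
        return simulate_session(SimulationConfig(**kw))

    def test_zero_motor_noise_hits_the_aim(self):
        s = self._session(motor_noise_sd=0.0,
                          task=TaskConfig(cue_kappas=(1e6, 5.0)),
                          p_broad_cue=0.0)
        for t in s.trials:
            aim = circular_mean(t.cue_angles)
            assert np.isclose(t.reach_endpoint, aim, atol=1e-12)
            assert t.success and t.rewarded

    def test_velocity_equals_finite_difference_of_position(self):
        s = self._session()
        for tid in (0, 1):
            g = s.kinematics[s.kinematics.trial_id == tid]
            t = g["time"].to_numpy()
            dt = t[1] - t[0]
            for pos, vel in (("x", "vx"), ("y", "vy")):
                fd = np.gradient(g[pos].to_numpy(), dt)
                # O(dt^2) agreement away from segment boundaries
                err = np.abs(fd - g[vel].to_numpy())
                assert np.median(err) < 0.05
                assert np.percentile(err, 90) < 1.0  # cm/s, peak speed ~30

    def test_speed_profile_is_bell_shaped(self):
        s = self._session(motor_noise_sd=0.0)
        t0 = s.trials[0]
        g = s.kinematics[s.kinematics.trial_id == 0]
        m = (g["time"] >= t0.movement_onset_time) & \
            (g["time"] <= t0.reward_onset_time - 0.15)
        speed = np.hypot(g["vx"], g["vy"])[m].to_numpy()
        speed = speed[speed > 1e-9]
        peak = np.argmax(speed)
        assert 0 < peak < len(speed) - 1
        assert np.all(np.diff(speed[:peak + 1]) > -1e-9)
        assert np.all(np.diff(speed[peak:]) < 1e-9)


class TestSessionLogic:
    def test_perfect_conditions_give_certain_success_and_withheld_fraction(self):
        cfg = SimulationConfig(n_trials=500, motor_noise_sd=0.0,
                               task=TaskConfig(cue_kappas=(1e6, 5.0)),
                               p_broad_cue=0.0, withheld_reward_fraction=0.2,
                               seed=5)
        s = simulate_session(cfg)
        assert all(t.success for t in s.trials)
        frac = np.mean([t.rewarded for t in s.trials])
        # binomial 3-sigma band around 0.8 at n=500
        assert abs(frac - 0.8) < 3 * np.sqrt(0.8 * 0.2 / 500)
        assert all(not t.rewarded for t in s.trials if t.withheld)

    def test_success_rate_increases_with_cue_concentration(self):
        rates = {}
        for kappa in (1.0, 100.0):
            cfg = SimulationConfig(
                n_trials=1000, seed=9, p_broad_cue=0.0,
                task=TaskConfig(cue_kappas=(kappa, 0.5)))
            s = simulate_session(cfg)
            rates[kappa] = np.mean([t.success for t in s.trials])
        assert rates[100.0] > rates[1.0]

    def test_previous_outcome_chains_success(self):
        s = simulate_session(SimulationConfig(n_trials=50, seed=3))
        assert s.trials[0].previous_outcome == 1
        for prev, cur in zip(s.trials[:-1], s.trials[1:]):
            assert cur.previous_outcome == (1 if prev.success else -1)

    def test_latency_offsets_read_back(self):
        cfg = SimulationConfig(n_trials=600, seed=13)
        s = simulate_session(cfg)
        lat = {c: np.array([t.movement_onset_time - t.go_cue_time
                            for t in s.trials if t.cue_condition == c])
               for c in ("narrow", "broad")}
        diff = lat["broad"].mean() - lat["narrow"].mean()
        se = np.sqrt(lat["broad"].var() / len(lat["broad"])
                     + lat["narrow"].var() / len(lat["narrow"]))
        assert abs(diff - (cfg.rt_offset_broad_s - cfg.rt_offset_narrow_s)) < 2 * se

    def test_determinism_bit_identical(self):
        def run():
            return simulate_session(SimulationConfig(
                n_trials=30, neuron_specs=default_neuron_specs(2), seed=77))
        a, b = run(), run()
        assert a.trials_df().equals(b.trials_df())
        assert a.spikes.equals(b.spikes)
        assert a.kinematics.equals(b.kinematics)


class TestGenerateSpikes:
    def test_baseline_rate_oracle(self, small_session, rng):
        dm = build_design_matrix(small_session, neuron_ids=[])
        counts = generate_spikes(dm.X, dm.column_names,
                                 null_weights(baseline_hz=20.0), rng)
        assert len(counts) == small_session.n_trials * 200
        mean = counts.mean()
        se = np.sqrt(0.2 / len(counts))
        assert abs(mean - 0.2) < 3 * se  # 20 spikes/s in 10-ms bins

    def test_epoch_has_exactly_200_bins_per_trial(self, small_session):
        dm = build_design_matrix(small_session, neuron_ids=[])
        assert dm.n_bins_per_trial == 200
        assert dm.n_rows == small_session.n_trials * 200

    def test_negative_reward_kernel_elevates_unrewarded_rate(self, small_session, rng):
        # sign bookkeeping through the shared design path: a negative kernel
        # applied to the -1 unrewarded impulse must raise the post-onset rate
        dm = build_design_matrix(small_session, neuron_ids=[])
        w = GroundTruthWeights(baseline_log_rate=np.log(0.2),
                               kernels={"reward": np.array([0.0, -0.3, -0.8, -0.4])})
        counts = generate_spikes(dm.X, dm.column_names, w, rng)
        n_bins, post = 200, dm.bin_times > 0.1
        per_trial = counts.reshape(-1, n_bins)[:, post].mean(axis=1)
        rew = np.array([t.rewarded for t in small_session.trials])
        assert per_trial[~rew].mean() > per_trial[rew].mean()

    def test_overflowing_weights_are_rejected(self, small_session, rng):
        dm = build_design_matrix(small_session, neuron_ids=[])
        w = GroundTruthWeights(baseline_log_rate=np.log(0.2),
                               kernels={"vx": np.array([10.0, 0, 0, 0])})
        with pytest.raises(ValueError, match="rescale"):
            generate_spikes(dm.X, dm.column_names, w, rng)

    def test_weight_vector_alignment(self, small_session):
        dm = build_design_matrix(small_session, neuron_ids=[])
        w = benchmark_weights(0)
        vec = weight_vector_for(w, dm.column_names)
        j = dm.column_names.index("reward:b2") - 1
        assert vec[j] == w.kernels["reward"][2]
        j = dm.column_names.index("uncertainty:b0") - 1
        assert vec[j] == 0.0
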