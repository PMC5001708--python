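"""Synthetic sessions of the uncertain-target center-out task.

Each trial draws a true target from a von Mises prior centered at 90 deg and
a five-segment cue from a von Mises likelihood centered on the target, with
narrow/broad concentration conditions.  The simulated animal aims at the
circular mean of the cue segments (the maximum-likelihood readout of the cue),
reaches 7 cm along a minimum-jerk trajectory with von Mises angular motor
noise, and succeeds when the endpoint falls within the 15-deg target window.
Reward follows success except on optional withheld-reward trials.  Spike
trains are generated from a known Poisson encoding model over the same design
matrix the analysis uses, so parameter recovery is a genuine inverse problem.

Event times (per-trial clock): cue onset at 0.5 s, go cue after a uniform
0.8-1.0 s delay, movement onset after a condition-specific reaction-time
offset plus jitter, reward onset 0.2 s after the reach ends, and a return
reach to the center 0.5 s after reward onset.  More uncertain (broad) cues
produce later movement onsets, mirroring the slowed reactions observed under
cue uncertainty.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .design import (ALL_COVARIATES, COVARIATE_CHANNELS, build_design_matrix,
                     raised_cosine_basis)
from .session import (GroundTruthWeights, Session, TaskConfig, Trial,
                      KINEMATICS_COLUMNS, SPIKE_COLUMNS)
from .util import circ_dist, circular_mean, wrap_angle


@dataclass
class NeuronSpec:
    neuron_id: int
    region: str  # 'PMd' | 'M1'
    weights: GroundTruthWeights


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic session."""

    task: TaskConfig = field(default_factory=TaskConfig)
    n_trials: int = 400
    p_broad_cue: float = 0.5
    withheld_reward_fraction: float = 0.0
    motor_noise_sd: float = 0.06          # radians at the target ring
    kinematics_rate_hz: float = 100.0
    rt_offset_narrow_s: float = 0.035
    rt_offset_broad_s: float = 0.111
    rt_jitter_sd_s: float = 0.012
    reach_duration_s: float = 0.4
    reach_duration_jitter_s: float = 0.06   # half-range of uniform duration jitter
    cue_onset_s: float = 0.5
    reward_delay_s: float = 0.2           # reach end -> outcome cue
    return_delay_s: float = 0.5           # reward onset -> return reach start
    iti_range_s: tuple = (2.54, 3.04)     # recorded in metadata only
    neuron_specs: list = field(default_factory=list)
    seed: int = 0

    def validate(self):
        for name in ("p_broad_cue", "withheld_reward_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.rt_offset_broad_s < self.rt_offset_narrow_s:
            raise ValueError("rt_offset_broad_s must be >= rt_offset_narrow_s")
        if self.motor_noise_sd < 0:
            raise ValueError("motor_noise_sd must be nonnegative")
        if self.n_trials < 1 or self.kinematics_rate_hz <= 0:
            raise ValueError("n_trials and kinematics_rate_hz must be positive")
        self.task.validate()


def sample_target_and_cue(task: TaskConfig, condition: str, rng):
    """Draw (true_target, cue_angles, dispersion) for one trial.

    The target follows von Mises(prior_center, prior kappa); the cue segments
    are i.i.d. von Mises(target, cue kappa), with the (narrow, broad) kappa
    pair indexed by ``condition``.
    """
    from .util import circular_dispersion
    idx = {"narrow": 0, "broad": 1}[condition]
    target = float(wrap_angle(rng.vonmises(task.prior_center, task.prior_kappas[idx])))
    cues = wrap_angle(rng.vonmises(target, task.cue_kappas[idx],
                                   size=task.n_cue_segments))
    return target, cues, circular_dispersion(cues)


def _min_jerk(tau):
    """Normalized minimum-jerk position profile and its two derivatives."""
    s = 10 * tau ** 3 - 15 * tau ** 4 + 6 * tau ** 5
    v = 30 * tau ** 2 - 60 * tau ** 3 + 30 * tau ** 4
    a = 60 * tau - 180 * tau ** 2 + 120 * tau ** 3
    return s, v, a


def simulate_reach(aim: float, go_cue_time: float, rt_offset_s: float,
                   cfg: SimulationConfig, rng):
    """Draw one reach: endpoint angle and movement-onset time.

    The endpoint is the aim direction plus von Mises angular noise with
    circular standard deviation ``motor_noise_sd`` (kappa = 1/sd^2);
    zero noise returns the aim exactly.  Movement onset is
    go cue + reaction-time offset + truncated Gaussian jitter.
    """
    jitter = rng.normal(0.0, cfg.rt_jitter_sd_s) if cfg.rt_jitter_sd_s > 0 else 0.0
    onset = go_cue_time + max(rt_offset_s + jitter, 0.001)
    if cfg.motor_noise_sd > 0:
        endpoint = float(wrap_angle(rng.vonmises(aim, 1.0 / cfg.motor_noise_sd ** 2)))
    else:
        endpoint = float(wrap_angle(aim))
    return endpoint, onset


def _trial_kinematics(endpoint, movement_onset, reach_end, return_start,
                      span, cfg: SimulationConfig, durations=None):
    """Analytic kinematics table for one trial on a uniform grid.

    Hold at center, minimum-jerk reach out to the 7-cm ring along
    ``endpoint``, hold at the ring, minimum-jerk return to center, hold.
    Velocity and acceleration columns are the closed-form derivatives, so
    they agree with finite differences of position to O(dt^2).
    """
    dt = 1.0 / cfg.kinematics_rate_hz
    t = np.arange(0.0, span + 0.5 * dt, dt)
    r = cfg.task.target_radius_cm
    ex, ey = r * np.cos(endpoint), r * np.sin(endpoint)
    T_out, T_back = durations if durations is not None \
        else (cfg.reach_duration_s, cfg.reach_duration_s)

    x = np.zeros_like(t)
    y = np.zeros_like(t)
    vx = np.zeros_like(t)
    vy = np.zeros_like(t)
    ax = np.zeros_like(t)
    ay = np.zeros_like(t)

    def _segment(t0, T, x0, y0, x1, y1):
        m = (t >= t0) & (t < t0 + T)
        tau = (t[m] - t0) / T
        s, v, a = _min_jerk(tau)
        dx_, dy_ = x1 - x0, y1 - y0
        x[m] = x0 + dx_ * s
        y[m] = y0 + dy_ * s
        vx[m] = dx_ * v / T
        vy[m] = dy_ * v / T
        ax[m] = dx_ * a / T ** 2
        ay[m] = dy_ * a / T ** 2

    # outward reach, hold at ring, return reach (holds are zeros by default)
    hold_out = (t >= movement_onset + T_out) & (t < return_start)
    x[hold_out], y[hold_out] = ex, ey
    _segment(movement_onset, T_out, 0.0, 0.0, ex, ey)
    _segment(return_start, T_back, ex, ey, 0.0, 0.0)
    return pd.DataFrame({"time": t, "x": x, "y": y, "vx": vx, "vy": vy,
                         "ax": ax, "ay": ay})


def weight_vector_for(weights: GroundTruthWeights, column_names):
    """Align ground-truth kernels with design feature columns (excl. intercept)."""
    w = np.zeros(len(column_names) - 1)
    for i, name in enumerate(column_names[1:]):
        ch, b = name.rsplit(":b", 1)
        kern = weights.kernels.get(ch)
        if kern is not None:
            w[i] = kern[int(b)]
    return w


def generate_spikes(features, column_names, weights: GroundTruthWeights, rng):
    """Poisson spike counts per epoch bin from the generative encoding model.

    ``features`` are design rows (including the intercept column) produced by
    the shared design path; counts are drawn independently per bin from
    Poisson(exp(baseline + features . weights)).
    """
    w = weight_vector_for(weights, column_names)
    eta = weights.baseline_log_rate + features[:, 1:] @ w
    if np.max(np.abs(eta)) > 20.0:
        raise ValueError("generative |log-rate| exceeds 20; rescale the "
                         "ground-truth kernel weights")
    return rng.poisson(np.exp(eta))


def simulate_session(cfg: SimulationConfig) -> Session:
    """Generate a full synthetic session; bit-deterministic given the seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    task = cfg.task
    lo, hi = task.epoch_window_s

    trials = []
    kin_frames = []
    prev_outcome = 1  # first-trial convention, recorded in metadata
    for tid in range(cfg.n_trials):
        condition = "broad" if rng.random() < cfg.p_broad_cue else "narrow"
        target, cues, dispersion = sample_target_and_cue(task, condition, rng)
        delay = rng.uniform(*task.delay_range_s)
        go = cfg.cue_onset_s + delay
        aim = circular_mean(cues)
        rt = cfg.rt_offset_narrow_s if condition == "narrow" else cfg.rt_offset_broad_s
        endpoint, onset = simulate_reach(aim, go, rt, cfg, rng)
        jit = cfg.reach_duration_jitter_s
        dur_out = cfg.reach_duration_s + (rng.uniform(-jit, jit) if jit > 0 else 0.0)
        dur_back = cfg.reach_duration_s + (rng.uniform(-jit, jit) if jit > 0 else 0.0)
        reach_end = onset + dur_out
        reward_onset = reach_end + cfg.reward_delay_s
        return_start = reward_onset + cfg.return_delay_s
        span = reward_onset + hi + 0.1

        err = float(circ_dist(endpoint, target))
        success = err <= task.success_halfwidth_rad
        withheld = bool(success and cfg.withheld_reward_fraction > 0
                        and rng.random() < cfg.withheld_reward_fraction)
        rewarded = success and not withheld

        trials.append(Trial(
            trial_id=tid, true_target=target, cue_angles=cues,
            cue_condition=condition, dispersion=dispersion,
            go_cue_time=go, movement_onset_time=onset,
            reward_onset_time=reward_onset, reach_endpoint=endpoint,
            error_magnitude=err, success=success, rewarded=rewarded,
            withheld=withheld, previous_outcome=prev_outcome,
            return_direction=float(wrap_angle(endpoint + np.pi)),
        ))
        kin = _trial_kinematics(endpoint, onset, reach_end, return_start, span, cfg,
                                durations=(dur_out, dur_back))
        kin.insert(0, "trial_id", tid)
        kin_frames.append(kin)
        prev_outcome = 1 if success else -1

    kinematics = pd.concat(kin_frames, ignore_index=True) if kin_frames \
        else pd.DataFrame(columns=KINEMATICS_COLUMNS)

    neuron_ids = [s.neuron_id for s in cfg.neuron_specs]
    region_labels = {s.neuron_id: s.region for s in cfg.neuron_specs}
    ground_truth = {s.neuron_id: s.weights for s in cfg.neuron_specs} or None

    session = Session(config=task, trials=trials,
                      spikes=pd.DataFrame(columns=SPIKE_COLUMNS),
                      kinematics=kinematics, neuron_ids=neuron_ids,
                      region_labels=region_labels, ground_truth=ground_truth,
                      meta={"simulated": True, "seed": cfg.seed,
                            "first_trial_previous_outcome": 1,
                            "iti_range_s": list(cfg.iti_range_s)})

    if neuron_ids:
        dm = build_design_matrix(session, neuron_ids=[],
                                 covariates=ALL_COVARIATES)
        kin_spans = {tid: float(g["time"].max())
                     for tid, g in kinematics.groupby("trial_id")}
        n_bins = task.n_epoch_bins
        bw = task.bin_width_s
        rows = []
        for spec in cfg.neuron_specs:
            counts = generate_spikes(dm.X, dm.column_names, spec.weights, rng)
            base_hz = np.exp(spec.weights.baseline_log_rate) / bw
            for i, trial in enumerate(trials):
                c = counts[i * n_bins:(i + 1) * n_bins]
                nz = np.flatnonzero(c)
                if len(nz):
                    reps = np.repeat(nz, c[nz])
                    times = (trial.reward_onset_time + lo + (reps + rng.random(len(reps))) * bw)
                    rows.append(pd.DataFrame({
                        "neuron_id": spec.neuron_id, "trial_id": trial.trial_id,
                        "spike_time": np.sort(times)}))
                # homogeneous baseline spiking outside the modeled epoch;
                # bounded by the kinematics grid so spikes stay in-span
                span = kin_spans[trial.trial_id]
                pre_len = trial.reward_onset_time + lo
                post_len = span - (trial.reward_onset_time + hi)
                extra = []
                for seg_start, seg_len in ((0.0, pre_len),
                                           (trial.reward_onset_time + hi, post_len)):
                    if seg_len <= 0:
                        continue
                    n = rng.poisson(base_hz * seg_len)
                    if n:
                        extra.append(seg_start + np.sort(rng.random(n)) * seg_len)
                if extra:
                    st = np.concatenate(extra)
                    rows.append(pd.DataFrame({
                        "neuron_id": spec.neuron_id, "trial_id": trial.trial_id,
                        "spike_time": st}))
        if rows:
            spikes = pd.concat(rows, ignore_index=True)
            spikes = spikes.sort_values(
                ["neuron_id", "trial_id", "spike_time"], kind="mergesort",
            ).reset_index(drop=True)
            session.spikes = spikes
    return session


# ---------------------------------------------------------------------------
# default populations

def benchmark_weights(index: int, baseline_hz: float = 20.0,
                      bin_width_s: float = 0.010) -> GroundTruthWeights:
    """Default ground truth: reward + kinematics encoding.

    The reward kernel is negative (firing increases after *unrewarded*
    outcomes) and peaks 400-600 ms after the outcome cue, the latency regime
    of the cortical reward signal.  Kinematic weights are sized for the cm/s
    feature scale so single-channel log-rate modulation stays ~0.5.
    Amplitudes vary deterministically with the neuron index so the population
    is heterogeneous.
    """
    amp = 0.7 + 0.3 * ((index * 7) % 5) / 4.0
    kamp = 0.8 + 0.4 * ((index * 3) % 5) / 4.0
    return GroundTruthWeights(
        baseline_log_rate=float(np.log(baseline_hz * bin_width_s)),
        kernels={
            "reward": amp * np.array([0.0, -0.25, -0.70, -0.45]),
            "vx": kamp * np.array([8e-4, 4e-4, 0.0, 0.0]),
            "vy": kamp * np.array([0.0, 6e-4, 3e-4, 0.0]),
            "ax": kamp * np.array([1e-4, 0.0, 0.0, 0.0]),
            "ay": kamp * np.array([0.0, 0.5e-4, 0.0, 0.0]),
        })


def null_weights(baseline_hz: float = 20.0,
                 bin_width_s: float = 0.010) -> GroundTruthWeights:
    """Ground truth with no covariate coding at all (calibration controls)."""
    return GroundTruthWeights(
        baseline_log_rate=float(np.log(baseline_hz * bin_width_s)), kernels={})


def default_neuron_specs(n_neurons: int, kind: str = "benchmark",
                         pmd_fraction: float = 0.6,
                         baseline_hz: float = 20.0) -> list:
    """Standard populations: 'benchmark' (reward+kinematics) or 'null'."""
    specs = []
    n_pmd = int(round(pmd_fraction * n_neurons))
    for i in range(n_neurons):
        region = "PMd" if i < n_pmd else "M1"
        if kind == "benchmark":
            w = benchmark_weights(i, baseline_hz=baseline_hz)
        elif kind == "null":
            w = null_weights(baseline_hz=baseline_hz)
        else:
            raise ValueError(f"unknown population kind {kind!r}")
        specs.append(NeuronSpec(neuron_id=i, region=region, weights=w))
    return specs
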