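"""Standard synthetic benchmarks for the analysis pipeline.

These procedures define the package's reference study conditions — the
sessions, populations and metrics used both by the acceptance checks and by
anyone wanting a quick end-to-end calibration of the method:

- ``benchmark_battery``: a 400-trial, 20-neuron session whose neurons encode
  reward (negative kernel peaking 400-600 ms post-outcome) and kinematics;
  reports covariate-battery sensitivity on the encoded covariates, the
  false-positive rate on the null scalar confounds (uncertainty, error,
  reward history), and kernel-recovery correlations at lambda = 0.001.
- ``null_psth_calibration`` / ``null_battery_calibration``: type-I error of
  the PSTH reward-modulation test and of the battery on neurons with no
  covariate coding at all.
- ``directional_effect_check``: the population-level up-for-unrewarded
  signature and per-neuron direction calls.
- ``behavior_check``: success rate, cue dispersion and movement latency as a
  function of cue concentration.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compare import run_covariate_battery
from .design import build_design_matrix
from .glm import GlmConfig, fit_poisson_elasticnet
from .psth import (compute_psth, match_kinematics, modulation_test_from_rates,
                   population_normalized_psth, reward_modulation_test)
from .simulate import (SimulationConfig, default_neuron_specs,
                       simulate_session, weight_vector_for)

#: covariate classes encoded by the benchmark ground truth
BENCHMARK_TRUE_COVARIATES = ("reward", "kinematics")
#: null scalar confounds counted in the benchmark false-positive rate
#: (return_goal is excluded: its features overlap the true kinematic signal
#: through the task geometry, so dropping it has a real held-out cost)
BENCHMARK_NULL_COVARIATES = ("uncertainty", "error", "reward_history")


@dataclass
class BatteryBenchmarkResult:
    sensitivity: float                 # over true covariates x neurons
    false_positive_rate: float         # over null covariates x neurons
    per_covariate_rates: dict          # covariate -> significant fraction
    recovery_correlations: list        # per neuron, lambda = 0.001
    mean_relative_pseudo_r2_reward: float
    full_model_pseudo_r2_mean: float
    prediction_r2_vs_truth: list = field(default_factory=list)
    prediction_r2_vs_empirical: list = field(default_factory=list)


def benchmark_session(seed: int, n_trials: int = 400, n_neurons: int = 20,
                      kind: str = "benchmark"):
    cfg = SimulationConfig(n_trials=n_trials,
                           neuron_specs=default_neuron_specs(n_neurons, kind=kind),
                           seed=seed)
    return simulate_session(cfg)


def benchmark_battery(seed: int, n_trials: int = 400, n_neurons: int = 20,
                      B: int = 1000, recovery_lam: float = 0.001,
                      with_recovery: bool = True) -> BatteryBenchmarkResult:
    """Run the covariate battery on the standard benchmark session."""
    session = benchmark_session(seed, n_trials=n_trials, n_neurons=n_neurons)
    design = build_design_matrix(session)
    battery = run_covariate_battery(session, glm_cfg=GlmConfig(seed=seed),
                                    B=B, seed=seed, design=design)
    df = battery.to_frame()
    df["sig"] = df.sigma_level != "none"

    rates = {c: float(df[df.covariate == c].sig.mean())
             for c in battery.covariates}
    sens = float(df[df.covariate.isin(BENCHMARK_TRUE_COVARIATES)].sig.mean())
    fpr = float(df[df.covariate.isin(BENCHMARK_NULL_COVARIATES)].sig.mean())

    recovery, r2_truth, r2_emp = [], [], []
    if with_recovery:
        cfg_rec = GlmConfig(lam=recovery_lam, seed=seed)
        for nid in session.neuron_ids:
            res = fit_poisson_elasticnet(design, nid, cfg_rec)
            wt = weight_vector_for(session.ground_truth[nid],
                                   design.column_names)
            recovery.append(float(np.corrcoef(res.weights, wt)[0, 1]))
            gt = session.ground_truth[nid]
            true_rate = np.exp(gt.baseline_log_rate + design.X[:, 1:] @ wt)
            pred = res.predict().reshape(-1, 200).mean(axis=0)
            tp = true_rate.reshape(-1, 200).mean(axis=0)
            ep = design.counts[nid].reshape(-1, 200).mean(axis=0)
            r2_truth.append(float(np.corrcoef(pred, tp)[0, 1] ** 2))
            r2_emp.append(float(np.corrcoef(pred, ep)[0, 1] ** 2))

    rew = df[df.covariate == "reward"]
    return BatteryBenchmarkResult(
        sensitivity=sens, false_positive_rate=fpr, per_covariate_rates=rates,
        recovery_correlations=recovery,
        mean_relative_pseudo_r2_reward=float(rew.mean_relative_pseudo_r2.mean()),
        full_model_pseudo_r2_mean=float(battery.full_model.pseudo_r2_mean.mean()),
        prediction_r2_vs_truth=r2_truth, prediction_r2_vs_empirical=r2_emp)


def null_psth_calibration(seed: int, n_neurons: int = 1000,
                          n_trials_per_condition: int = 60,
                          rate_hz: float = 20.0, n_family: int | None = None,
                          alpha: float = 0.05) -> float:
    """Fraction of null neurons flagged by the Bonferroni-corrected test.

    Each simulated neuron fires at the same Poisson rate on rewarded and
    unrewarded trials; per-trial mean rates over the [0, 1.5] s window feed
    the same two one-sided t-tests the session-level test uses, corrected for
    ``n_family`` neurons (defaults to the population size).
    """
    rng = np.random.default_rng(seed)
    n_family = n_family or n_neurons
    window = 1.5
    lam = rate_hz * window
    flagged = 0
    for _ in range(n_neurons):
        a = rng.poisson(lam, size=n_trials_per_condition) / window
        b = rng.poisson(lam, size=n_trials_per_condition) / window
        res = modulation_test_from_rates(a, b, n_family, alpha=alpha)
        flagged += res.significant
    return flagged / n_neurons


def null_battery_calibration(seed: int, n_trials: int = 200,
                             n_neurons: int = 40, B: int = 500) -> dict:
    """Per-covariate significant fraction on neurons with no coding at all."""
    session = benchmark_session(seed, n_trials=n_trials, n_neurons=n_neurons,
                                kind="null")
    battery = run_covariate_battery(session, glm_cfg=GlmConfig(seed=seed),
                                    B=B, seed=seed)
    df = battery.to_frame()
    df["sig"] = df.sigma_level != "none"
    return {c: float(df[df.covariate == c].sig.mean())
            for c in battery.covariates}


def directional_effect_check(seed: int, n_trials: int = 400,
                             n_neurons: int = 12) -> dict:
    """Population PSTH signature and per-neuron direction calls.

    Returns the fraction of effect neurons called up_unrewarded, the number
    of matched pairs, and the per-bin post-onset differences of the
    population-normalized PSTHs (unrewarded - rewarded).
    """
    session = benchmark_session(seed, n_trials=n_trials, n_neurons=n_neurons)
    rew = session.trial_ids(rewarded=True)
    unrew = session.trial_ids(rewarded=False)
    match = match_kinematics(session, rew, unrew)

    n_up = 0
    pairs = {}
    for nid in session.neuron_ids:
        res = reward_modulation_test(session, nid, match, n_neurons)
        n_up += res.direction == "up_unrewarded"
        pairs[nid] = {
            "rewarded": compute_psth(session, nid, match.rewarded_ids,
                                     condition="rewarded"),
            "unrewarded": compute_psth(session, nid, match.unrewarded_ids,
                                       condition="unrewarded"),
        }
    pop = population_normalized_psth(pairs)
    post = pop.bin_centers > 0
    diffs = pop.mean["unrewarded"][post] - pop.mean["rewarded"][post]
    return {"fraction_up_unrewarded": n_up / n_neurons,
            "n_matched_pairs": len(match.pairs),
            "post_onset_differences": diffs}


def behavior_check(seed: int, n_trials: int = 1000) -> dict:
    """Success, dispersion and latency by cue condition on a large session."""
    session = simulate_session(SimulationConfig(n_trials=n_trials, seed=seed))
    out = {}
    for cond in ("narrow", "broad"):
        tr = [t for t in session.trials if t.cue_condition == cond]
        lat = np.array([t.movement_onset_time - t.go_cue_time for t in tr])
        out[cond] = {
            "success_rate": float(np.mean([t.success for t in tr])),
            "mean_dispersion": float(np.mean([t.dispersion for t in tr])),
            "latency_mean_s": float(lat.mean()),
            "latency_sem_s": float(lat.std(ddof=1) / np.sqrt(len(lat))),
            "n": len(tr),
        }
    return out
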