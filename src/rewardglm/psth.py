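"""PSTH estimation, kinematic trial matching, and reward-modulation tests.

Firing rates are estimated in 25-ms bins aligned to the reward timestamp (the
end-of-trial outcome cue) and averaged across trials; single-neuron reward
modulation is assessed by one-sided t-tests on mean rates in the [0, 1.5] s
post-outcome interval, Bonferroni-corrected for the number of neurons.
Because rewarded and unrewarded trials may differ behaviorally, the two
conditions are first matched on their single-trial speed profiles, and the
match is checked by an explicit balance test rather than assumed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class Psth:
    """Trial-averaged firing rate (spikes/s) on a uniform bin grid."""

    bin_centers: np.ndarray    # s relative to reward onset
    rate: np.ndarray           # spikes/s per bin
    sem: np.ndarray            # across-trial SEM, spikes/s
    n_trials: int
    condition: str = ""        # 'rewarded' | 'unrewarded' | ''


@dataclass
class MatchReport:
    """Outcome of kinematic trial matching between the two reward conditions."""

    pairs: list                        # (rewarded_id, unrewarded_id)
    discarded_rewarded: int
    discarded_unrewarded: int
    mean_speed_diff: float             # matched rewarded - unrewarded, cm/s
    p_balance: float                   # post-match two-sample t-test
    p_balance_pre: float               # same test before matching

    @property
    def rewarded_ids(self):
        return [p[0] for p in self.pairs]

    @property
    def unrewarded_ids(self):
        return [p[1] for p in self.pairs]


def _aligned_counts(session, neuron_id, trial_ids, edges):
    """Per-trial spike counts in bins aligned to each trial's reward onset."""
    sp = session.spikes
    sub = sp[sp["neuron_id"] == neuron_id]
    by_trial = {tid: g["spike_time"].to_numpy() for tid, g in sub.groupby("trial_id")}
    out = np.zeros((len(trial_ids), len(edges) - 1))
    for i, tid in enumerate(trial_ids):
        trial = session.trial(tid)
        st = by_trial.get(tid)
        if st is not None and len(st):
            out[i], _ = np.histogram(st - trial.reward_onset_time, bins=edges)
    return out


def compute_psth(session, neuron_id, trial_ids, window=(-0.5, 1.5),
                 bin_width: float = 0.025, condition: str = "") -> Psth:
    """PSTH of one neuron over a set of trials, aligned to reward onset.

    rate[b] is the across-trial mean of count/bin_width; sem[b] the
    across-trial standard error of the same quantity.
    """
    trial_ids = list(trial_ids)
    if len(trial_ids) < 2:
        raise ValueError("compute_psth needs at least 2 trials")
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + np.arange(n_bins + 1) * bin_width
    counts = _aligned_counts(session, neuron_id, trial_ids, edges)
    rates = counts / bin_width
    return Psth(bin_centers=0.5 * (edges[:-1] + edges[1:]),
                rate=rates.mean(axis=0),
                sem=rates.std(axis=0, ddof=1) / np.sqrt(len(trial_ids)),
                n_trials=len(trial_ids), condition=condition)


def _speed_profile(session, trial, n_points=50):
    """Single-trial speed profile resampled to n_points over the reach.

    The reach window runs from movement onset to the last time the speed
    exceeds 5% of its peak before reward onset (falling back to reward onset
    for flat profiles).
    """
    kin = session.kinematics
    g = kin[kin["trial_id"] == trial.trial_id]
    if not len(g):
        raise ValueError(f"trial {trial.trial_id} has no kinematics")
    t = g["time"].to_numpy()
    speed = np.hypot(g["vx"].to_numpy(), g["vy"].to_numpy())
    m = (t >= trial.movement_onset_time) & (t <= trial.reward_onset_time)
    tm, sm = t[m], speed[m]
    if len(sm) < 2:
        raise ValueError(f"trial {trial.trial_id}: no samples in reach window")
    peak = sm.max()
    if peak > 0:
        last = np.flatnonzero(sm >= 0.05 * peak)[-1]
        end = tm[last] if last > 0 else tm[-1]
    else:
        end = tm[-1]
    grid = np.linspace(trial.movement_onset_time, end, n_points)
    return np.interp(grid, tm, sm)


def match_kinematics(session, rewarded_ids, unrewarded_ids, n_points: int = 50,
                     discard_quantile: float = 0.75) -> MatchReport:
    """Greedy nearest-neighbor pairing of trials on speed profiles.

    Pairs are formed without replacement by repeatedly taking the globally
    closest (rewarded, unrewarded) pair under Euclidean distance between
    resampled speed profiles; pairs whose distance exceeds the
    ``discard_quantile`` of the matched-pair distance distribution are then
    discarded.  The report carries a two-sample t-test on matched mean speeds
    as a falsifiable balance check (expected non-significant).
    """
    rewarded_ids, unrewarded_ids = list(rewarded_ids), list(unrewarded_ids)
    if not rewarded_ids or not unrewarded_ids:
        raise ValueError("both conditions must be nonempty")
    prof_r = np.stack([_speed_profile(session, session.trial(t), n_points)
                       for t in rewarded_ids])
    prof_u = np.stack([_speed_profile(session, session.trial(t), n_points)
                       for t in unrewarded_ids])

    p_pre = stats.ttest_ind(prof_r.mean(axis=1), prof_u.mean(axis=1)).pvalue

    d = np.sqrt(((prof_r[:, None, :] - prof_u[None, :, :]) ** 2).sum(axis=2))
    dist = d.copy()
    pairs, pair_d = [], []
    n_pairs = min(len(rewarded_ids), len(unrewarded_ids))
    for _ in range(n_pairs):
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        pairs.append((rewarded_ids[i], unrewarded_ids[j], i, j))
        pair_d.append(dist[i, j])
        dist[i, :] = np.inf
        dist[:, j] = np.inf
    pair_d = np.array(pair_d)

    thresh = np.quantile(pair_d, discard_quantile)
    kept = [(p, dd) for p, dd in zip(pairs, pair_d) if dd <= thresh]
    if len(kept) < 2:
        raise ValueError("fewer than 2 matched pairs survive; relax "
                         "discard_quantile or check the kinematics")
    kept_pairs = [(p[0], p[1]) for p, _ in kept]
    ki = [p[2] for p, _ in kept]
    kj = [p[3] for p, _ in kept]
    ms_r = prof_r[ki].mean(axis=1)
    ms_u = prof_u[kj].mean(axis=1)
    with np.errstate(invalid="ignore"):
        p_post = stats.ttest_ind(ms_r, ms_u).pvalue
    if np.isnan(p_post):  # identical profiles -> zero variance; perfectly balanced
        p_post = 1.0
    return MatchReport(pairs=kept_pairs,
                       discarded_rewarded=len(rewarded_ids) - len(kept_pairs),
                       discarded_unrewarded=len(unrewarded_ids) - len(kept_pairs),
                       mean_speed_diff=float(ms_r.mean() - ms_u.mean()),
                       p_balance=float(p_post), p_balance_pre=float(p_pre))


@dataclass
class ModulationResult:
    direction: str      # 'up_unrewarded' | 'up_rewarded' | 'none'
    p: float            # smaller one-sided p-value
    significant: bool
    mean_rate_rewarded: float
    mean_rate_unrewarded: float


def modulation_test_from_rates(rates_rewarded, rates_unrewarded,
                               n_neurons_for_correction: int,
                               alpha: float = 0.05) -> ModulationResult:
    """Core reward-modulation test on per-trial mean rates.

    Two one-sided Welch t-tests (one per direction); the neuron is called
    significant when the smaller one-sided p falls below the
    Bonferroni-corrected level alpha / n_neurons, and the winning direction
    is reported.
    """
    r = np.asarray(rates_rewarded, dtype=float)
    u = np.asarray(rates_unrewarded, dtype=float)
    if r.std(ddof=1) == 0 and u.std(ddof=1) == 0:
        warnings.warn("zero-variance rates; modulation test skipped", RuntimeWarning)
        return ModulationResult("none", np.nan, False, float(r.mean()), float(u.mean()))
    p_up_unrew = stats.ttest_ind(u, r, equal_var=False, alternative="greater").pvalue
    p_up_rew = stats.ttest_ind(r, u, equal_var=False, alternative="greater").pvalue
    if p_up_unrew <= p_up_rew:
        direction, p = "up_unrewarded", float(p_up_unrew)
    else:
        direction, p = "up_rewarded", float(p_up_rew)
    significant = bool(p < alpha / max(n_neurons_for_correction, 1))
    return ModulationResult(direction if significant else "none", p, significant,
                            float(r.mean()), float(u.mean()))


def reward_modulation_test(session, neuron_id, matched: MatchReport,
                           n_neurons_for_correction: int, alpha: float = 0.05,
                           window=(0.0, 1.5)) -> ModulationResult:
    """Reward-modulation test for one neuron on kinematically matched trials.

    Per-trial mean rate is the spike count in ``window`` (s after reward
    onset) divided by the window length.
    """
    lo, hi = window
    edges = np.array([lo, hi])
    cr = _aligned_counts(session, neuron_id, matched.rewarded_ids, edges)[:, 0]
    cu = _aligned_counts(session, neuron_id, matched.unrewarded_ids, edges)[:, 0]
    return modulation_test_from_rates(cr / (hi - lo), cu / (hi - lo),
                                      n_neurons_for_correction, alpha=alpha)


@dataclass
class PopulationPsth:
    bin_centers: np.ndarray
    mean: dict = field(default_factory=dict)   # condition -> (n_bins,) array
    sem: dict = field(default_factory=dict)
    n_neurons: int = 0


def population_normalized_psth(psths_by_neuron: dict) -> PopulationPsth:
    """Peak-normalized population average over neurons.

    ``psths_by_neuron`` maps neuron_id to a dict with 'rewarded' and
    'unrewarded' Psth objects.  Each neuron's two PSTHs are divided by the
    *joint* peak over both conditions (so the between-condition difference
    survives normalization), then averaged across neurons with an
    across-neuron SEM.  All-zero neurons are excluded with a warning.
    """
    if not psths_by_neuron:
        raise ValueError("need at least one neuron")
    curves = {"rewarded": [], "unrewarded": []}
    bin_centers = None
    for nid, pair in psths_by_neuron.items():
        peak = max(pair["rewarded"].rate.max(), pair["unrewarded"].rate.max())
        if peak <= 0:
            warnings.warn(f"neuron {nid}: all-zero PSTH excluded from the "
                          "population average", RuntimeWarning)
            continue
        for cond in curves:
            curves[cond].append(pair[cond].rate / peak)
        bin_centers = pair["rewarded"].bin_centers
    n = len(curves["rewarded"])
    if n == 0:
        raise ValueError("all neurons had empty PSTHs")
    out = PopulationPsth(bin_centers=bin_centers, n_neurons=n)
    for cond, rows in curves.items():
        arr = np.stack(rows)
        out.mean[cond] = arr.mean(axis=0)
        out.sem[cond] = (arr.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 \
            else np.zeros(arr.shape[1])
    return out
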