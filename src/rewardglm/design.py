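"""Raised-cosine temporal bases and design-matrix assembly.

Covariates are expanded into time-lagged features by convolving each covariate
series with a set of raised-cosine kernels.  Event-like covariates use a
*lead* basis (kernels at nonnegative delays: the event precedes the spikes it
drives); kinematic covariates use a *lag* basis (kernels at nonpositive
delays: motor-cortical spikes precede the movement they cause).

Convolution is performed the trial-safe way: every trial is zero-padded on
both sides, trials are concatenated, the padded series is convolved, and the
padding is removed.  With padding of at least a kernel half-length the result
is identical to convolving each trial in isolation, so no feature column ever
mixes data across trials.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .util import circular_dispersion  # noqa: F401  (canonical home, re-exported)

#: covariate class -> design channels
COVARIATE_CHANNELS = {
    "reward": ["reward"],
    "kinematics": ["vx", "vy", "ax", "ay"],
    "uncertainty": ["uncertainty"],
    "reward_history": ["reward_history"],
    "error": ["error"],
    "return_goal": ["return_cos", "return_sin"],
}
ALL_COVARIATES = tuple(COVARIATE_CHANNELS)
#: channels whose kernels lag the spikes (everything else leads)
LAG_CHANNELS = frozenset(["vx", "vy", "ax", "ay"])


@dataclass
class BasisSet:
    """Raised-cosine temporal kernels with lead/lag direction semantics.

    Each kernel is ``0.5 * (1 + cos(2*pi*(t - c_k)/width))`` on
    ``|t - c_k| <= width/2`` and zero elsewhere, sampled on the bin grid so
    the center sample is exactly 1 and the two boundary samples are exactly 0.
    Centers are spaced ``spacing_s`` apart starting at delay 0; for
    ``direction='lag'`` the center delays are negated (mirrored in time).
    """

    n_basis: int
    width_s: float
    spacing_s: float
    bin_width_s: float
    direction: str  # 'lead' | 'lag'
    kernels: np.ndarray = field(repr=False)  # (n_basis, L) samples
    first_delay_bins: np.ndarray = field(repr=False)  # delay (bins) of sample 0

    @property
    def kernel_length(self) -> int:
        return self.kernels.shape[1]

    @property
    def half_length_bins(self) -> int:
        return (self.kernel_length - 1) // 2

    def delays_s(self, k: int) -> np.ndarray:
        """Time delays (s) of kernel k's samples; positive delay = covariate past."""
        j = np.arange(self.kernel_length)
        return (self.first_delay_bins[k] + j) * self.bin_width_s


def raised_cosine_basis(n_basis: int = 4, width_s: float = 0.400,
                        spacing_s: float = 0.200, bin_width_s: float = 0.010,
                        direction: str = "lead") -> BasisSet:
    """Build a raised-cosine basis set.

    Defaults follow the analysis configuration: 4 kernels of 400-ms width with
    centers separated by 200 ms, on a 10-ms bin grid.  Width and spacing must
    be (even) multiples of the bin width so kernel centers and boundaries land
    on grid points.
    """
    if direction not in ("lead", "lag"):
        raise ValueError("direction must be 'lead' or 'lag'")
    half = width_s / (2.0 * bin_width_s)
    if abs(half - round(half)) > 1e-9:
        raise ValueError("width_s must be an even multiple of bin_width_s")
    sp = spacing_s / bin_width_s
    if abs(sp - round(sp)) > 1e-9:
        raise ValueError("spacing_s must be a multiple of bin_width_s")
    half = int(round(half))
    sp = int(round(sp))

    j = np.arange(-half, half + 1)  # sample offsets from center, in bins
    kern = 0.5 * (1.0 + np.cos(2.0 * np.pi * j * bin_width_s / width_s))
    kern[0] = 0.0
    kern[-1] = 0.0  # exact zeros at +- width/2
    kernels = np.tile(kern, (n_basis, 1))

    centers = np.arange(n_basis) * sp
    if direction == "lag":
        centers = -centers
    first = centers - half
    return BasisSet(n_basis=n_basis, width_s=width_s, spacing_s=spacing_s,
                    bin_width_s=bin_width_s, direction=direction,
                    kernels=kernels, first_delay_bins=first.astype(int))


def convolve_with_padding(series_by_trial, basis: BasisSet, pad_bins: int = 50):
    """Convolve per-trial covariate series with every kernel of a basis set.

    Each trial is zero-padded with ``pad_bins`` bins on both sides, trials are
    concatenated, the padded series is convolved with each kernel, and the
    padding is removed.  ``pad_bins`` must be at least the kernel half-length,
    which guarantees the output for each trial equals the convolution of that
    trial in isolation (leakage-free).

    The feature for kernel k is ``f[t] = sum_d x[t - d] * k(d)`` over the
    kernel's delay support; a lag-direction kernel has negative delays, so the
    operation there is a correlation with the time-reversed kernel.

    Parameters
    ----------
    series_by_trial : sequence of 1-D arrays
        Covariate value per bin, one array per trial.
    basis : BasisSet
    pad_bins : int

    Returns
    -------
    list of (n_bins_trial, n_basis) arrays, one per trial.
    """
    if pad_bins < basis.half_length_bins:
        raise ValueError("pad_bins must be >= kernel half-length "
                         f"({basis.half_length_bins} bins)")
    series_by_trial = [np.asarray(s, dtype=float) for s in series_by_trial]
    for s in series_by_trial:
        if s.ndim != 1 or s.size < 1:
            raise ValueError("each trial series must be a nonempty 1-D array")

    pad = np.zeros(pad_bins)
    pieces, starts, pos = [], [], 0
    for s in series_by_trial:
        pieces += [pad, s, pad]
        starts.append(pos + pad_bins)
        pos += len(s) + 2 * pad_bins
    concat = np.concatenate(pieces)

    out = [np.empty((len(s), basis.n_basis)) for s in series_by_trial]
    for k in range(basis.n_basis):
        # full[m] = sum_j concat[m - j] * kern[j]; with tap j at delay
        # d_j = first_delay + j, feature[g] = full[g - first_delay].
        full = np.convolve(concat, basis.kernels[k], mode="full")
        fd = int(basis.first_delay_bins[k])
        for i, s in enumerate(series_by_trial):
            lo = starts[i] - fd
            out[i][:, k] = full[lo:lo + len(s)]
    return out


@dataclass
class DesignMatrix:
    """Stacked per-trial epochs with covariate-by-basis feature columns.

    Rows are the concatenated 10-ms bins of every trial's analysis epoch
    (neuron-independent); ``counts`` holds one spike-count vector per neuron
    on the same rows.  Column 0 is the intercept; ``column_groups`` maps each
    covariate class to the indices of its feature columns and partitions all
    non-intercept columns.
    """

    X: np.ndarray                      # (n_rows, 1 + n_features), col 0 = intercept
    column_names: list                 # len = X.shape[1]
    column_groups: dict                # covariate class -> np.ndarray of col indices
    trial_ids: list                    # trial id per epoch block
    trial_index: np.ndarray            # (n_rows,) index into trial_ids
    bin_times: np.ndarray              # (n_bins_per_trial,) bin centers rel. reward onset
    bin_width_s: float
    counts: dict = field(default_factory=dict)  # neuron_id -> (n_rows,) int array

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_bins_per_trial(self) -> int:
        return len(self.bin_times)

    @property
    def feature_indices(self) -> np.ndarray:
        return np.arange(1, self.X.shape[1])

    def rows_for_trials(self, trial_ids) -> np.ndarray:
        pos = {t: i for i, t in enumerate(self.trial_ids)}
        want = np.array(sorted(pos[t] for t in trial_ids))
        return np.concatenate([np.flatnonzero(self.trial_index == i) for i in want]) \
            if len(want) else np.array([], dtype=int)

    def columns_without(self, covariate: str) -> np.ndarray:
        """All column indices (incl. intercept) except one covariate group."""
        drop = set(self.column_groups[covariate].tolist())
        return np.array([j for j in range(self.X.shape[1]) if j not in drop])


def _trial_channel_series(trial, kin_trial, config, channels):
    """Per-channel covariate series over the trial's epoch bins.

    Scalar covariates enter as an impulse of the scalar value at the
    reward-onset bin; kinematic channels are the instantaneous velocity /
    acceleration components linearly interpolated onto the bin centers.
    """
    lo, hi = config.epoch_window_s
    n_bins = config.n_epoch_bins
    bw = config.bin_width_s
    bin_times = lo + (np.arange(n_bins) + 0.5) * bw
    onset_bin = int(np.floor((0.0 - lo) / bw))

    out = {}
    kin_t = kin_abs = None
    for ch in channels:
        if ch in LAG_CHANNELS:
            if kin_trial is None or not len(kin_trial):
                raise ValueError(f"trial {trial.trial_id}: kinematics required "
                                 f"for channel {ch}")
            if kin_t is None:
                kin_t = kin_trial["time"].to_numpy()
                kin_abs = trial.reward_onset_time + bin_times
            out[ch] = np.interp(kin_abs, kin_t, kin_trial[ch].to_numpy())
        else:
            s = np.zeros(n_bins)
            s[onset_bin] = {
                "reward": 1.0 if trial.rewarded else -1.0,
                "uncertainty": trial.dispersion,
                "reward_history": float(trial.previous_outcome),
                "error": trial.error_magnitude,
                "return_cos": np.cos(trial.return_direction),
                "return_sin": np.sin(trial.return_direction),
            }[ch]
            out[ch] = s
    return out, bin_times


def build_design_matrix(session, neuron_ids=None, basis_lead=None, basis_lag=None,
                        covariates=ALL_COVARIATES, pad_bins: int = 50) -> DesignMatrix:
    """Assemble the design matrix over the session's trial epochs.

    Per trial epoch (default 200 bins of 10 ms spanning -0.5..+1.5 s around
    reward onset): the reward covariate is a +/-1 impulse at the reward-onset
    bin convolved with the lead basis; uncertainty, reward history, error and
    the return-goal direction cosines are scalar-scaled impulses convolved
    with the lead basis; the four kinematic components are series convolved
    with the lag basis.  Spike counts are binned on the same grid for each
    requested neuron.

    Parameters
    ----------
    session : Session
    neuron_ids : sequence or None
        Neurons whose spike counts to bin; None means all in the session,
        an empty list skips counts (features only).
    basis_lead, basis_lag : BasisSet or None
        Defaults to the standard 4-kernel raised-cosine sets.
    covariates : sequence of covariate class names
    pad_bins : int
        Zero padding (bins) applied around each trial before convolution.
    """
    config = session.config
    unknown = [c for c in covariates if c not in COVARIATE_CHANNELS]
    if unknown:
        raise ValueError(f"unknown covariates: {unknown}")
    covariates = [c for c in ALL_COVARIATES if c in covariates]
    if basis_lead is None:
        basis_lead = raised_cosine_basis(direction="lead",
                                         bin_width_s=config.bin_width_s)
    if basis_lag is None:
        basis_lag = raised_cosine_basis(direction="lag",
                                        bin_width_s=config.bin_width_s)
    if neuron_ids is None:
        neuron_ids = list(session.neuron_ids)

    channels = [ch for c in covariates for ch in COVARIATE_CHANNELS[c]]
    kin_by_trial = {tid: g for tid, g in session.kinematics.groupby("trial_id")} \
        if len(session.kinematics) else {}

    series = {ch: [] for ch in channels}
    bin_times = None
    for trial in session.trials:
        per_ch, bin_times = _trial_channel_series(
            trial, kin_by_trial.get(trial.trial_id), config, channels)
        for ch in channels:
            series[ch].append(per_ch[ch])

    n_bins = config.n_epoch_bins
    n_trials = len(session.trials)
    feats, names, groups = [], [], {}
    col = 1
    for cov in covariates:
        idx = []
        for ch in COVARIATE_CHANNELS[cov]:
            basis = basis_lag if ch in LAG_CHANNELS else basis_lead
            per_trial = convolve_with_padding(series[ch], basis, pad_bins=pad_bins)
            feats.append(np.concatenate(per_trial, axis=0))
            names += [f"{ch}:b{k}" for k in range(basis.n_basis)]
            idx += list(range(col, col + basis.n_basis))
            col += basis.n_basis
        groups[cov] = np.array(idx, dtype=int)

    n_rows = n_trials * n_bins
    X = np.empty((n_rows, col))
    X[:, 0] = 1.0
    if feats:
        X[:, 1:] = np.concatenate(feats, axis=1)
    column_names = ["intercept"] + names

    trial_ids = [t.trial_id for t in session.trials]
    trial_index = np.repeat(np.arange(n_trials), n_bins)

    counts = {}
    lo, hi = config.epoch_window_s
    edges = lo + np.arange(n_bins + 1) * config.bin_width_s
    for nid in neuron_ids:
        c = np.zeros(n_rows, dtype=int)
        sp = session.spikes
        sub = sp[sp["neuron_id"] == nid]
        by_trial = {tid: g["spike_time"].to_numpy() for tid, g in sub.groupby("trial_id")}
        for i, trial in enumerate(session.trials):
            st = by_trial.get(trial.trial_id)
            if st is None or not len(st):
                continue
            rel = st - trial.reward_onset_time
            h, _ = np.histogram(rel, bins=edges)
            c[i * n_bins:(i + 1) * n_bins] = h
        counts[nid] = c

    if bin_times is None:
        bin_times = lo + (np.arange(n_bins) + 0.5) * config.bin_width_s
    return DesignMatrix(X=X, column_names=column_names, column_groups=groups,
                        trial_ids=trial_ids, trial_index=trial_index,
                        bin_times=bin_times, bin_width_s=config.bin_width_s,
                        counts=counts)


def save_design(dm: DesignMatrix, path) -> None:
    """Serialize a DesignMatrix to an .npz container."""
    import json as _json
    np.savez_compressed(
        path,
        X=dm.X,
        column_names=np.array(dm.column_names),
        groups_json=np.array(_json.dumps({k: v.tolist() for k, v in dm.column_groups.items()})),
        trial_ids=np.array(dm.trial_ids),
        trial_index=dm.trial_index,
        bin_times=dm.bin_times,
        bin_width_s=np.array(dm.bin_width_s),
        count_neurons=np.array(sorted(dm.counts)),
        counts=np.stack([dm.counts[n] for n in sorted(dm.counts)], axis=0)
        if dm.counts else np.zeros((0, dm.n_rows), dtype=int),
    )


def load_design(path) -> DesignMatrix:
    import json as _json
    z = np.load(path, allow_pickle=False)
    groups = {k: np.array(v, dtype=int)
              for k, v in _json.loads(str(z["groups_json"])).items()}
    neurons = z["count_neurons"]
    counts = {int(n): z["counts"][i] for i, n in enumerate(neurons)}
    return DesignMatrix(X=z["X"], column_names=[str(s) for s in z["column_names"]],
                        column_groups=groups, trial_ids=list(z["trial_ids"]),
                        trial_index=z["trial_index"], bin_times=z["bin_times"],
                        bin_width_s=float(z["bin_width_s"]), counts=counts)
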