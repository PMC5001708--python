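"""Domain types for a recording session and the portable on-disk format.

A session directory contains::

    session.json      task configuration, neuron ids, region labels, metadata
    trials.csv        one row per trial (events, covariates, outcome flags)
    spikes.csv        neuron_id, trial_id, spike_time (s, relative to trial start)
    kinematics.csv    trial_id, time, x, y, vx, vy, ax, ay  (cm, cm/s, cm/s^2)
    ground_truth.json optional simulator ground-truth encoding weights

Units are seconds / centimeters / radians throughout; angles are wrapped to
(-pi, pi] on read.  Spike times are stored relative to trial start; alignment
to reward onset is always computed downstream, never stored.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .util import circ_dist, circular_dispersion, wrap_angle

KINEMATICS_COLUMNS = ["trial_id", "time", "x", "y", "vx", "vy", "ax", "ay"]
SPIKE_COLUMNS = ["neuron_id", "trial_id", "spike_time"]

_TRIAL_SCALAR_COLUMNS = [
    "trial_id", "true_target", "cue_condition", "dispersion",
    "go_cue_time", "movement_onset_time", "reward_onset_time",
    "reach_endpoint", "error_magnitude", "success", "rewarded",
    "withheld", "previous_outcome", "return_direction",
]


class SessionValidationError(ValueError):
    """Raised when a session violates a structural invariant."""

    def __init__(self, violations):
        self.violations = list(violations)
        msg = "; ".join(str(v) for v in self.violations)
        super().__init__(f"invalid session: {msg}")


@dataclass
class TaskConfig:
    """Geometry and timing of the uncertain-target center-out task.

    Targets live on an annulus of radius ``target_radius_cm``; the true target
    is drawn from a von Mises prior centered at ``prior_center`` and cued by
    ``n_cue_segments`` line segments drawn from a von Mises likelihood centered
    on the target.  ``*_kappas`` are (narrow, broad) concentration pairs.
    """

    prior_center: float = np.pi / 2.0
    prior_kappas: tuple = (10.0, 2.0)
    cue_kappas: tuple = (50.0, 5.0)
    n_cue_segments: int = 5
    target_radius_cm: float = 7.0
    target_diameter_deg: float = 15.0
    delay_range_s: tuple = (0.8, 1.0)
    bin_width_s: float = 0.010
    epoch_window_s: tuple = (-0.5, 1.5)

    def validate(self):
        errs = []
        if not (self.cue_kappas[0] > 0 and self.cue_kappas[1] > 0):
            errs.append("cue kappas must be positive")
        if not (self.prior_kappas[0] > 0 and self.prior_kappas[1] > 0):
            errs.append("prior kappas must be positive")
        if not self.cue_kappas[0] > self.cue_kappas[1]:
            errs.append("narrow cue kappa must exceed broad cue kappa")
        if self.n_cue_segments < 2:
            errs.append("need at least 2 cue segments")
        if self.target_radius_cm <= 0 or self.target_diameter_deg <= 0:
            errs.append("target geometry must be positive")
        lo, hi = self.epoch_window_s
        if not (lo < 0.0 < hi):
            errs.append("epoch window must straddle reward onset (start < 0 < end)")
        n = (hi - lo) / self.bin_width_s
        if abs(n - round(n)) > 1e-9:
            errs.append("epoch window length must be divisible by bin width")
        if errs:
            raise ValueError("invalid TaskConfig: " + "; ".join(errs))

    @property
    def n_epoch_bins(self) -> int:
        lo, hi = self.epoch_window_s
        return int(round((hi - lo) / self.bin_width_s))

    @property
    def success_halfwidth_rad(self) -> float:
        """Angular half-width of the acceptance window at the target ring."""
        return np.deg2rad(self.target_diameter_deg) / 2.0

    def to_dict(self):
        d = dataclasses.asdict(self)
        for k in ("prior_kappas", "cue_kappas", "delay_range_s", "epoch_window_s"):
            d[k] = list(d[k])
        return d

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        for k in ("prior_kappas", "cue_kappas", "delay_range_s", "epoch_window_s"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class Trial:
    """One behavioral trial: events (s from trial start), covariates, outcome."""

    trial_id: int
    true_target: float
    cue_angles: np.ndarray
    cue_condition: str  # 'narrow' | 'broad'
    dispersion: float
    go_cue_time: float
    movement_onset_time: float
    reward_onset_time: float
    reach_endpoint: float
    error_magnitude: float
    success: bool
    rewarded: bool
    withheld: bool
    previous_outcome: int  # +1 / -1
    return_direction: float

    def __post_init__(self):
        self.cue_angles = np.asarray(self.cue_angles, dtype=float)


@dataclass
class GroundTruthWeights:
    """Generative encoding weights for one simulated neuron.

    ``kernels`` maps covariate channel name (reward, vx, vy, ax, ay,
    uncertainty, reward_history, error, return_cos, return_sin) to its
    basis-weight vector.  ``baseline_log_rate`` is log expected count per bin.
    """

    baseline_log_rate: float
    kernels: dict = field(default_factory=dict)

    def to_dict(self):
        return {"baseline_log_rate": float(self.baseline_log_rate),
                "kernels": {k: [float(x) for x in v] for k, v in self.kernels.items()}}

    @classmethod
    def from_dict(cls, d):
        return cls(baseline_log_rate=float(d["baseline_log_rate"]),
                   kernels={k: np.asarray(v, dtype=float) for k, v in d["kernels"].items()})


@dataclass
class Session:
    """Trials + spike events + kinematics + configuration for one recording."""

    config: TaskConfig
    trials: list
    spikes: pd.DataFrame
    kinematics: pd.DataFrame
    neuron_ids: list
    region_labels: dict
    ground_truth: Optional[dict] = None
    meta: dict = field(default_factory=dict)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def trial(self, trial_id) -> Trial:
        for t in self.trials:
            if t.trial_id == trial_id:
                return t
        raise KeyError(f"no trial {trial_id}")

    def spike_times(self, neuron_id, trial_id) -> np.ndarray:
        s = self.spikes
        m = (s["neuron_id"] == neuron_id) & (s["trial_id"] == trial_id)
        return s.loc[m, "spike_time"].to_numpy()

    def trials_df(self) -> pd.DataFrame:
        return _trials_to_frame(self.trials, self.config.n_cue_segments)

    def trial_ids(self, rewarded=None, condition=None):
        ids = []
        for t in self.trials:
            if rewarded is not None and t.rewarded != rewarded:
                continue
            if condition is not None and t.cue_condition != condition:
                continue
            ids.append(t.trial_id)
        return ids


@dataclass
class Violation:
    type_name: str
    field: str
    offender: object
    message: str

    def __str__(self):
        return f"{self.type_name}.{self.field} [{self.offender}]: {self.message}"


def _trials_to_frame(trials, n_cue):
    rows = []
    for t in trials:
        row = {c: getattr(t, c) for c in _TRIAL_SCALAR_COLUMNS}
        for i in range(n_cue):
            row[f"cue_angle_{i}"] = float(t.cue_angles[i])
        rows.append(row)
    cols = _TRIAL_SCALAR_COLUMNS + [f"cue_angle_{i}" for i in range(n_cue)]
    return pd.DataFrame(rows, columns=cols)


def validate_session(session: Session, atol: float = 1e-6):
    """Check every structural invariant; return a list of Violation records.

    Violations are data, not exceptions: an empty list means the session is
    pristine.  Checked per trial: the dispersion field against a recomputed
    max pairwise circular distance of the cue angles, the error magnitude
    against the endpoint-target circular distance, the reward/success/withheld
    logic, and strict event-time ordering.  Checked globally: spike reference
    integrity and spans, and uniform per-trial kinematics grids.
    """
    out = []
    try:
        session.config.validate()
    except ValueError as e:
        out.append(Violation("TaskConfig", "config", "-", str(e)))

    trial_ids = set()
    spans = {}
    for t in session.trials:
        tid = t.trial_id
        trial_ids.add(tid)
        d = circular_dispersion(t.cue_angles)
        if abs(d - t.dispersion) > atol:
            out.append(Violation("Trial", "dispersion", tid,
                                 f"stored {t.dispersion:.6g} != recomputed max pairwise "
                                 f"circular distance {d:.6g}"))
        e = float(circ_dist(t.reach_endpoint, t.true_target))
        if abs(e - t.error_magnitude) > atol:
            out.append(Violation("Trial", "error_magnitude", tid,
                                 f"stored {t.error_magnitude:.6g} != circular distance "
                                 f"endpoint-target {e:.6g}"))
        if t.error_magnitude < 0:
            out.append(Violation("Trial", "error_magnitude", tid, "negative"))
        if t.rewarded and not t.success:
            out.append(Violation("Trial", "rewarded", tid, "rewarded on unsuccessful trial"))
        if t.withheld and t.success and t.rewarded:
            out.append(Violation("Trial", "rewarded", tid, "withheld-reward trial marked rewarded"))
        if not (t.go_cue_time < t.movement_onset_time < t.reward_onset_time):
            out.append(Violation("Trial", "event_times", tid,
                                 "event times not strictly increasing "
                                 f"(go={t.go_cue_time}, move={t.movement_onset_time}, "
                                 f"reward={t.reward_onset_time})"))
        if t.previous_outcome not in (1, -1):
            out.append(Violation("Trial", "previous_outcome", tid, "must be +1 or -1"))

    kin = session.kinematics
    if len(kin):
        for tid, g in kin.groupby("trial_id"):
            if tid not in trial_ids:
                out.append(Violation("Session", "kinematics", tid, "unknown trial_id"))
                continue
            tt = g["time"].to_numpy()
            spans[tid] = (float(tt.min()), float(tt.max()))
            if len(tt) > 2:
                dt = np.diff(tt)
                if dt.min() <= 0 or (dt.max() - dt.min()) > 1e-6:
                    out.append(Violation("Session", "kinematics", tid,
                                         "time grid not uniform/increasing"))

    sp = session.spikes
    if len(sp):
        known_neurons = set(session.neuron_ids)
        bad_n = set(sp["neuron_id"]) - known_neurons
        for nid in sorted(bad_n):
            out.append(Violation("Session", "spikes.neuron_id", nid, "unknown neuron_id"))
        bad_t = set(sp["trial_id"]) - trial_ids
        for tid in sorted(bad_t):
            out.append(Violation("Session", "spikes.trial_id", tid, "unknown trial_id"))
        for tid, g in sp.groupby("trial_id"):
            if tid not in trial_ids:
                continue
            lo, hi = spans.get(tid, (0.0, np.inf))
            st = g["spike_time"].to_numpy()
            if len(st) and (st.min() < lo - atol or st.max() > hi + atol):
                out.append(Violation("Session", "spikes.spike_time", tid,
                                     "spike time outside the trial's recorded span"))

    if session.ground_truth:
        for nid in session.ground_truth:
            if nid not in set(session.neuron_ids):
                out.append(Violation("Session", "ground_truth", nid, "unknown neuron_id"))
    return out


def write_session(session: Session, path) -> None:
    """Write a session directory (session.json + CSV tables).

    The session is validated first; a read-back round-trip reproduces every
    field to full precision (floats are written with shortest round-trip repr).
    """
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    meta = dict(session.meta)
    meta.setdefault("angle_convention",
                    "radians, counterclockwise from the rightmost point, wrapped to (-pi, pi]")
    head = {
        "format_version": 1,
        "config": session.config.to_dict(),
        "neuron_ids": [int(n) for n in session.neuron_ids],
        "region_labels": {str(k): v for k, v in session.region_labels.items()},
        "meta": meta,
    }
    (path / "session.json").write_text(json.dumps(head, indent=2, sort_keys=True))

    session.trials_df().to_csv(path / "trials.csv", index=False)
    sp = session.spikes if len(session.spikes) else pd.DataFrame(columns=SPIKE_COLUMNS)
    sp.to_csv(path / "spikes.csv", index=False, columns=SPIKE_COLUMNS)
    kin = session.kinematics if len(session.kinematics) else pd.DataFrame(columns=KINEMATICS_COLUMNS)
    kin.to_csv(path / "kinematics.csv", index=False, columns=KINEMATICS_COLUMNS)

    if session.ground_truth is not None:
        gt = {str(k): v.to_dict() for k, v in session.ground_truth.items()}
        (path / "ground_truth.json").write_text(json.dumps(gt, indent=2, sort_keys=True))


def read_session(path) -> Session:
    """Read and fully validate a session directory written by write_session.

    All angle fields are normalized to (-pi, pi] on entry.  Raises
    FileNotFoundError for a missing table, ValueError naming the file for a
    malformed row, and SessionValidationError (naming type, field and id) for
    invariant violations.
    """
    path = Path(path)
    for fn in ("session.json", "trials.csv", "spikes.csv", "kinematics.csv"):
        if not (path / fn).exists():
            raise FileNotFoundError(f"missing {fn} in session directory {path}")

    head = json.loads((path / "session.json").read_text())
    config = TaskConfig.from_dict(head["config"])
    neuron_ids = [int(n) for n in head.get("neuron_ids", [])]
    region_labels = {int(k): v for k, v in head.get("region_labels", {}).items()}

    def _read_csv(name, **kw):
        kw.setdefault("float_precision", "round_trip")  # lossless float parse
        try:
            return pd.read_csv(path / name, **kw)
        except Exception as e:  # report file context
            raise ValueError(f"malformed {name}: {e}") from e

    tdf = _read_csv("trials.csv")
    trials = []
    angle_cols = ["true_target", "reach_endpoint", "return_direction"]
    cue_cols = [f"cue_angle_{i}" for i in range(config.n_cue_segments)]
    for i, row in tdf.iterrows():
        try:
            trials.append(Trial(
                trial_id=int(row["trial_id"]),
                true_target=float(wrap_angle(row["true_target"])),
                cue_angles=wrap_angle(np.array([row[c] for c in cue_cols], dtype=float)),
                cue_condition=str(row["cue_condition"]),
                dispersion=float(row["dispersion"]),
                go_cue_time=float(row["go_cue_time"]),
                movement_onset_time=float(row["movement_onset_time"]),
                reward_onset_time=float(row["reward_onset_time"]),
                reach_endpoint=float(wrap_angle(row["reach_endpoint"])),
                error_magnitude=float(row["error_magnitude"]),
                success=_as_bool(row["success"]),
                rewarded=_as_bool(row["rewarded"]),
                withheld=_as_bool(row["withheld"]),
                previous_outcome=int(row["previous_outcome"]),
                return_direction=float(wrap_angle(row["return_direction"])),
            ))
        except (KeyError, TypeError, ValueError) as e:
            raise ValueError(f"malformed trials.csv at data line {i + 2}: {e}") from e

    sdf = _read_csv("spikes.csv")
    if len(sdf):
        sdf = sdf.astype({"neuron_id": int, "trial_id": int, "spike_time": float})
    else:
        sdf = pd.DataFrame(columns=SPIKE_COLUMNS)
    kdf = _read_csv("kinematics.csv")
    if len(kdf):
        kdf = kdf.astype({c: (int if c == "trial_id" else float) for c in KINEMATICS_COLUMNS})
    else:
        kdf = pd.DataFrame(columns=KINEMATICS_COLUMNS)

    ground_truth = None
    if (path / "ground_truth.json").exists():
        raw = json.loads((path / "ground_truth.json").read_text())
        ground_truth = {int(k): GroundTruthWeights.from_dict(v) for k, v in raw.items()}

    session = Session(config=config, trials=trials, spikes=sdf, kinematics=kdf,
                      neuron_ids=neuron_ids, region_labels=region_labels,
                      ground_truth=ground_truth, meta=head.get("meta", {}))
    violations = validate_session(session)
    if violations:
        raise SessionValidationError(violations)
    return session


def _as_bool(x):
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    s = str(x).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    raise ValueError(f"not a boolean: {x!r}")
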