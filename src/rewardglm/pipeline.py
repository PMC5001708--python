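"""End-to-end orchestration: simulate -> PSTH -> design/GLM -> comparison.

``run_all`` drives the whole analysis from one config and one master seed,
writes every stage's output under the output directory, and produces a
machine-readable ``report.json`` (byte-identical across reruns with the same
config and seed) plus a human-readable ``report.md``.

Seed derivation: the master seed S yields the simulator seed S + 11, the
cross-validation split seed S + 23, and the bootstrap seed S + 37.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .compare import run_covariate_battery
from .design import ALL_COVARIATES
from .glm import GlmConfig
from .psth import (compute_psth, match_kinematics, population_normalized_psth,
                   reward_modulation_test)
from .session import Session, TaskConfig, read_session, validate_session, \
    SessionValidationError
from .simulate import (NeuronSpec, SimulationConfig, default_neuron_specs,
                       simulate_session)

logger = logging.getLogger(__name__)

SIM_SEED_OFFSET = 11
CV_SEED_OFFSET = 23
BOOT_SEED_OFFSET = 37


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


@dataclass
class PipelineConfig:
    """One config to drive the full analysis."""

    simulation: SimulationConfig | None = None
    session_path: str | None = None       # analyze an existing session instead
    match_kinematics: bool = True
    psth_alpha: float = 0.05
    covariates: tuple = ALL_COVARIATES
    glm: GlmConfig = field(default_factory=GlmConfig)
    bootstrap_B: int = 1000
    bootstrap_level: float = 0.95
    min_rate_hz: float = 0.5
    seed: int = 0

    def resolve_seeds(self):
        if self.simulation is not None:
            self.simulation.seed = self.seed + SIM_SEED_OFFSET
        self.glm.seed = self.seed + CV_SEED_OFFSET
        return self.seed + BOOT_SEED_OFFSET


def report_latency(session: Session) -> dict:
    """Movement-onset latency (movement onset - go cue) by cue condition."""
    out = {}
    for cond in ("narrow", "broad"):
        lat = np.array([t.movement_onset_time - t.go_cue_time
                        for t in session.trials if t.cue_condition == cond])
        if len(lat):
            sem = float(lat.std(ddof=1) / np.sqrt(len(lat))) if len(lat) > 1 else 0.0
            out[cond] = {"mean_s": float(lat.mean()), "sem_s": sem, "n": int(len(lat))}
    return out


def _behavior_stage(session: Session) -> dict:
    beh = {"n_trials": session.n_trials, "latency": report_latency(session)}
    for cond in ("narrow", "broad"):
        tr = [t for t in session.trials if t.cue_condition == cond]
        if tr:
            beh[f"success_rate_{cond}"] = float(np.mean([t.success for t in tr]))
            beh[f"mean_dispersion_{cond}"] = float(np.mean([t.dispersion for t in tr]))
    beh["rewarded_fraction"] = float(np.mean([t.rewarded for t in session.trials]))
    return beh


def _psth_stage(session: Session, cfg: PipelineConfig, out_dir: Path) -> dict:
    rew_ids = session.trial_ids(rewarded=True)
    unrew_ids = session.trial_ids(rewarded=False)
    if len(rew_ids) < 2 or len(unrew_ids) < 2:
        raise ValueError("need >= 2 trials in each reward condition")
    if cfg.match_kinematics:
        match = match_kinematics(session, rew_ids, unrew_ids)
        rew_ids, unrew_ids = match.rewarded_ids, match.unrewarded_ids
        match_info = {"n_pairs": len(match.pairs),
                      "p_balance": match.p_balance,
                      "p_balance_pre": match.p_balance_pre,
                      "mean_speed_diff": match.mean_speed_diff}
        pd.DataFrame(match.pairs, columns=["rewarded_id", "unrewarded_id"]) \
            .to_csv(out_dir / "matches.csv", index=False)
    else:
        match = type("M", (), {"rewarded_ids": rew_ids,
                               "unrewarded_ids": unrew_ids})()
        match_info = {"n_pairs": min(len(rew_ids), len(unrew_ids)),
                      "matched": False}

    n_neurons = len(session.neuron_ids)
    mod_rows, psths = [], {}
    for nid in session.neuron_ids:
        res = reward_modulation_test(session, nid, match, n_neurons,
                                     alpha=cfg.psth_alpha)
        mod_rows.append({"neuron_id": nid,
                         "region": session.region_labels.get(nid, ""),
                         "direction": res.direction, "p": res.p,
                         "mean_rate_rewarded": res.mean_rate_rewarded,
                         "mean_rate_unrewarded": res.mean_rate_unrewarded})
        psths[nid] = {
            "rewarded": compute_psth(session, nid, rew_ids, condition="rewarded"),
            "unrewarded": compute_psth(session, nid, unrew_ids,
                                       condition="unrewarded"),
        }
    mod_df = pd.DataFrame(mod_rows)
    mod_df.to_csv(out_dir / "modulation_tests.csv", index=False)

    counts = {}
    for region in sorted(set(session.region_labels.values())):
        sub = mod_df[mod_df["region"] == region]
        counts[region] = {
            "n_neurons": int(len(sub)),
            "up_unrewarded": int((sub["direction"] == "up_unrewarded").sum()),
            "up_rewarded": int((sub["direction"] == "up_rewarded").sum()),
        }

    pop = population_normalized_psth(psths)
    pop_df = pd.DataFrame({"time": pop.bin_centers,
                           "rewarded_mean": pop.mean["rewarded"],
                           "rewarded_sem": pop.sem["rewarded"],
                           "unrewarded_mean": pop.mean["unrewarded"],
                           "unrewarded_sem": pop.sem["unrewarded"]})
    pop_df.to_csv(out_dir / "population_psth.csv", index=False)

    post = pop.bin_centers > 0
    return {"matching": match_info, "modulation_counts_by_region": counts,
            "population_unrewarded_minus_rewarded_post_onset": float(
                (pop.mean["unrewarded"][post] - pop.mean["rewarded"][post]).mean())}


def _round_floats(obj, ndigits=10):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    return obj


def run_all(cfg: PipelineConfig, out_dir) -> dict:
    """Run the full pipeline; returns the report dict and writes all outputs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    boot_seed = cfg.resolve_seeds()
    (out_dir / "pipeline_config.yaml").write_text(yaml.safe_dump(config_to_dict(cfg)))

    try:
        if cfg.simulation is not None:
            session = simulate_session(cfg.simulation)
            from .session import write_session
            write_session(session, out_dir / "session")
        elif cfg.session_path:
            session = read_session(cfg.session_path)
        else:
            raise ValueError("config needs either a simulation block or a session_path")
        violations = validate_session(session)
        if violations:
            raise SessionValidationError(violations)
    except Exception as e:
        raise PipelineError("session", e) from e

    report = {"seed": cfg.seed,
              "seeds": {"simulator": cfg.seed + SIM_SEED_OFFSET,
                        "cv_split": cfg.seed + CV_SEED_OFFSET,
                        "bootstrap": boot_seed}}
    try:
        report["behavior"] = _behavior_stage(session)
    except Exception as e:
        raise PipelineError("behavior", e) from e

    try:
        report["psth"] = _psth_stage(session, cfg, out_dir)
    except Exception as e:
        raise PipelineError("psth", e) from e

    try:
        battery = run_covariate_battery(
            session, covariates=cfg.covariates, glm_cfg=cfg.glm,
            B=cfg.bootstrap_B, level=cfg.bootstrap_level, seed=boot_seed,
            min_rate_hz=cfg.min_rate_hz)
        battery.to_frame().to_csv(out_dir / "comparison_results.csv", index=False)
        counts_df = battery.summary_counts(session.region_labels)
        counts_df.to_csv(out_dir / "summary_counts.csv", index=False)
        battery_report = {
            "n_neurons_analyzed": int(battery.full_model.shape[0]),
            "n_neurons_skipped": len(battery.skipped),
            "significant_counts": {
                f"{r.region}:{r.covariate}": int(r.n_significant_2sigma)
                for r in counts_df.itertuples()},
            "mean_relative_pseudo_r2": {
                cov: float(np.nanmean([x.mean for x in battery.results
                                       if x.covariate == cov]))
                for cov in battery.covariates},
            "full_model_pseudo_r2_mean": float(
                battery.full_model["pseudo_r2_mean"].mean())
            if len(battery.full_model) else float("nan"),
        }
        report["battery"] = battery_report
    except Exception as e:
        raise PipelineError("battery", e) from e

    report = _round_floats(report)
    (out_dir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n")
    (out_dir / "report.md").write_text(_render_md(report))
    logger.info("pipeline complete; outputs in %s", out_dir)
    return report


def _render_md(report: dict) -> str:
    beh = report.get("behavior", {})
    lines = ["# Session analysis report", ""]
    lines.append(f"Master seed: {report['seed']}")
    lines.append("")
    lines.append("## Behavior")
    for cond in ("narrow", "broad"):
        sr = beh.get(f"success_rate_{cond}")
        lat = beh.get("latency", {}).get(cond)
        if sr is not None and lat:
            lines.append(f"- {cond} cue: success rate {sr:.3f}, movement-onset "
                         f"latency {1e3 * lat['mean_s']:.1f} +/- "
                         f"{1e3 * lat['sem_s']:.1f} ms (n={lat['n']})")
    lines.append("")
    lines.append("## Reward modulation (PSTH)")
    for region, c in report.get("psth", {}).get(
            "modulation_counts_by_region", {}).items():
        lines.append(f"- {region}: {c['up_unrewarded']}/{c['n_neurons']} up for "
                     f"unrewarded, {c['up_rewarded']}/{c['n_neurons']} up for "
                     "rewarded outcomes")
    lines.append("")
    lines.append("## Covariate battery (2-sigma significant counts)")
    for key, n in report.get("battery", {}).get("significant_counts", {}).items():
        lines.append(f"- {key}: {n}")
    lines.append("")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# config (de)serialization for the CLI

def config_to_dict(cfg: PipelineConfig) -> dict:
    d = {
        "seed": cfg.seed,
        "match_kinematics": cfg.match_kinematics,
        "psth_alpha": cfg.psth_alpha,
        "covariates": list(cfg.covariates),
        "glm": dataclasses.asdict(cfg.glm),
        "bootstrap_B": cfg.bootstrap_B,
        "bootstrap_level": cfg.bootstrap_level,
        "min_rate_hz": cfg.min_rate_hz,
    }
    if cfg.session_path:
        d["session_path"] = str(cfg.session_path)
    if cfg.simulation is not None:
        d["simulation"] = simulation_config_to_dict(cfg.simulation)
    return d


def simulation_config_to_dict(sim: SimulationConfig) -> dict:
    d = dataclasses.asdict(sim)
    d["task"] = sim.task.to_dict()
    d["iti_range_s"] = list(sim.iti_range_s)
    d["neuron_specs"] = [
        {"neuron_id": s.neuron_id, "region": s.region,
         **s.weights.to_dict()} for s in sim.neuron_specs]
    return d


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    """Build a SimulationConfig from a YAML-style dict.

    ``neurons: {n: 20, kind: benchmark}`` expands to the standard population;
    an explicit ``neuron_specs`` list overrides it.
    """
    from .session import GroundTruthWeights
    d = dict(d)
    task = TaskConfig.from_dict(d.pop("task", {}))
    specs = []
    if "neuron_specs" in d:
        for s in d.pop("neuron_specs"):
            specs.append(NeuronSpec(
                neuron_id=int(s["neuron_id"]), region=s["region"],
                weights=GroundTruthWeights.from_dict(s)))
    elif "neurons" in d:
        n = d.pop("neurons")
        specs = default_neuron_specs(int(n.get("n", 10)),
                                     kind=n.get("kind", "benchmark"),
                                     pmd_fraction=float(n.get("pmd_fraction", 0.6)),
                                     baseline_hz=float(n.get("baseline_hz", 20.0)))
    if "iti_range_s" in d:
        d["iti_range_s"] = tuple(d["iti_range_s"])
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    extra = set(d) - known
    if extra:
        raise ValueError(f"unknown simulation config keys: {sorted(extra)}")
    return SimulationConfig(task=task, neuron_specs=specs, **d)


def pipeline_config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    sim = d.pop("simulation", None)
    glm = d.pop("glm", {})
    cfg = PipelineConfig(
        simulation=simulation_config_from_dict(sim) if sim else None,
        session_path=d.pop("session_path", None),
        match_kinematics=bool(d.pop("match_kinematics", True)),
        psth_alpha=float(d.pop("psth_alpha", 0.05)),
        covariates=tuple(d.pop("covariates", ALL_COVARIATES)),
        glm=GlmConfig(**glm),
        bootstrap_B=int(d.pop("bootstrap_B", 1000)),
        bootstrap_level=float(d.pop("bootstrap_level", 0.95)),
        min_rate_hz=float(d.pop("min_rate_hz", 0.5)),
        seed=int(d.pop("seed", 0)),
    )
    if d:
        raise ValueError(f"unknown pipeline config keys: {sorted(d)}")
    return cfg


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        return pipeline_config_from_dict(yaml.safe_load(fh) or {})
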