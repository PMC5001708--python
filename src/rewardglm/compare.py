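"""Nested-model comparison: pseudo-R², bootstrap CIs, and significance calls.

Goodness of fit uses McFadden's pseudo-R² in its deviance-normalized form

    pseudo_R2 = 1 - (LL_sat - LL_model) / (LL_sat - LL_null),

where the saturated model predicts each count exactly and the null model is
an intercept-only fit on the training data; this maps the likelihood ratio
into [0, 1] on the training set (it can go negative out of sample).  The
marginal effect of one covariate group is the relative pseudo-R²

    rel_R2 = 1 - (LL_sat - LL_full) / (LL_sat - LL_partial),

comparing the full model against the partial model refit without that group.
Uncertainty comes from bootstrapping whole trials on each cross-validation
fold's test set; fold CIs are pooled as (min of lower bounds, max of upper
bounds), an implied sigma is read off the pooled 95% interval, and effects
are classified at the 2-sigma / 5-sigma levels by whether mean - k*sigma
stays above zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import ALL_COVARIATES, build_design_matrix
from .glm import (GlmConfig, PoissonEncodingGLM, make_folds,
                  poisson_ll_per_row, poisson_log_likelihood)

logger = logging.getLogger(__name__)

_Z95 = 1.959964  # two-sided 95% normal quantile


def pseudo_r2(counts, model_rates, null_rates, saturated_rates=None) -> float:
    """Deviance-normalized McFadden pseudo-R² on one set of rows.

    Returns NaN (reported as missing) when the null model already saturates
    the data (constant counts), where the ratio is undefined.
    """
    counts = np.asarray(counts, dtype=float)
    sat = counts if saturated_rates is None else np.asarray(saturated_rates, float)
    ll_sat = poisson_log_likelihood(counts, sat)
    ll_model = poisson_log_likelihood(counts, model_rates)
    ll_null = poisson_log_likelihood(counts, null_rates)
    denom = ll_sat - ll_null
    if abs(denom) < 1e-12:
        return np.nan
    return 1.0 - (ll_sat - ll_model) / denom


def relative_pseudo_r2(counts, full_rates, partial_rates,
                       saturated_rates=None) -> float:
    """Relative pseudo-R² of the full model beyond one partial model.

    Reduces exactly to ``pseudo_r2`` when the partial model is the null
    model; negative values mean the full model generalized worse than the
    partial one on these rows.
    """
    return pseudo_r2(counts, full_rates, partial_rates,
                     saturated_rates=saturated_rates)


def bootstrap_ci(statistic, n_trials: int, B: int = 1000, level: float = 0.95,
                 seed: int = 0):
    """Percentile bootstrap CI of a trial-level statistic.

    ``statistic`` maps an array of trial indices (a resample with
    replacement of ``range(n_trials)``) to a scalar; trials are the resampling
    unit so within-trial dependence between bins is preserved.

    Returns (lower, upper); NaN resamples are dropped.
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials to bootstrap")
    rng = np.random.default_rng(seed)
    vals = np.empty(B)
    for b in range(B):
        vals[b] = statistic(rng.integers(0, n_trials, size=n_trials))
    vals = vals[~np.isnan(vals)]
    if not len(vals):
        return (np.nan, np.nan)
    a = 0.5 * (1.0 - level)
    return (float(np.quantile(vals, a)), float(np.quantile(vals, 1.0 - a)))


def pool_and_classify(fold_means, fold_cis, atol: float = 1e-12):
    """Pool per-fold means and CIs into one significance call.

    pooled CI = (min lower, max upper); sigma = CI width / (2 * 1.959964);
    classification is '5sigma' if mean - 5*sigma > 0, else '2sigma' if
    mean - 2*sigma > 0, else 'none'.  NaN folds are dropped.  ``atol`` is a
    numerical floor: an effect whose mean is below it is rounding residue
    (identical full and partial fits differ at ~1e-16) and is never called
    significant.
    """
    means = [m for m in fold_means if not np.isnan(m)]
    cis = [c for c in fold_cis if not (np.isnan(c[0]) or np.isnan(c[1]))]
    if not means or not cis:
        return np.nan, (np.nan, np.nan), "none"
    lo = min(c[0] for c in cis)
    hi = max(c[1] for c in cis)
    mean = float(np.mean(means))
    sigma = (hi - lo) / (2.0 * _Z95)
    if mean <= atol:
        level = "none"
    elif mean - 5.0 * sigma > 0:
        level = "5sigma"
    elif mean - 2.0 * sigma > 0:
        level = "2sigma"
    else:
        level = "none"
    return mean, (float(lo), float(hi)), level


@dataclass
class ComparisonResult:
    """Per-neuron, per-covariate relative pseudo-R² with pooled CI."""

    neuron_id: int
    covariate: str
    mean: float
    ci: tuple
    sigma_level: str                     # 'none' | '2sigma' | '5sigma'
    fold_means: list = field(default_factory=list)
    fold_cis: list = field(default_factory=list)
    bootstrap_samples: list = field(default_factory=list, repr=False)  # audit


@dataclass
class BatteryResult:
    """Full leave-one-covariate-out battery over a population."""

    results: list                        # ComparisonResult rows
    full_model: pd.DataFrame             # per-neuron full-model pseudo-R²
    skipped: list                        # (neuron_id, reason)
    covariates: tuple

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"neuron_id": r.neuron_id, "covariate": r.covariate,
             "mean_relative_pseudo_r2": r.mean, "ci_lower": r.ci[0],
             "ci_upper": r.ci[1], "sigma_level": r.sigma_level}
            for r in self.results])

    def summary_counts(self, region_labels) -> pd.DataFrame:
        """Counts of significant neurons (>= 2 sigma) per region x covariate."""
        rows = []
        regions = sorted(set(region_labels.values()))
        for region in regions:
            nids = {n for n, r in region_labels.items() if r == region}
            for cov in self.covariates:
                n_sig = sum(1 for r in self.results
                            if r.covariate == cov and r.neuron_id in nids
                            and r.sigma_level in ("2sigma", "5sigma"))
                rows.append({"region": region, "covariate": cov,
                             "n_significant_2sigma": n_sig,
                             "n_neurons": len(nids)})
        return pd.DataFrame(rows)


def _per_trial_ll_sums(counts, rates, trial_index):
    """Sum the per-row LL terms within each test trial (bootstrap unit)."""
    ll = poisson_ll_per_row(counts, rates)
    order = np.unique(trial_index)
    return np.array([ll[trial_index == t].sum() for t in order])


def run_covariate_battery(session, neuron_ids=None, covariates=ALL_COVARIATES,
                          glm_cfg: GlmConfig | None = None, B: int = 1000,
                          level: float = 0.95, seed: int = 0,
                          min_rate_hz: float = 0.5,
                          design=None) -> BatteryResult:
    """Fit the full model and all leave-one-covariate-out partials per neuron.

    For every neuron above the minimum-rate gate: split trials into stratified
    halves, fit full / partial / intercept-only models per fold, evaluate
    relative pseudo-R² per covariate on the held-out half, bootstrap a CI by
    resampling test trials, pool the folds, and classify at 2/5 sigma.
    Per-neuron failures are logged and skipped without aborting the battery.
    """
    glm_cfg = glm_cfg or GlmConfig()
    if design is None:
        design = build_design_matrix(session, neuron_ids=neuron_ids,
                                     covariates=covariates)
    if neuron_ids is None:
        neuron_ids = list(session.neuron_ids)
    covariates = tuple(c for c in ALL_COVARIATES if c in covariates)
    rewarded = np.array([t.rewarded for t in session.trials])
    n_bins = design.n_bins_per_trial
    bw = design.bin_width_s

    results, skipped, full_rows = [], [], []
    for nid in neuron_ids:
        counts = design.counts[nid]
        mean_hz = counts.mean() / bw
        if mean_hz < min_rate_hz:
            logger.info("neuron %s: mean rate %.3f spikes/s below %.2f gate; skipped",
                        nid, mean_hz, min_rate_hz)
            skipped.append((nid, f"mean rate {mean_hz:.3f} spikes/s below gate"))
            continue
        try:
            res = _battery_one_neuron(design, session, nid, covariates, glm_cfg,
                                      rewarded, B, level, seed)
        except Exception as e:  # keep the battery alive
            logger.warning("neuron %s: battery failed (%s); skipped", nid, e)
            skipped.append((nid, str(e)))
            continue
        per_cov, full_stats = res
        results.extend(per_cov)
        full_rows.append({"neuron_id": nid, "mean_rate_hz": mean_hz, **full_stats})

    return BatteryResult(results=results,
                         full_model=pd.DataFrame(full_rows),
                         skipped=skipped, covariates=covariates)


def _battery_one_neuron(design, session, nid, covariates, glm_cfg, rewarded,
                        B, level, seed):
    counts_all = design.counts[nid]
    folds = make_folds(design.trial_ids, rewarded, n_folds=glm_cfg.cv_folds,
                       seed=glm_cfg.seed, stratify=glm_cfg.stratify)

    fold_stats = {cov: {"means": [], "cis": [], "boot": []} for cov in covariates}
    full_means, full_cis = [], []
    for i, test_ids in enumerate(folds):
        train_ids = np.concatenate([f for j, f in enumerate(folds) if j != i])
        train_rows = design.rows_for_trials(train_ids)
        test_rows = design.rows_for_trials(test_ids)
        y_test = counts_all[test_rows]
        trial_idx_test = design.trial_index[test_rows]
        n_test_trials = len(test_ids)

        full_model = PoissonEncodingGLM.from_design(design, nid, config=glm_cfg,
                                                    row_subset=train_rows)
        full_fit = full_model.fit()
        full_rates = np.exp(design.X[test_rows] @ full_fit.params)
        null_rate = max(float(counts_all[train_rows].mean()), 1e-12)

        ll_sat_t = _per_trial_ll_sums(y_test, y_test, trial_idx_test)
        ll_full_t = _per_trial_ll_sums(y_test, full_rates, trial_idx_test)
        ll_null_t = _per_trial_ll_sums(y_test, np.full_like(full_rates, null_rate),
                                       trial_idx_test)

        def _stat(num_t, den_t):
            def stat(idx):
                den = den_t[idx].sum()
                if abs(den) < 1e-12:
                    return np.nan
                return 1.0 - num_t[idx].sum() / den
            return stat

        # full-model pseudo-R² vs the intercept-only null
        num_t = ll_sat_t - ll_full_t
        den_t = ll_sat_t - ll_null_t
        full_means.append(_stat(num_t, den_t)(np.arange(n_test_trials)))
        full_cis.append(bootstrap_ci(_stat(num_t, den_t), n_test_trials, B=B,
                                     level=level, seed=seed + 1000 * i))

        # leave-one-out partials, warm-started from the full fit
        for k, cov in enumerate(covariates):
            cols = design.columns_without(cov)
            start = full_fit.params[cols]
            part_fit = PoissonEncodingGLM.from_design(
                design, nid, config=glm_cfg, row_subset=train_rows,
                drop_covariate=cov).fit(start_params=start)
            part_rates = np.exp(design.X[test_rows][:, cols] @ part_fit.params)
            ll_part_t = _per_trial_ll_sums(y_test, part_rates, trial_idx_test)
            num = ll_sat_t - ll_full_t
            den = ll_sat_t - ll_part_t
            st = _stat(num, den)
            fold_stats[cov]["means"].append(st(np.arange(n_test_trials)))
            ci = bootstrap_ci(st, n_test_trials, B=B, level=level,
                              seed=seed + 1000 * i + 7 * (k + 1))
            fold_stats[cov]["cis"].append(ci)

    per_cov = []
    for cov in covariates:
        mean, ci, lev = pool_and_classify(fold_stats[cov]["means"],
                                          fold_stats[cov]["cis"])
        per_cov.append(ComparisonResult(
            neuron_id=nid, covariate=cov, mean=mean, ci=ci, sigma_level=lev,
            fold_means=fold_stats[cov]["means"], fold_cis=fold_stats[cov]["cis"]))
    f_mean, f_ci, f_lev = pool_and_classify(full_means, full_cis)
    full_stats = {"pseudo_r2_mean": f_mean, "pseudo_r2_ci_lower": f_ci[0],
                  "pseudo_r2_ci_upper": f_ci[1], "pseudo_r2_sigma_level": f_lev}
    return per_cov, full_stats
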