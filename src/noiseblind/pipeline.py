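"""End-to-end orchestration: simulate cohorts, fit, compare, summarise.

One root seed spawns per-stage and per-observer child streams through
``numpy.random.SeedSequence``, so a run is reproducible bit-for-bit from
its manifest, including under reordering of observers.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict

import numpy as np
import pandas as pd
from . import comparison, metrics, noise_fit
from .observer import (
    GEN_MEAN_OFFSET,
    GEN_MEAN_SD,
    InternalModelSpec,
    MODEL_REGISTRY,
    NOISE_BLIND,
    OMNISCIENT,
    VARIABILITY_MIXER,
    ObserverNoiseParams,
    simulate_observer,
)
from .task import ExperimentConfig, sample_trial_sequence

__all__ = [
    "PipelineError",
    "GROUP_PARAM_MEANS",
    "GROUP_PARAM_SEMS",
    "sample_cohort_params",
    "run_experiment",
    "run_full_analysis",
    "format_report",
    "neutral_accuracy",
    "simulated_accuracy_drop",
]


class PipelineError(RuntimeError):
    pass


# Group-level noise statistics (degrees): means and SEMs of the fitted
# nC_low, nC_high, nV_med, nV_high across participants.
GROUP_PARAM_MEANS = {"nC_low": 10.10, "nC_high": 3.31, "nV_med": 3.0, "nV_high": 6.8}
GROUP_PARAM_SEMS = {"nC_low": 1.51, "nC_high": 0.39, "nV_med": 0.78, "nV_high": 1.0}
COHORT_N = 20  # per-experiment sample size behind the SEMs


def sample_cohort_params(
    rng: np.random.Generator,
    lower: float = 0.5,
    upper: float = 45.0,
) -> ObserverNoiseParams:
    """Draw one observer's noise parameters from the group distribution.

    Gaussian per parameter with SD = SEM * sqrt(cohort n), clipped to
    [lower, upper] degrees to keep every draw physically meaningful.
    """
    vals = {}
    for name, mean in GROUP_PARAM_MEANS.items():
        sd = GROUP_PARAM_SEMS[name] * np.sqrt(COHORT_N)
        vals[name] = float(np.clip(rng.normal(mean, sd), lower, upper))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # nC ordering can invert in a draw
        return ObserverNoiseParams(**vals)


def _checksum(frame: pd.DataFrame) -> str:
    return hashlib.sha256(frame.to_csv(index=False).encode()).hexdigest()


def run_experiment(
    config: ExperimentConfig,
    model_spec: InternalModelSpec,
    true_params: ObserverNoiseParams | None = None,
    seed: int = 0,
    n_observers: int = 20,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a cohort: trial sequences plus observer responses.

    ``true_params`` fixes every observer's generative noise; when None,
    each observer's parameters are drawn from the group distribution.
    Returns the stacked behavioural records (one participant column) and
    a manifest of seeds, per-observer parameters and checksums.
    """
    config.validate()
    root = np.random.SeedSequence(seed)
    param_ss, *obs_ss = root.spawn(1 + n_observers)
    param_rng = np.random.default_rng(param_ss)

    frames = []
    observer_params = {}
    obs_seeds = {}
    for i, ss in enumerate(obs_ss):
        task_seed, sim_seed = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2)]
        obs_seeds[i] = {"task": task_seed, "sim": sim_seed}
        params = true_params if true_params is not None else sample_cohort_params(param_rng)
        observer_params[i] = params
        trials = sample_trial_sequence(config, task_seed)
        records = simulate_observer(trials, params, model_spec, sim_seed)
        records.insert(0, "participant", i)
        records.insert(0, "experiment", config.experiment_id)
        frames.append(records)
    dataset = pd.concat(frames, ignore_index=True)
    manifest = {
        "config": asdict(config),
        "model": model_spec.name,
        "seed": seed,
        "n_observers": n_observers,
        "observer_seeds": obs_seeds,
        "observer_params": {
            i: {k: v for k, v in asdict(p).items()} for i, p in observer_params.items()
        },
        "checksum": _checksum(dataset),
        "n_rows": len(dataset),
    }
    return dataset, manifest


def run_full_analysis(
    dataset: pd.DataFrame,
    seed: int = 0,
    models: tuple[InternalModelSpec, ...] = (OMNISCIENT, NOISE_BLIND, VARIABILITY_MIXER),
    n_restarts: int = 20,
) -> dict:
    """Fit noise per observer (neutral trials), score the internal-model
    variants on biased trials, and compute the behavioural panels.

    Returns a report dict with noise fits, model scores, pairwise mean
    ΔBIC, the condition summary, and the bias index per condition cell.
    """
    if dataset is None or len(dataset) == 0:
        raise PipelineError("empty dataset: nothing to analyse")
    required = {"participant", "contrast", "variability", "cue_p_cw", "mu_deg", "choice"}
    missing = required - set(dataset.columns)
    if missing:
        raise PipelineError(f"dataset missing column(s): {sorted(missing)}")
    has_biased = (dataset["cue_p_cw"] != 0.5).any()
    neutral = dataset[(dataset["cue_p_cw"] == 0.5) & (dataset["choice"] != 0)]
    if neutral.empty:
        raise PipelineError("dataset has no neutral trials; noise cannot be fitted")

    cfg = noise_fit.OptimizerConfig(n_restarts=n_restarts)
    fits = {}
    fit_rows = []
    for i, (obs_id, sub) in enumerate(neutral.groupby("participant")):
        res = noise_fit.fit_noise_params(
            sub, sub["choice"].to_numpy(), cfg, seed=seed + i
        )
        fits[obs_id] = res.params
        fit_rows.append(
            {
                "participant": obs_id,
                **asdict(res.params),
                "neg_log_lik": res.neg_log_lik,
                "n_trials": res.n_trials,
                "converged": res.converged,
            }
        )
    report: dict = {"noise_fits": pd.DataFrame(fit_rows)}

    if has_biased:
        scores = comparison.compare_models(dataset, fits, list(models))
        report["model_scores"] = scores
        deltas = {}
        names = [m.name for m in models]
        for a in names:
            for b in names:
                if a < b:
                    d = comparison.pairwise_delta_bic(scores, a, b)
                    deltas[f"{a} - {b}"] = float(d["delta_bic"].mean())
        report["mean_delta_bic"] = deltas

        bias_rows = []
        biased = dataset[dataset["cue_p_cw"] != 0.5]
        for (contrast, variability), cell in biased.groupby(["contrast", "variability"]):
            per_obs = []
            for obs_id, sub in cell.groupby("participant"):
                cued_cw = sub[sub["cue_p_cw"] > 0.5]
                cued_ccw = sub[sub["cue_p_cw"] < 0.5]
                if cued_cw.empty or cued_ccw.empty:
                    continue
                try:
                    per_obs.append(
                        metrics.bias_index(cued_cw, cued_ccw).bias_index
                    )
                except ValueError:
                    continue
            if per_obs:
                bias_rows.append(
                    {
                        "contrast": contrast,
                        "variability": variability,
                        "bias_index_mean": float(np.mean(per_obs)),
                        "bias_index_sem": float(np.std(per_obs, ddof=1) / np.sqrt(len(per_obs)))
                        if len(per_obs) > 1
                        else np.nan,
                        "n_observers": len(per_obs),
                    }
                )
        report["bias_index"] = pd.DataFrame(bias_rows)

    report["condition_summary"] = metrics.condition_summary(dataset)
    return report


def format_report(report: dict) -> str:
    """Plain-text rendering of a run_full_analysis report."""
    lines = ["noise fits (per observer):", report["noise_fits"].to_string(index=False), ""]
    if "mean_delta_bic" in report:
        lines.append("mean pairwise ΔBIC (negative favours first-named):")
        for pair, val in report["mean_delta_bic"].items():
            lines.append(f"  {pair}: {val:+.2f}")
        lines.append("")
    if "bias_index" in report and len(report["bias_index"]):
        lines += ["bias index by condition:", report["bias_index"].to_string(index=False), ""]
    lines += ["condition summary:", report["condition_summary"].to_string(index=False)]
    return "\n".join(lines)


def neutral_accuracy(
    sigma: float,
    n: int,
    rng: np.random.Generator,
    offset: float = GEN_MEAN_OFFSET,
    sd: float = GEN_MEAN_SD,
) -> float:
    """Monte-Carlo accuracy of the neutral-trial decision rule.

    mu from the two-component mixture, evidence x = mu + N(0, sigma^2),
    choice = sign(x), correct iff sign(x) = sign(mu).
    """
    category = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    mu = rng.normal(category * offset, sd)
    x = mu + rng.standard_normal(n) * sigma
    return float(np.mean(np.sign(x) == np.sign(mu)))


def simulated_accuracy_drop(
    sigma_baseline: float = 3.31,
    sigma_low_contrast: float = 10.1,
    sigma_high_variability: float = 8.0,
    n: int = 1_000_000,
    seed: int = 0,
) -> dict:
    """Accuracy drop (percentage points) from baseline to the degraded
    conditions at the group-mean total noise levels.

    Returns the three accuracies and the mean of the two drops.
    """
    ss = np.random.SeedSequence(seed).spawn(3)
    acc_base = neutral_accuracy(sigma_baseline, n, np.random.default_rng(ss[0]))
    acc_lowc = neutral_accuracy(sigma_low_contrast, n, np.random.default_rng(ss[1]))
    acc_highv = neutral_accuracy(sigma_high_variability, n, np.random.default_rng(ss[2]))
    drop = 100.0 * (acc_base - 0.5 * (acc_lowc + acc_highv))
    return {
        "accuracy_baseline": acc_base,
        "accuracy_low_contrast": acc_lowc,
        "accuracy_high_variability": acc_highv,
        "mean_drop_pp": drop,
        "n": n,
    }
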