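"""Model comparison on biased-trial choices via BIC.

Noise parameters are fixed from each observer's neutral-trial fit; the
internal-model variants differ only in their evidence densities, hence
in the cue-shifted decision boundary per condition.  No additional
parameters are fitted, so with equal k the BIC ordering equals the
log-likelihood ordering; k is recorded anyway for transparency.

Sign convention for pairwise comparisons: ΔBIC(A − B) negative favours
the first-named model A.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .noise_fit import LIK_FLOOR
from .observer import (
    BayesianObserver,
    InternalModelSpec,
    ObserverNoiseParams,
)

__all__ = ["ModelScore", "loglik_biased", "bic", "compare_models", "pairwise_delta_bic"]


@dataclass
class ModelScore:
    model_name: str
    log_lik: float
    n_trials: int
    k_free: int
    bic: float


def loglik_biased(
    spec: InternalModelSpec,
    params: ObserverNoiseParams,
    trials,
    choices,
    conditions: Iterable[tuple[float, float]] | None = None,
) -> float:
    """Log-likelihood (nats) of biased-trial choices under ``spec``.

    P(CW) = Phi((mu - x*) / sigma_true) where x* is the spec's boundary
    for the trial's cell and cue and sigma_true comes from the fitted
    noise parameters.
    """
    if isinstance(trials, pd.DataFrame):
        mu = trials["mu_deg"].to_numpy(dtype=float)
        contrast = trials["contrast"].to_numpy(dtype=float)
        variability = trials["variability"].to_numpy(dtype=float)
        cue = trials["cue_p_cw"].to_numpy(dtype=float)
    else:
        mu = np.array([t.mu_deg for t in trials], dtype=float)
        contrast = np.array([t.contrast for t in trials], dtype=float)
        variability = np.array([t.variability for t in trials], dtype=float)
        cue = np.array([t.cue_p_cw for t in trials], dtype=float)
    ch = np.asarray(choices, dtype=float)
    if np.any(cue == 0.5):
        raise ValueError(
            "model scoring uses biased trials only; neutral trial present"
        )
    if conditions is None:
        conditions = sorted(set(zip(contrast, variability)))
    obs = BayesianObserver(params, spec, conditions)
    total = 0.0
    for cell in conditions:
        in_cell = (contrast == cell[0]) & (variability == cell[1])
        if not in_cell.any():
            continue
        sigma = obs.true_total_noise(cell)
        for c in np.unique(cue[in_cell]):
            mask = in_cell & (cue == c)
            b = obs.boundary(cell, c)
            z = (mu[mask] - b) / max(sigma, 1e-300)
            p_cw = ndtr(z)
            p_obs = np.where(ch[mask] > 0, p_cw, 1.0 - p_cw)
            total += np.sum(np.log(np.maximum(p_obs, LIK_FLOOR)))
    return float(total)


def bic(log_lik: float, k_free: int, n: int) -> float:
    """Bayesian Information Criterion: -2*logL + k*ln(n)."""
    if n < 1:
        raise ValueError("n must be at least 1")
    return -2.0 * log_lik + k_free * np.log(n)


def compare_models(
    dataset: pd.DataFrame,
    fitted_params_per_observer: Mapping[int, ObserverNoiseParams],
    model_list: Sequence[InternalModelSpec],
    k_free: int = 4,
) -> pd.DataFrame:
    """Score each model on every observer's biased-trial choices.

    ``dataset`` must carry participant, condition, cue, mu_deg and choice
    columns (neutral trials are ignored; opted-out trials are dropped).
    Returns a tidy frame of per-observer ModelScores.
    """
    required = {"participant", "contrast", "variability", "cue_p_cw", "mu_deg", "choice"}
    missing = required - set(dataset.columns)
    if missing:
        raise ValueError(f"dataset missing column(s): {sorted(missing)}")
    observers = sorted(dataset["participant"].unique())
    absent = [int(o) for o in observers if o not in fitted_params_per_observer]
    if absent:
        raise ValueError(f"missing noise fits for observer(s): {absent}")
    rows = []
    for obs_id in observers:
        sub = dataset[
            (dataset["participant"] == obs_id)
            & (dataset["cue_p_cw"] != 0.5)
            & (dataset["choice"] != 0)
        ]
        if sub.empty:
            raise ValueError(f"observer {obs_id} has no biased-trial choices")
        params = fitted_params_per_observer[obs_id]
        for spec in model_list:
            ll = loglik_biased(spec, params, sub, sub["choice"].to_numpy())
            rows.append(
                {
                    "participant": obs_id,
                    "model": spec.name,
                    "log_lik": ll,
                    "n_trials": len(sub),
                    "k_free": k_free,
                    "bic": bic(ll, k_free, len(sub)),
                }
            )
    return pd.DataFrame(rows)


def pairwise_delta_bic(
    scores: pd.DataFrame, first: str, second: str
) -> pd.DataFrame:
    """Per-observer and mean ΔBIC = BIC(first) − BIC(second).

    Negative values favour the first-named model.
    """
    a = scores[scores["model"] == first].set_index("participant")["bic"]
    b = scores[scores["model"] == second].set_index("participant")["bic"]
    delta = (a - b).rename("delta_bic").reset_index()
    delta["first"] = first
    delta["second"] = second
    return delta
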