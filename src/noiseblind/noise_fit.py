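"""Maximum-likelihood estimation of encoding and integration noise.

Noise magnitudes are fitted on neutral-trial choices only: with an
uninformative prior every internal-model variant predicts the same
sign(x) decision rule, so P(CW) = Phi(mu / sigma_cond) and the four
parameters (nC_low, nC_high, nV_med, nV_high; three for 2x2 designs)
are identified by the factorial crossing of contrast and variability.

The original estimation procedure used a genetic algorithm; the
estimate, not the optimizer, is what matters, so a bounded multi-start
quasi-Newton search with an agreement criterion across restarts is used
instead (the GA settings are retained in :class:`OptimizerConfig` for
provenance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr

from .observer import ObserverNoiseParams

__all__ = [
    "IdentifiabilityError",
    "OptimizerConfig",
    "NoiseFitResult",
    "negloglik_neutral",
    "fit_noise_params",
]

LIK_FLOOR = 1e-9  # avoids -inf from rare large-|mu| errors
PARAM_LOWER = 0.0
PARAM_UPPER = 45.0  # beyond this, performance is chance on this task


class IdentifiabilityError(ValueError):
    """The design lacks the cells needed to separate the noise sources."""


@dataclass(frozen=True)
class OptimizerConfig:
    n_restarts: int = 20
    bounds: tuple[float, float] = (PARAM_LOWER, PARAM_UPPER)
    start_low: float = 0.5
    start_high: float = 20.0
    agreement_nats: float = 0.1
    # Provenance: settings of the original genetic-algorithm fit.
    ga_population_size: int = 100
    ga_max_generations: int = 1000


@dataclass
class NoiseFitResult:
    params: ObserverNoiseParams
    neg_log_lik: float
    n_trials: int
    converged: bool
    n_restarts: int
    seed: int | None


def _design_arrays(trials, choices):
    """Extract (mu, contrast, variability, choice) arrays from trials."""
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
    choices = np.asarray(choices, dtype=float)
    if len(choices) != len(mu):
        raise ValueError("trials and choices differ in length")
    if not np.all(np.isin(choices, (-1.0, 1.0))):
        raise ValueError("choices must be +1 (CW) or -1 (CCW)")
    if np.any(cue != 0.5):
        raise ValueError(
            "noise estimation uses neutral trials only; biased trial present"
        )
    return mu, contrast, variability, choices


def _sigma_table(theta, contrast_levels, nonzero_var_levels):
    """Map a parameter vector to sigma per (contrast, variability) cell."""
    int_noise = {0.0: 0.0}
    if len(nonzero_var_levels) == 2:
        nc_low, nc_high, nv_med, nv_high = theta
        int_noise[nonzero_var_levels[0]] = nv_med
        int_noise[nonzero_var_levels[1]] = nv_high
    elif len(nonzero_var_levels) == 1:
        nc_low, nc_high, nv_high = theta
        int_noise[nonzero_var_levels[0]] = nv_high
    else:
        nc_low, nc_high = theta[0], theta[1]
    enc_noise = {contrast_levels[0]: nc_low, contrast_levels[1]: nc_high}
    return enc_noise, int_noise


def negloglik_neutral(
    params: ObserverNoiseParams | np.ndarray,
    trials,
    choices,
) -> float:
    """Negative log-likelihood of neutral-trial choices in nats.

    P(CW) = Phi(mu / sigma_cond); probabilities are floored at 1e-9.
    """
    mu, contrast, variability, ch = _design_arrays(trials, choices)
    contrast_levels = sorted(set(contrast))
    var_levels = sorted(set(variability))
    nonzero = [v for v in var_levels if v > 0]
    if isinstance(params, ObserverNoiseParams):
        theta = [params.nC_low, params.nC_high]
        if len(nonzero) == 2:
            theta += [params.nV_med, params.nV_high]
        elif len(nonzero) == 1:
            theta += [params.nV_high]
    else:
        theta = params
    if len(contrast_levels) == 1:
        # A single contrast level still yields a valid likelihood (both
        # encoding parameters map to the same level).
        contrast_levels = contrast_levels * 2
    enc_noise, int_noise = _sigma_table(theta, contrast_levels, nonzero)
    sigma = np.array(
        [
            np.hypot(enc_noise[c], int_noise[v])
            for c, v in zip(contrast, variability)
        ]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, mu / np.maximum(sigma, 1e-300), np.inf * np.sign(mu))
    p_cw = ndtr(z)
    p_obs = np.where(ch > 0, p_cw, 1.0 - p_cw)
    return float(-np.sum(np.log(np.maximum(p_obs, LIK_FLOOR))))


def _fast_nll_factory(trials, choices):
    """Precompute per-cell |z|-ready arrays for repeated NLL evaluation."""
    mu, contrast, variability, ch = _design_arrays(trials, choices)
    contrast_levels = sorted(set(contrast))
    var_levels = sorted(set(variability))
    nonzero = [v for v in var_levels if v > 0]
    if len(contrast_levels) < 2:
        raise IdentifiabilityError(
            "both contrast levels are needed to separate encoding noise "
            f"(found {contrast_levels})"
        )
    if not nonzero:
        raise IdentifiabilityError(
            "at least one non-zero variability level is needed to estimate "
            "integration noise"
        )
    zero_cells = {
        (c, 0.0) for c, v in zip(contrast, variability) if v == 0.0
    }
    if len(zero_cells) < 2:
        raise IdentifiabilityError(
            "zero-variability trials at both contrast levels are needed to "
            "pin down encoding noise before integration noise"
        )
    # Signed mu: the likelihood only depends on choice * mu per cell.
    signed = mu * ch
    cell_signed = {}
    for ci, c in enumerate(contrast_levels):
        for v in var_levels:
            mask = (contrast == c) & (variability == v)
            if mask.any():
                cell_signed[(ci, v)] = signed[mask]
    n_params = 4 if len(nonzero) == 2 else 3

    def nll(theta):
        enc = {0: theta[0], 1: theta[1]}
        if n_params == 4:
            integ = {0.0: 0.0, nonzero[0]: theta[2], nonzero[1]: theta[3]}
        else:
            integ = {0.0: 0.0, nonzero[0]: theta[2]}
        total = 0.0
        for (ci, v), s in cell_signed.items():
            sigma = np.hypot(enc[ci], integ[v])
            if sigma <= 0:
                p = np.where(s > 0, 1.0, np.where(s < 0, 0.0, 0.5))
            else:
                p = ndtr(s / sigma)
            total -= np.sum(np.log(np.maximum(p, LIK_FLOOR)))
        return total

    return nll, n_params, nonzero, contrast_levels, len(mu)


def fit_noise_params(
    trials,
    choices,
    optimizer_config: OptimizerConfig | None = None,
    seed: int | None = 0,
) -> NoiseFitResult:
    """Fit the noise parameters by bounded multi-start minimisation.

    Starts are drawn uniformly over [start_low, start_high]^k; the fit is
    flagged converged when at least two restarts land within
    ``agreement_nats`` of the best NLL.
    """
    cfg = optimizer_config or OptimizerConfig()
    nll, n_params, nonzero, contrast_levels, n_trials = _fast_nll_factory(
        trials, choices
    )
    rng = np.random.default_rng(seed)
    bounds = [cfg.bounds] * n_params
    starts = rng.uniform(cfg.start_low, cfg.start_high, (cfg.n_restarts, n_params))

    best = None
    finals = []
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        finals.append(res.fun)
        if best is None or res.fun < best.fun:
            best = res
    finals = np.array(finals)
    converged = int(np.sum(finals <= best.fun + cfg.agreement_nats)) >= 2

    theta = best.x
    if n_params == 4:
        params = ObserverNoiseParams(
            nC_low=theta[0], nC_high=theta[1], nV_med=theta[2], nV_high=theta[3]
        )
    else:
        params = ObserverNoiseParams(
            nC_low=theta[0], nC_high=theta[1], nV_high=theta[2]
        )
    return NoiseFitResult(
        params=params,
        neg_log_lik=float(best.fun),
        n_trials=n_trials,
        converged=bool(converged),
        n_restarts=cfg.n_restarts,
        seed=seed,
    )
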