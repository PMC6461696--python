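"""Subsampling observer: averages k of N items, with encoding noise only.

The alternative account of the performance cost of orientation
variability: instead of integration noise, the agent bases its response
on the mean of a random subset of k gratings plus encoding noise.  The
exact choice likelihood averages over all C(N, k) subsets (N <= 8, at
most 70 subsets), which makes maximum-likelihood estimation of k
trivial and exact.

Without variability the subset mean always equals the array mean, so k
is unidentifiable from zero-variability data; ties in the likelihood
are broken toward larger k (the full-averaging null).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .noise_fit import LIK_FLOOR
from .observer import (
    BayesianObserver,
    NOISE_BLIND,
    ObserverNoiseParams,
    build_sign_density,
    decision_boundary,
    make_grid,
)

__all__ = [
    "SubsamplingFit",
    "simulate_subsampler",
    "subsample_choice_probability",
    "fit_k",
]


@dataclass
class SubsamplingFit:
    k_hat: int
    neg_log_lik_per_k: np.ndarray
    n_trials: int


def _subset_means(items: np.ndarray, k: int) -> np.ndarray:
    idx = np.array(list(combinations(range(len(items)), k)))
    return items[idx].mean(axis=1)


def _believed_boundary(cue_p_cw: float, encoding_noise: float, grid=None) -> float:
    """Boundary of an agent whose internal density carries encoding noise
    only (the subsampler has no integration noise to model)."""
    if cue_p_cw == 0.5:
        return 0.0
    if grid is None:
        grid = make_grid()
    dens = build_sign_density(None, encoding_noise, grid)
    return decision_boundary(cue_p_cw, dens)


def simulate_subsampler(
    trials,
    k: int,
    encoding_noise: float,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate the k-of-N subsampling observer over a trial sequence.

    Per trial: draw k items without replacement, add N(0, encoding_noise^2)
    to their mean, and decide by sign (neutral cue) or by the cue-shifted
    boundary of the encoding-only internal density.
    """
    from .task import frame_to_trials

    trial_list = frame_to_trials(trials) if isinstance(trials, pd.DataFrame) else trials
    rng = np.random.default_rng(seed)
    grid = make_grid()
    boundaries: dict[float, float] = {}
    rows = []
    for t in trial_list:
        n_items = len(t.item_orientations)
        if k > n_items:
            raise ValueError(f"k={k} exceeds set size {n_items}")
        chosen = rng.choice(n_items, size=k, replace=False)
        x = float(np.mean(t.item_orientations[chosen])) + rng.normal(0, encoding_noise)
        if t.cue_p_cw not in boundaries:
            boundaries[t.cue_p_cw] = _believed_boundary(
                t.cue_p_cw, encoding_noise, grid
            )
        b = boundaries[t.cue_p_cw]
        choice = 1 if x > b else (-1 if x < b else (1 if rng.random() < 0.5 else -1))
        rows.append(
            {
                "trial_id": t.trial_id,
                "contrast": t.contrast,
                "variability": t.variability,
                "set_size": n_items,
                "cue_p_cw": t.cue_p_cw,
                "mu_deg": t.mu_deg,
                "evidence_x": x,
                "choice": choice,
                "correct": float(choice == np.sign(t.mu_deg)),
            }
        )
    return pd.DataFrame(rows)


def subsample_choice_probability(
    trial,
    k: int,
    encoding_noise: float,
    boundary: float | None = None,
) -> float:
    """Exact P(choose CW) for the k-subsampler on one trial.

    Averages Phi((subset_mean - x*) / encoding_noise) over all C(N, k)
    subsets, enumerated exhaustively.
    """
    items = np.asarray(trial.item_orientations, dtype=float)
    if k > len(items):
        raise ValueError(f"k={k} exceeds set size {len(items)}")
    if boundary is None:
        boundary = _believed_boundary(trial.cue_p_cw, encoding_noise)
    means = _subset_means(items, k)
    if encoding_noise == 0:
        p = np.where(means > boundary, 1.0, np.where(means < boundary, 0.0, 0.5))
    else:
        p = ndtr((means - boundary) / encoding_noise)
    return float(p.mean())


def fit_k(
    trials,
    choices,
    encoding_noise_params: ObserverNoiseParams,
    contrast_levels=(0.15, 0.6),
) -> SubsamplingFit:
    """Maximum-likelihood subset size k on neutral trials.

    Encoding noise per trial comes from the fitted contrast parameters;
    k in 1..N is scored by the exact subset-averaged likelihood.  Ties
    break toward larger k.
    """
    from .task import frame_to_trials

    trial_list = frame_to_trials(trials) if isinstance(trials, pd.DataFrame) else trials
    choices = np.asarray(choices, dtype=float)
    if len(choices) != len(trial_list):
        raise ValueError("trials and choices differ in length")
    if any(t.cue_p_cw != 0.5 for t in trial_list):
        raise ValueError("fit_k uses neutral trials only; biased trial present")
    n_max = max(len(t.item_orientations) for t in trial_list)
    items = np.array(
        [t.item_orientations for t in trial_list if len(t.item_orientations) == n_max]
    )
    enc = np.array(
        [
            encoding_noise_params.encoding_noise(t.contrast, contrast_levels)
            for t in trial_list
            if len(t.item_orientations) == n_max
        ]
    )
    ch = np.array(
        [
            c
            for c, t in zip(choices, trial_list)
            if len(t.item_orientations) == n_max
        ]
    )
    nll = np.zeros(n_max)
    for ki, k in enumerate(range(1, n_max + 1)):
        idx = np.array(list(combinations(range(n_max), k)))
        means = items[:, idx].mean(axis=2)  # (n_trials, C(N,k))
        with np.errstate(divide="ignore", invalid="ignore"):
            z = means / np.maximum(enc[:, None], 1e-300)
        p_cw = ndtr(z).mean(axis=1)
        p_obs = np.where(ch > 0, p_cw, 1.0 - p_cw)
        nll[ki] = -np.sum(np.log(np.maximum(p_obs, LIK_FLOOR)))
    # argmin with ties toward larger k
    best = np.flatnonzero(nll <= nll.min() + 1e-9).max()
    return SubsamplingFit(
        k_hat=int(best + 1), neg_log_lik_per_k=nll, n_trials=len(ch)
    )
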