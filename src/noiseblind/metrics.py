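"""Descriptive behavioural analyses.

Condition summaries (accuracy, confidence, overconfidence, opt-in, RT),
four-parameter logistic psychometric fits, the signal-detection bias
index quantifying cue usage, and the trial-wise choice and confidence
regressions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import curve_fit
from scipy.stats import norm, sem, ttest_1samp

__all__ = [
    "PsychometricFit",
    "BiasIndexResult",
    "FitError",
    "condition_summary",
    "logistic4",
    "fit_psychometric",
    "sdt_criterion",
    "bias_index",
    "choice_glm",
    "confidence_regression",
]


class FitError(RuntimeError):
    """A curve fit failed to converge after restarts."""


@dataclass
class PsychometricFit:
    """Four-parameter logistic fit to binned proportion-CW data.

    P(x) = (A1 - A2) / (1 + exp((x - x0) / dx)) + A2, with x0 the
    inflection point and 1/dx the steepness.
    """

    A1: float
    A2: float
    x0: float
    inv_dx: float
    n_bins: int
    bin_mu: np.ndarray | None = None
    bin_p: np.ndarray | None = None

    def predict(self, x):
        dx = 1.0 / self.inv_dx
        return (self.A1 - self.A2) / (1.0 + np.exp((np.asarray(x) - self.x0) / dx)) + self.A2


@dataclass
class BiasIndexResult:
    c_cw: float
    c_ccw: float
    bias_index: float
    hr_cw: float
    far_cw: float
    hr_ccw: float
    far_ccw: float


def condition_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-cell behavioural summary, aggregated across observers.

    For every (contrast, variability) cell: mean accuracy, confidence,
    overconfidence (confidence − accuracy), opt-in rate, and RT, as
    means ± SEM across observers.  Cells with no trials are flagged with
    n_observers = 0 rather than reported as zero.
    """
    if "participant" not in records.columns:
        records = records.assign(participant=0)
    cells = sorted(
        set(
            zip(
                records["contrast"].astype(float),
                records["variability"].astype(float),
            )
        )
    )
    rows = []
    for contrast, variability in cells:
        cell = records[
            (records["contrast"] == contrast)
            & (records["variability"] == variability)
        ]
        per_obs = []
        for _, sub in cell.groupby("participant"):
            made = sub[sub["choice"] != 0]
            entry = {
                "accuracy": made["correct"].mean() if len(made) else np.nan,
                "confidence": made["confidence"].mean()
                if made["confidence"].notna().any()
                else np.nan,
                "rt_s": sub["rt_s"].mean() if "rt_s" in sub else np.nan,
            }
            optional = sub[sub["is_optional"] == True]  # noqa: E712
            entry["opt_in_rate"] = (
                optional["opted_in"].mean() if len(optional) else np.nan
            )
            entry["overconfidence"] = entry["confidence"] - entry["accuracy"]
            per_obs.append(entry)
        per_obs = pd.DataFrame(per_obs)
        row = {"contrast": contrast, "variability": variability,
               "n_observers": len(per_obs), "n_trials": len(cell)}
        for col in ("accuracy", "confidence", "overconfidence", "opt_in_rate", "rt_s"):
            vals = per_obs[col].dropna() if len(per_obs) else pd.Series(dtype=float)
            row[f"{col}_mean"] = vals.mean() if len(vals) else np.nan
            row[f"{col}_sem"] = sem(vals) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def logistic4(x, a1, a2, x0, dx):
    return (a1 - a2) / (1.0 + np.exp((x - x0) / dx)) + a2


def fit_psychometric(
    mu_values,
    choices,
    n_bins: int = 6,
    max_restarts: int = 10,
    seed: int | None = 0,
) -> PsychometricFit:
    """Least-squares logistic fit to proportion-CW in quantile bins of mu."""
    mu_values = np.asarray(mu_values, dtype=float)
    choices = np.asarray(choices, dtype=float)
    if len(np.unique(mu_values)) < n_bins:
        raise ValueError(
            f"need at least {n_bins} distinct mu values, got "
            f"{len(np.unique(mu_values))}"
        )
    bins = pd.qcut(mu_values, n_bins, duplicates="drop")
    frame = pd.DataFrame({"mu": mu_values, "cw": (choices > 0).astype(float), "bin": bins})
    grouped = frame.groupby("bin", observed=True)
    bin_mu = grouped["mu"].mean().to_numpy()
    bin_p = grouped["cw"].mean().to_numpy()

    rng = np.random.default_rng(seed)
    p0 = np.array([bin_p[0], bin_p[-1], float(np.median(mu_values)), 3.0])
    span = bin_mu[-1] - bin_mu[0]
    # asymptotes stay near the proportion scale, the inflection inside the
    # sampled range, and dx positive (so A1 is the left asymptote)
    bounds = (
        [-0.2, -0.2, bin_mu[0] - span, 1e-3],
        [1.2, 1.2, bin_mu[-1] + span, 10 * span],
    )
    last_err = None
    for attempt in range(max_restarts):
        start = p0 if attempt == 0 else p0 + rng.normal(0, [0.1, 0.1, 2.0, 1.0])
        start = np.clip(start, np.array(bounds[0]) + 1e-6, np.array(bounds[1]) - 1e-6)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    logistic4, bin_mu, bin_p, p0=start, bounds=bounds,
                    maxfev=20000,
                )
            a1, a2, x0, dx = popt
            return PsychometricFit(
                A1=float(a1),
                A2=float(a2),
                x0=float(x0),
                inv_dx=float(1.0 / dx),
                n_bins=len(bin_mu),
                bin_mu=bin_mu,
                bin_p=bin_p,
            )
        except (RuntimeError, ZeroDivisionError) as exc:
            last_err = exc
    raise FitError(
        f"psychometric fit failed after {max_restarts} restarts: {last_err}; "
        f"bin proportions were {np.round(bin_p, 3)}"
    )


def _rate_corrected(n_hits: float, n: float) -> float:
    """Log-linear correction: (hits + 0.5) / (n + 1) keeps rates off 0/1."""
    return (n_hits + 0.5) / (n + 1.0)


def sdt_criterion(hr: float, far: float) -> float:
    """SDT criterion c = -0.5 * [Phi^-1(HR) + Phi^-1(FAR)]."""
    return -0.5 * (norm.ppf(hr) + norm.ppf(far))


def _rates(records: pd.DataFrame) -> tuple[float, float]:
    made = records[records["choice"] != 0]
    stim_cw = made[np.sign(made["mu_deg"]) > 0]
    stim_ccw = made[np.sign(made["mu_deg"]) < 0]
    if stim_cw.empty or stim_ccw.empty:
        raise ValueError(
            "both stimulus categories (CW and CCW realized means) are "
            "required in each cue set"
        )
    hr = _rate_corrected((stim_cw["choice"] > 0).sum(), len(stim_cw))
    far = _rate_corrected((stim_ccw["choice"] > 0).sum(), len(stim_ccw))
    return hr, far


def bias_index(
    records_cued_cw: pd.DataFrame, records_cued_ccw: pd.DataFrame
) -> BiasIndexResult:
    """Cue usage as the criterion difference between opposite cue sets.

    HR is the proportion of CW responses on realized-CW trials and FAR
    the proportion on realized-CCW trials, log-linear-corrected before
    the probit transform.  The index is signed as c_CCW − c_CW so that
    following the cue yields positive values (a CW cue pushes c_CW
    negative under the CW-as-signal coding).
    """
    hr_cw, far_cw = _rates(records_cued_cw)
    hr_ccw, far_ccw = _rates(records_cued_ccw)
    c_cw = sdt_criterion(hr_cw, far_cw)
    c_ccw = sdt_criterion(hr_ccw, far_ccw)
    return BiasIndexResult(
        c_cw=c_cw,
        c_ccw=c_ccw,
        bias_index=c_ccw - c_cw,
        hr_cw=hr_cw,
        far_cw=far_cw,
        hr_ccw=hr_ccw,
        far_ccw=far_ccw,
    )


def _centred_codes(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Contrast/variability as centred binaries: −0.5 low (or zero), +0.5 high."""
    contrast = records["contrast"].to_numpy(dtype=float)
    variability = records["variability"].to_numpy(dtype=float)
    c_code = np.where(contrast == contrast.max(), 0.5, -0.5)
    v_code = np.where(variability > 0, 0.5, -0.5)
    return c_code, v_code


def _group_summary(per_obs: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean, SEM, and one-sample t-test per coefficient."""
    out = []
    for term in per_obs.columns:
        vals = per_obs[term].dropna().to_numpy()
        if len(vals) == 0:
            out.append({"term": term, "mean": np.nan, "sem": np.nan,
                        "t": np.nan, "p": np.nan, "n": 0})
            continue
        if len(vals) > 1:
            t, p = ttest_1samp(vals, 0.0)
            s = sem(vals)
        else:
            t = p = s = np.nan
        out.append({"term": term, "mean": vals.mean(), "sem": s,
                    "t": t, "p": p, "n": len(vals)})
    return pd.DataFrame(out)


def choice_glm(records: pd.DataFrame) -> dict:
    """Trial-wise logistic regression of CW choice.

    Predictors: signed mu, signed cue, and the mu×contrast, mu×variability,
    cue×contrast, cue×variability interactions (centred binary condition
    codes).  Fitted per observer; returns per-observer coefficients and a
    group summary.  Needs both neutral and biased trials.
    """
    if "participant" not in records.columns:
        records = records.assign(participant=0)
    cues = records["cue_p_cw"].unique()
    if not ((cues == 0.5).any() and (cues != 0.5).any()):
        raise ValueError("choice_glm needs both neutral and biased trials")
    rows = {}
    flags = {}
    for obs_id, sub in records.groupby("participant"):
        sub = sub[sub["choice"] != 0]
        mu = sub["mu_deg"].to_numpy(dtype=float)
        cue = np.sign(sub["cue_p_cw"].to_numpy(dtype=float) - 0.5)
        c_code, v_code = _centred_codes(sub)
        X = pd.DataFrame(
            {
                "mu": mu,
                "cue": cue,
                "mu:c": mu * c_code,
                "mu:v": mu * v_code,
                "cue:c": cue * c_code,
                "cue:v": cue * v_code,
            }
        )
        X = sm.add_constant(X)
        y = (sub["choice"].to_numpy() > 0).astype(float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
            rows[obs_id] = fit.params
            flags[obs_id] = not fit.mle_retvals.get("converged", True)
        except Exception as exc:  # separation or singular design
            warnings.warn(
                f"choice GLM failed for observer {obs_id}: {exc}", stacklevel=2
            )
            flags[obs_id] = True
    per_obs = pd.DataFrame(rows).T
    return {
        "per_observer": per_obs,
        "group": _group_summary(per_obs),
        "flagged": flags,
    }


def confidence_regression(records: pd.DataFrame) -> dict:
    """Linear regression of confidence on |mu|, contrast, variability,
    correctness and RT, per observer plus group summary."""
    needed = ["confidence", "rt_s", "mu_deg", "contrast", "variability", "correct"]
    missing = [c for c in needed if c not in records.columns]
    if missing:
        raise ValueError(f"missing predictor column(s): {missing}")
    if "participant" not in records.columns:
        records = records.assign(participant=0)
    rows = {}
    for obs_id, sub in records.groupby("participant"):
        sub = sub[(sub["choice"] != 0) & sub["confidence"].notna() & sub["rt_s"].notna()]
        if sub.empty:
            continue
        c_code, v_code = _centred_codes(sub)
        X = pd.DataFrame(
            {
                "abs_mu": np.abs(sub["mu_deg"].to_numpy(dtype=float)),
                "c": c_code,
                "v": v_code,
                "correct": sub["correct"].to_numpy(dtype=float),
                "rt": sub["rt_s"].to_numpy(dtype=float),
            }
        )
        X = sm.add_constant(X)
        y = sub["confidence"].to_numpy(dtype=float)
        fit = sm.OLS(y, X).fit()
        rows[obs_id] = fit.params
    per_obs = pd.DataFrame(rows).T
    return {"per_observer": per_obs, "group": _group_summary(per_obs)}
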