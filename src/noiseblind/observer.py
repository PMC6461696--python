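"""Bayesian observers for the orientation-averaging task.

The generative model on every trial is x = mu + N(0, sigma_cond^2): the
observer receives a single noisy estimate of the array's mean
orientation, with sigma_cond the total (encoding plus integration) noise
of the condition.  An observer decodes x through *internal* category-
conditioned evidence densities p(x | cat, cond); which densities it has
depends on its internal model of the noise sources:

* omniscient        — one density pair per condition at the true total noise;
* variability-mixer — aware of integration noise but unable to identify the
                      variability level, so it mixes the omniscient density
                      pairs across variability levels (per contrast);
* noise-blind       — ignores integration noise entirely; densities carry
                      encoding noise only.

The same four awareness/identification flags applied to the contrast
(encoding) side generate the full grid of variants.

Because the mean-orientation prior is a Gaussian mixture (components at
±3 deg, SD 8 deg), every density is available in closed form: conditioning
on the generating component gives N(±3, sqrt(8^2 + sigma^2))
(``build_density``), while conditioning on the sign of the realized mean —
the category that feedback rewards, and the one decisions and confidence
use — gives the truncated mixture convolved with the noise kernel
(``build_sign_density``).  The numeric convolution route is retained in
the test suite as an independent oracle.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

__all__ = [
    "GridError",
    "GEN_MEAN_OFFSET",
    "GEN_MEAN_SD",
    "ObserverNoiseParams",
    "InternalModelSpec",
    "EvidenceDensity",
    "OMNISCIENT",
    "VARIABILITY_MIXER",
    "NOISE_BLIND",
    "MODEL_REGISTRY",
    "model_grid",
    "make_grid",
    "total_noise",
    "generative_mu_density",
    "build_density",
    "build_sign_density",
    "mix_densities",
    "internal_densities",
    "posterior_cw",
    "choose_and_confidence",
    "decision_boundary",
    "BayesianObserver",
    "choice_probability",
    "opt_in_decision",
    "simulate_observer",
    "simulate_ensemble_observer",
]

# Generative mixture of mean orientations: components at +/-3 deg, SD 8 deg.
GEN_MEAN_OFFSET = 3.0
GEN_MEAN_SD = 8.0

# Sure-bet option pays off with 75% probability, so a risk-neutral agent
# opts in only above this confidence.
OPT_IN_THRESHOLD = 0.75

# Descriptive response-time stand-in: slower when the posterior is close
# to 0.5, plus multiplicative-style lognormal jitter.  Not a process model.
RT_INTERCEPT_S = 0.4
RT_SLOPE_S = 0.8
RT_NOISE_MEDIAN_S = 0.15
RT_NOISE_SIGMA = 0.4


class GridError(ValueError):
    """The evidence grid cannot support the requested density."""


def make_grid(half_width: float = 60.0, step: float = 0.05) -> np.ndarray:
    """Uniform evidence grid symmetric about zero (default +/-60 deg, 0.05 step)."""
    n = int(round(half_width / step))
    return np.linspace(-half_width, half_width, 2 * n + 1)


@dataclass(frozen=True)
class ObserverNoiseParams:
    """Fitted noise magnitudes in degrees.

    ``nC_low``/``nC_high`` are encoding-noise SDs for the low/high contrast
    level; ``nV_med``/``nV_high`` are integration-noise SDs for the medium/
    high variability level (``nV_med`` is None for 2x2 designs).  Zero
    variability contributes zero integration noise by definition.
    """

    nC_low: float
    nC_high: float
    nV_high: float
    nV_med: float | None = None

    def __post_init__(self) -> None:
        for name in ("nC_low", "nC_high", "nV_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.nV_med is not None and self.nV_med < 0:
            raise ValueError("nV_med must be non-negative")
        if self.nC_low < self.nC_high:
            warnings.warn(
                "nC_low < nC_high: encoding noise is usually larger at low "
                "contrast; check the parameter order",
                stacklevel=2,
            )

    def encoding_noise(
        self, contrast: float, contrast_levels: Sequence[float]
    ) -> float:
        levels = sorted(set(contrast_levels))
        if len(levels) != 2:
            raise ValueError(
                f"expected exactly two contrast levels, got {levels}"
            )
        if contrast == levels[0]:
            return self.nC_low
        if contrast == levels[1]:
            return self.nC_high
        raise ValueError(
            f"unknown contrast level {contrast}; known levels: {levels}"
        )

    def integration_noise(
        self, variability: float, variability_levels: Sequence[float]
    ) -> float:
        if variability == 0:
            return 0.0
        nonzero = sorted(v for v in set(variability_levels) if v > 0)
        if variability not in nonzero:
            raise ValueError(
                f"unknown variability level {variability}; known levels: "
                f"{sorted(set(variability_levels))}"
            )
        if len(nonzero) == 1:
            return self.nV_high
        if len(nonzero) == 2:
            if variability == nonzero[0]:
                if self.nV_med is None:
                    raise ValueError(
                        "nV_med is required for a three-level variability design"
                    )
                return self.nV_med
            return self.nV_high
        raise ValueError(
            f"at most two non-zero variability levels supported, got {nonzero}"
        )


def total_noise(
    params: ObserverNoiseParams,
    condition: tuple[float, float],
    contrast_levels: Sequence[float] = (0.15, 0.6),
    variability_levels: Sequence[float] = (0.0, 4.0, 10.0),
) -> float:
    """Total noise SD for a (contrast, variability) cell.

    Encoding and integration noise combine independently:
    sigma_cond = sqrt(enc^2 + int^2).
    """
    contrast, variability = condition
    enc = params.encoding_noise(contrast, contrast_levels)
    integ = params.integration_noise(variability, variability_levels)
    return float(np.hypot(enc, integ))


@dataclass(frozen=True)
class InternalModelSpec:
    """Flags defining the agent's internal model of the noise sources.

    ``integration_aware``: the internal densities include integration noise.
    ``variability_identified``: the agent knows the trial's variability level
    (otherwise it mixes densities across levels).  The two ``encoding``/
    ``contrast`` flags act symmetrically on the encoding side.  Flags that
    are irrelevant (identification without awareness) are canonicalised to
    False so that equivalent specs compare equal.
    """

    integration_aware: bool
    variability_identified: bool
    encoding_aware: bool = True
    contrast_identified: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        if not self.integration_aware:
            object.__setattr__(self, "variability_identified", False)
        if not self.encoding_aware:
            object.__setattr__(self, "contrast_identified", False)
        if not self.name:
            object.__setattr__(
                self,
                "name",
                "model_i{:d}{:d}_e{:d}{:d}".format(
                    self.integration_aware,
                    self.variability_identified,
                    self.encoding_aware,
                    self.contrast_identified,
                ),
            )


OMNISCIENT = InternalModelSpec(True, True, True, True, name="omniscient")
VARIABILITY_MIXER = InternalModelSpec(True, False, True, True, name="variability_mixer")
NOISE_BLIND = InternalModelSpec(False, False, True, True, name="noise_blind")

MODEL_REGISTRY: dict[str, InternalModelSpec] = {
    m.name: m for m in (OMNISCIENT, VARIABILITY_MIXER, NOISE_BLIND)
}


def model_grid() -> list[InternalModelSpec]:
    """All distinct internal-model variants generated by the flag grid."""
    specs: dict[tuple, InternalModelSpec] = {}
    for flags in itertools.product([True, False], repeat=4):
        spec = InternalModelSpec(*flags)
        key = (
            spec.integration_aware,
            spec.variability_identified,
            spec.encoding_aware,
            spec.contrast_identified,
        )
        specs.setdefault(key, spec)
    return list(specs.values())


@dataclass
class EvidenceDensity:
    """Category-conditioned densities over evidence on a uniform grid."""

    grid: np.ndarray
    density_cw: np.ndarray
    density_ccw: np.ndarray
    condition: tuple[float, float] | None = None

    def validate(self, atol_mass: float = 1e-3, atol_mirror: float = 1e-10) -> None:
        for dens in (self.density_cw, self.density_ccw):
            mass = np.trapezoid(dens, self.grid)
            if abs(mass - 1.0) > atol_mass:
                raise GridError(
                    f"density mass {mass:.6f} deviates from 1 by more than "
                    f"{atol_mass}; widen the evidence grid"
                )
        if np.max(np.abs(self.density_cw - self.density_ccw[::-1])) > atol_mirror:
            raise GridError("densities are not mirror-symmetric about zero")


def generative_mu_density(
    grid: np.ndarray,
    offset: float = GEN_MEAN_OFFSET,
    sd: float = GEN_MEAN_SD,
) -> EvidenceDensity:
    """Category-conditioned densities of the mean orientation itself:
    N(+offset, sd^2) for CW and N(-offset, sd^2) for CCW."""
    dens = EvidenceDensity(
        grid=grid,
        density_cw=_norm_pdf(grid, offset, sd),
        density_ccw=_norm_pdf(grid, -offset, sd),
        condition=None,
    )
    dens.validate()
    return dens


def _norm_pdf(x: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mean) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))


def build_density(
    condition: tuple[float, float] | None,
    sigma_internal: float,
    grid: np.ndarray,
    offset: float = GEN_MEAN_OFFSET,
    sd: float = GEN_MEAN_SD,
) -> EvidenceDensity:
    """Evidence density implied by internal noise ``sigma_internal``.

    Convolving the Gaussian prior over means with a zero-centred Gaussian
    noise kernel is itself Gaussian, so the density is evaluated in closed
    form as N(+/-offset, sd^2 + sigma^2).  sigma_internal = 0 returns the
    generative density (delta kernel).
    """
    if sigma_internal < 0:
        raise ValueError("sigma_internal must be non-negative")
    s = float(np.hypot(sd, sigma_internal))
    dens = EvidenceDensity(
        grid=grid,
        density_cw=_norm_pdf(grid, offset, s),
        density_ccw=_norm_pdf(grid, -offset, s),
        condition=condition,
    )
    dens.validate()
    return dens


def build_sign_density(
    condition: tuple[float, float] | None,
    sigma_internal: float,
    grid: np.ndarray,
    offset: float = GEN_MEAN_OFFSET,
    sd: float = GEN_MEAN_SD,
) -> EvidenceDensity:
    """Evidence density conditioned on the sign of the mean orientation.

    The behaviourally relevant category is whether the realized mean is
    tilted CW or CCW (feedback follows the on-screen mean), so the
    conditional over means is the full ±offset mixture truncated at zero.
    Convolving it with the N(0, sigma^2) noise kernel gives, in closed
    form,

        p(x | CW) = sum_m N(x; m, S^2) * Phi(m_post(x, m) / s_post),

    with m in {+offset, -offset}, S^2 = sd^2 + sigma^2,
    m_post = (x*sd^2 + m*sigma^2) / S^2 and s_post = sd*sigma/S (the
    skew-normal-style tilt of each component).  Posteriors computed from
    these densities equal P(sign(mu) = cat | x), so an observer using
    them at the true noise level is calibrated against feedback.

    For sigma_internal = 0 the density is the truncated mixture itself,
    with the jump at zero represented by its midpoint value on the grid.
    """
    if sigma_internal < 0:
        raise ValueError("sigma_internal must be non-negative")
    S = float(np.hypot(sd, sigma_internal))
    mix = 0.5 * (_norm_pdf(grid, offset, sd) + _norm_pdf(grid, -offset, sd))
    if sigma_internal == 0:
        cw = np.where(grid > 0, 2.0 * mix, 0.0)
        cw[grid == 0] = mix[grid == 0]  # midpoint of the jump
    else:
        s_post = sd * sigma_internal / S
        cw = np.zeros_like(grid)
        for m in (offset, -offset):
            m_post = (grid * sd**2 + m * sigma_internal**2) / S**2
            cw += _norm_pdf(grid, m, S) * ndtr(m_post / s_post)
    dens = EvidenceDensity(
        grid=grid,
        density_cw=cw,
        density_ccw=cw[::-1].copy(),
        condition=condition,
    )
    dens.validate()
    return dens


def mix_densities(
    densities: Sequence[EvidenceDensity],
    weights: Sequence[float] | None = None,
    condition: tuple[float, float] | None = None,
) -> EvidenceDensity:
    """Pointwise mixture of densities sharing one grid."""
    if weights is None:
        weights = np.full(len(densities), 1.0 / len(densities))
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    grid = densities[0].grid
    cw = sum(w * d.density_cw for w, d in zip(weights, densities))
    ccw = sum(w * d.density_ccw for w, d in zip(weights, densities))
    return EvidenceDensity(grid=grid, density_cw=cw, density_ccw=ccw, condition=condition)


def _design_levels(conditions, contrast_levels=None, variability_levels=None):
    """Resolve the design's contrast/variability levels for a condition set.

    When only one contrast level is present (single-cell use) and it is
    one of the canonical levels, fall back to the canonical (0.15, 0.6)
    pair so encoding noise can still be classified low vs high.
    """
    cls = (
        sorted({c for c, _ in conditions})
        if contrast_levels is None
        else sorted(contrast_levels)
    )
    vls = (
        sorted({v for _, v in conditions})
        if variability_levels is None
        else sorted(variability_levels)
    )
    if len(cls) < 2 and set(cls) <= {0.15, 0.6}:
        cls = [0.15, 0.6]
    return cls, vls


def internal_densities(
    spec: InternalModelSpec,
    params: ObserverNoiseParams,
    conditions: Iterable[tuple[float, float]],
    grid: np.ndarray | None = None,
    offset: float = GEN_MEAN_OFFSET,
    sd: float = GEN_MEAN_SD,
    conditioning: str = "sign",
    contrast_levels: Sequence[float] | None = None,
    variability_levels: Sequence[float] | None = None,
) -> dict[tuple[float, float], EvidenceDensity]:
    """Internal evidence densities for every condition cell under ``spec``.

    An unaware noise source contributes zero sigma; an aware but
    unidentified source is marginalised by an equal-weight mixture over
    its levels (conditions are equifrequent by design).

    ``conditioning`` selects the category semantics: "sign" (default)
    conditions on the sign of the mean orientation, the category that
    feedback rewards, and is what decision and confidence computations
    use; "component" conditions on the generating mixture component,
    giving the closed-form Gaussian pair N(±offset, sd^2 + sigma^2).
    """
    if conditioning not in ("sign", "component"):
        raise ValueError("conditioning must be 'sign' or 'component'")
    builder = build_sign_density if conditioning == "sign" else build_density
    conditions = list(conditions)
    contrast_levels, variability_levels = _design_levels(
        conditions, contrast_levels, variability_levels
    )
    out: dict[tuple[float, float], EvidenceDensity] = {}
    if grid is None:
        grid = make_grid()
    for cell in conditions:
        contrast, variability = cell
        if not spec.encoding_aware:
            enc_sigmas = [0.0]
        elif spec.contrast_identified:
            enc_sigmas = [params.encoding_noise(contrast, contrast_levels)]
        else:
            enc_sigmas = [
                params.encoding_noise(c, contrast_levels) for c in contrast_levels
            ]
        if not spec.integration_aware:
            int_sigmas = [0.0]
        elif spec.variability_identified:
            int_sigmas = [params.integration_noise(variability, variability_levels)]
        else:
            int_sigmas = [
                params.integration_noise(v, variability_levels)
                for v in variability_levels
            ]
        components = [
            builder(cell, float(np.hypot(e, i)), grid, offset, sd)
            for e, i in itertools.product(enc_sigmas, int_sigmas)
        ]
        if len(components) == 1:
            dens = components[0]
        else:
            dens = mix_densities(components, condition=cell)
        out[cell] = dens
    return out


def _interp_density(x, grid, values):
    x = np.asarray(x, dtype=float)
    if np.any(x < grid[0]) or np.any(x > grid[-1]):
        raise ValueError(
            f"evidence outside the grid [{grid[0]}, {grid[-1]}]; "
            "no extrapolation is performed"
        )
    return np.interp(x, grid, values)


def posterior_cw(x, cue_p_cw: float, density: EvidenceDensity):
    """Posterior probability of CW given evidence x and the cue prior.

    p = L_cw * pi / (L_cw * pi + L_ccw * (1 - pi)) with likelihoods
    linearly interpolated on the density grid.
    """
    if not 0 < cue_p_cw < 1:
        raise ValueError("cue_p_cw must lie strictly between 0 and 1")
    l_cw = _interp_density(x, density.grid, density.density_cw)
    l_ccw = _interp_density(x, density.grid, density.density_ccw)
    num = l_cw * cue_p_cw
    den = num + l_ccw * (1.0 - cue_p_cw)
    with np.errstate(invalid="ignore"):
        p = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
    return float(p) if np.isscalar(x) or np.asarray(x).ndim == 0 else p


def choose_and_confidence(
    x,
    cue_p_cw: float,
    density: EvidenceDensity,
    tie_rng: np.random.Generator | None = None,
):
    """Argmax-posterior choice and its posterior probability as confidence.

    Exact posterior ties are broken by a fair coin from ``tie_rng``.
    """
    p = posterior_cw(x, cue_p_cw, density)
    if p > 0.5:
        return 1, p
    if p < 0.5:
        return -1, 1.0 - p
    if tie_rng is None:
        tie_rng = np.random.default_rng()
    return (1 if tie_rng.random() < 0.5 else -1), 0.5


def decision_boundary(cue_p_cw: float, density: EvidenceDensity) -> float:
    """Evidence value where the posterior equals 0.5.

    For a neutral cue the mirror symmetry of the densities puts the
    boundary exactly at zero; otherwise the root of
    pi * L_cw(x) - (1 - pi) * L_ccw(x) is bracketed on the grid and
    polished with Brent's method.  Unique because the likelihood ratio of
    (mixtures of) mirrored equal-variance Gaussians is monotone.
    """
    if cue_p_cw == 0.5:
        return 0.0
    grid = density.grid
    g = cue_p_cw * density.density_cw - (1.0 - cue_p_cw) * density.density_ccw
    sign = np.sign(g)
    flips = np.nonzero(np.diff(sign) != 0)[0]
    if len(flips) == 0:
        raise ValueError(
            "posterior never crosses 0.5 on the evidence grid; the cue is "
            "too extreme for this density or the grid is too narrow"
        )
    i = flips[0]
    f = lambda x: (
        cue_p_cw * np.interp(x, grid, density.density_cw)
        - (1.0 - cue_p_cw) * np.interp(x, grid, density.density_ccw)
    )
    return float(brentq(f, grid[i], grid[i + 1], xtol=1e-12))


class BayesianObserver:
    """An internal-model spec bound to noise parameters and a condition set.

    Caches the internal densities and the per-(cell, cue) decision
    boundaries, which fully determine choices; confidence additionally
    uses the posterior at the realized evidence.
    """

    def __init__(
        self,
        params: ObserverNoiseParams,
        spec: InternalModelSpec,
        conditions: Iterable[tuple[float, float]],
        grid: np.ndarray | None = None,
        offset: float = GEN_MEAN_OFFSET,
        sd: float = GEN_MEAN_SD,
        conditioning: str = "sign",
        contrast_levels: Sequence[float] | None = None,
        variability_levels: Sequence[float] | None = None,
    ):
        self.params = params
        self.spec = spec
        self.conditioning = conditioning
        self.conditions = list(conditions)
        self.offset = offset
        self.sd = sd
        self.contrast_levels, self.variability_levels = _design_levels(
            self.conditions, contrast_levels, variability_levels
        )
        if grid is None:
            # Default +/-60 deg grid, widened when large fitted noise would
            # otherwise lose density mass at the edges.
            sigma_max = max(
                total_noise(
                    params, cell, self.contrast_levels, self.variability_levels
                )
                for cell in self.conditions
            )
            half_width = max(60.0, np.ceil(offset + 6.5 * np.hypot(sd, sigma_max)))
            grid = make_grid(half_width)
        self.grid = grid
        self.densities = internal_densities(
            spec, params, self.conditions, self.grid, offset, sd, conditioning,
            self.contrast_levels, self.variability_levels,
        )
        self._boundaries: dict[tuple, float] = {}

    def density(self, condition) -> EvidenceDensity:
        return self.densities[tuple(condition)]

    def boundary(self, condition, cue_p_cw: float) -> float:
        key = (tuple(condition), cue_p_cw)
        if key not in self._boundaries:
            try:
                b = decision_boundary(cue_p_cw, self.density(condition))
            except ValueError:
                # With very large fitted noise the crossing lies beyond the
                # working grid; rebuild the cell's density on progressively
                # wider grids (a finite crossing always exists because the
                # widest Gaussian component dominates the tails).
                b = None
                hw = float(self.grid[-1])
                while b is None and hw < 1e5:
                    hw *= 4
                    wide = make_grid(hw, step=hw / 1200)
                    dens = internal_densities(
                        self.spec, self.params, self.conditions, wide,
                        self.offset, self.sd, self.conditioning,
                        self.contrast_levels, self.variability_levels,
                    )[tuple(condition)]
                    try:
                        b = decision_boundary(cue_p_cw, dens)
                    except ValueError:
                        continue
                if b is None:
                    raise
            self._boundaries[key] = b
        return self._boundaries[key]

    def true_total_noise(self, condition) -> float:
        return total_noise(
            self.params, condition, self.contrast_levels, self.variability_levels
        )

    def choice_probability(self, mu: float, condition, cue_p_cw: float) -> float:
        """P(choose CW) marginalised over the evidence distribution:
        Phi((mu - x*) / sigma_true)."""
        sigma = self.true_total_noise(condition)
        b = self.boundary(condition, cue_p_cw)
        if sigma == 0:
            return float(mu > b) if mu != b else 0.5
        return float(ndtr((mu - b) / sigma))


def choice_probability(
    trial,
    params: ObserverNoiseParams,
    spec: InternalModelSpec,
    cue_p_cw: float | None = None,
    conditions: Iterable[tuple[float, float]] | None = None,
    grid: np.ndarray | None = None,
) -> float:
    """Probability of a CW response on one trial.

    Evidence is generated at the trial's *true* total noise; the decision
    boundary comes from the spec's internal model.  ``conditions`` defaults
    to the full 2x3 cell set implied by the standard design.
    """
    if conditions is None:
        conditions = [
            (c, v) for c in (0.15, 0.6) for v in (0.0, 4.0, 10.0)
        ]
    obs = BayesianObserver(params, spec, conditions, grid)
    cue = trial.cue_p_cw if cue_p_cw is None else cue_p_cw
    return obs.choice_probability(
        trial.mu_deg, (trial.contrast, trial.variability), cue
    )


def opt_in_decision(confidence: float, threshold: float = OPT_IN_THRESHOLD) -> bool:
    """Opt in iff confidence strictly exceeds the sure-bet reward rate.

    At exact indifference the sure option is taken (opt out).
    """
    if not 0.5 <= confidence <= 1.0:
        raise ValueError("confidence must lie in [0.5, 1]")
    return confidence > threshold


RECORD_COLUMNS = [
    "trial_id",
    "block",
    "contrast",
    "variability",
    "set_size",
    "cue_p_cw",
    "category",
    "mu_deg",
    "is_optional",
    "evidence_x",
    "choice",
    "correct",
    "confidence",
    "opted_in",
    "rt_s",
]


def _trials_frame(trials) -> pd.DataFrame:
    """Accept a list of TrialDesign or an already-tabulated frame."""
    if isinstance(trials, pd.DataFrame):
        return trials
    from .task import trials_to_frame

    frame = trials_to_frame(trials)
    return frame.rename(columns={"trial": "trial_id"})


def simulate_observer(
    trials,
    true_params: ObserverNoiseParams,
    spec: InternalModelSpec,
    seed: int | None = None,
    grid: np.ndarray | None = None,
    round_confidence: bool = True,
) -> pd.DataFrame:
    """Simulate one observer over a trial sequence.

    Evidence x ~ N(mu, sigma_true^2) with sigma_true from the TRUE
    condition cell; choices and confidence come from the spec's internal
    densities.  Correctness follows the sign of the realized mean.  On
    optional trials the agent opts in only when its confidence exceeds
    75%; opted-out trials record no choice, correctness or confidence.
    Reported confidence is rounded to the 1% resolution of the response
    scale (disable with ``round_confidence=False``).

    Evidence draws depend only on the trials and the seed, never on the
    spec, so variants can be compared on identical noise realisations.
    """
    frame = _trials_frame(trials)
    if "trial_id" not in frame.columns and "trial" in frame.columns:
        frame = frame.rename(columns={"trial": "trial_id"})
    n = len(frame)
    rng = np.random.default_rng(seed)
    tie_rng = np.random.default_rng(
        np.random.SeedSequence(seed).spawn(1)[0] if seed is not None else None
    )

    conditions = sorted(
        set(zip(frame["contrast"].to_numpy(), frame["variability"].to_numpy()))
    )
    obs = BayesianObserver(true_params, spec, conditions, grid)

    mu = frame["mu_deg"].to_numpy(dtype=float)
    sigma = np.array(
        [
            obs.true_total_noise(cell)
            for cell in zip(frame["contrast"], frame["variability"])
        ]
    )
    x = mu + rng.standard_normal(n) * sigma

    cues = frame["cue_p_cw"].to_numpy(dtype=float)
    contrast_arr = frame["contrast"].to_numpy(dtype=float)
    variability_arr = frame["variability"].to_numpy(dtype=float)

    boundary = np.empty(n)
    p_cw = np.empty(n)
    for cell in conditions:
        in_cell = (contrast_arr == cell[0]) & (variability_arr == cell[1])
        dens = obs.density(cell)
        for cue in np.unique(cues[in_cell]):
            mask = in_cell & (cues == cue)
            boundary[mask] = obs.boundary(cell, cue)
            # Rare evidence draws beyond the grid edge have a posterior
            # saturated at the edge value; clipping is monotone-consistent.
            p_cw[mask] = posterior_cw(
                np.clip(x[mask], obs.grid[0], obs.grid[-1]), cue, dens
            )

    choice = np.where(x > boundary, 1, -1)
    ties = x == boundary
    if ties.any():
        choice[ties] = np.where(tie_rng.random(ties.sum()) < 0.5, 1, -1)
    conf = np.where(choice == 1, p_cw, 1.0 - p_cw)
    conf = np.clip(conf, 0.5, 1.0)

    correct = (choice == np.sign(mu)).astype(float)
    rt = (
        RT_INTERCEPT_S
        + RT_SLOPE_S * (1.0 - np.abs(p_cw - 0.5) * 2.0)
        + rng.lognormal(np.log(RT_NOISE_MEDIAN_S), RT_NOISE_SIGMA, n)
    )

    reported_conf = np.round(conf * 100) / 100 if round_confidence else conf.copy()

    optional = frame["is_optional"].to_numpy().astype(bool)
    opted_in = np.where(optional, conf > OPT_IN_THRESHOLD, np.nan)
    made_choice = ~optional | (opted_in == 1)

    out = frame.loc[
        :,
        [
            "trial_id",
            "block",
            "contrast",
            "variability",
            "set_size",
            "cue_p_cw",
            "category",
            "mu_deg",
            "is_optional",
        ],
    ].copy()
    out["evidence_x"] = x
    out["choice"] = np.where(made_choice, choice, 0)
    out["correct"] = np.where(made_choice, correct, np.nan)
    out["confidence"] = np.where(made_choice, reported_conf, np.nan)
    out["opted_in"] = opted_in
    out["rt_s"] = rt
    return out


def simulate_ensemble_observer(
    trials,
    item_noise: float,
    seed: int | None = None,
    grid: np.ndarray | None = None,
) -> pd.DataFrame:
    """Observer that perturbs each grating independently and averages.

    Each of the N item orientations receives independent N(0,
    item_noise^2) noise; the evidence is the mean of the perturbed items,
    so its distribution is N(mu, item_noise^2 / N) regardless of the
    orientation variability of the array — which is why this model cannot
    produce a performance cost of variability.  Decisions use a matched
    internal density at sigma = item_noise / sqrt(N).
    """
    if item_noise < 0:
        raise ValueError("item_noise must be non-negative")
    if not isinstance(trials, pd.DataFrame):
        trial_list = trials
    else:
        from .task import frame_to_trials

        trial_list = frame_to_trials(trials)
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = make_grid()
    dens_by_n: dict[int, EvidenceDensity] = {}
    rows = []
    for t in trial_list:
        n_items = len(t.item_orientations)
        noisy = t.item_orientations + rng.standard_normal(n_items) * item_noise
        x = float(np.mean(noisy))
        if n_items not in dens_by_n:
            dens_by_n[n_items] = build_sign_density(
                None, item_noise / np.sqrt(n_items), grid
            )
        x_eval = float(np.clip(x, grid[0], grid[-1]))
        choice, conf = choose_and_confidence(x_eval, t.cue_p_cw, dens_by_n[n_items], rng)
        rows.append(
            {
                "trial_id": t.trial_id,
                "block": t.block,
                "contrast": t.contrast,
                "variability": t.variability,
                "set_size": t.set_size,
                "cue_p_cw": t.cue_p_cw,
                "category": t.category,
                "mu_deg": t.mu_deg,
                "is_optional": t.is_optional,
                "evidence_x": x,
                "choice": choice,
                "correct": float(choice == np.sign(t.mu_deg)),
                "confidence": conf,
                "opted_in": np.nan,
                "rt_s": np.nan,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
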