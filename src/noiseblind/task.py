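"""Synthetic task generation for the orientation-averaging experiments.

Each trial presents an array of N gratings whose orientations have a
prescribed mean (drawn from a two-component Gaussian mixture centred at
±3° with 8° SD) and a prescribed population SD (the variability level).
Contrast and variability are crossed factorially; prior cues, when
present, signal the generating category with 75% validity; opt-out
blocks offer a sure-bet alternative rewarded at 75%.

Trial tables round-trip losslessly through a delimited-text format so
that every downstream stage can run from files as well as from memory.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "TrialTableError",
    "ExperimentConfig",
    "TrialDesign",
    "EXP1_CONFIG",
    "EXP3_CONFIG",
    "EXP6_CONFIG",
    "sample_trial_sequence",
    "sample_array_orientations",
    "trials_to_frame",
    "frame_to_trials",
    "write_trial_table",
    "read_trial_table",
]


class ConfigError(ValueError):
    """An ExperimentConfig violates one of its invariants."""


class TrialTableError(ValueError):
    """A trial-table file does not conform to the expected schema."""


TRIAL_TABLE_COLUMNS = [
    "experiment",
    "participant",
    "block",
    "trial",
    "contrast",
    "variability",
    "set_size",
    "cue_p_cw",
    "category",
    "mu_deg",
    "item_orientations",
    "is_optional",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Design parameters for one experiment.

    Defaults reproduce the Exp1-style design: 1296 trials in 36 blocks,
    two contrast levels crossed with three variability levels, set size
    eight, and half the blocks carrying an informative (75% valid) cue.
    """

    experiment_id: str = "exp1"
    n_trials: int = 1296
    n_blocks: int = 36
    contrast_levels: tuple[float, ...] = (0.15, 0.6)
    variability_levels: tuple[float, ...] = (0.0, 4.0, 10.0)
    set_sizes: tuple[int, ...] = (8,)
    cue_scheme: str = "neutral_and_biased"  # or "none"
    cue_validity: float = 0.75
    opt_out_scheme: str = "none"  # or "half_blocks"
    opt_out_reward_prob: float = 0.75
    generative_mean_offset: float = 3.0
    generative_mean_sd: float = 8.0
    seed: int = 0

    @property
    def n_cells(self) -> int:
        return (
            len(self.contrast_levels)
            * len(self.variability_levels)
            * len(self.set_sizes)
        )

    @property
    def block_size(self) -> int:
        return self.n_trials // self.n_blocks

    def validate(self) -> None:
        if not 0.5 < self.cue_validity <= 1.0:
            raise ConfigError(
                f"cue_validity must lie in (0.5, 1], got {self.cue_validity}"
            )
        if not 0.5 < self.opt_out_reward_prob <= 1.0:
            raise ConfigError(
                "opt_out_reward_prob must lie in (0.5, 1], got "
                f"{self.opt_out_reward_prob}"
            )
        if self.n_trials % self.n_blocks:
            raise ConfigError(
                f"n_trials ({self.n_trials}) not divisible by n_blocks "
                f"({self.n_blocks})"
            )
        if self.n_trials % self.n_cells:
            raise ConfigError(
                f"n_trials ({self.n_trials}) not divisible by the number of "
                f"factorial cells ({self.n_cells})"
            )
        if self.block_size % self.n_cells:
            raise ConfigError(
                f"block size ({self.block_size}) not divisible by the number "
                f"of factorial cells ({self.n_cells}); cells cannot be "
                "balanced within blocks"
            )
        if self.cue_scheme not in ("none", "neutral_and_biased"):
            raise ConfigError(f"unknown cue_scheme {self.cue_scheme!r}")
        if self.opt_out_scheme not in ("none", "half_blocks"):
            raise ConfigError(f"unknown opt_out_scheme {self.opt_out_scheme!r}")
        if self.cue_scheme == "neutral_and_biased" and self.n_blocks % 2:
            raise ConfigError(
                "cue_scheme 'neutral_and_biased' needs an even n_blocks"
            )
        if self.opt_out_scheme == "half_blocks" and self.n_blocks % 2:
            raise ConfigError(
                "opt_out_scheme 'half_blocks' needs an even n_blocks"
            )
        if self.generative_mean_sd <= 0:
            raise ConfigError("generative_mean_sd must be positive")


# Ready-made configurations matching the main experimental designs.
EXP1_CONFIG = ExperimentConfig()
EXP3_CONFIG = ExperimentConfig(
    experiment_id="exp3", cue_scheme="none", opt_out_scheme="half_blocks"
)
# Set size is treated as a within-block factor; 1280 = 32 blocks of 40
# keeps the 2x2x2 cells balanced within every block.
EXP6_CONFIG = ExperimentConfig(
    experiment_id="exp6",
    n_trials=1280,
    n_blocks=32,
    variability_levels=(0.0, 10.0),
    set_sizes=(4, 8),
    cue_scheme="none",
)


@dataclass
class TrialDesign:
    """One task trial: condition cell, cue, stimulus, and category label.

    ``category`` is the mixture component the mean was drawn from; because
    the components overlap, ``sign(mu_deg)`` can disagree with it, and
    correctness feedback follows the realized on-screen mean.
    """

    trial_id: int
    block: int
    contrast: float
    variability: float
    set_size: int
    cue_p_cw: float
    category: int
    mu_deg: float
    item_orientations: np.ndarray
    is_optional: bool = False

    def __post_init__(self) -> None:
        self.item_orientations = np.asarray(self.item_orientations, dtype=float)


def sample_array_orientations(
    mu: float,
    v: float,
    n_items: int,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Draw ``n_items`` orientations with mean exactly ``mu`` and population
    SD exactly ``v``.

    Deviations are sampled as standard normals, centred, and rescaled so
    the realized mean and SD match the nominal values exactly; this keeps
    feedback-by-realized-mean and SD-equated-across-set-sizes literal.
    """
    if v < 0:
        raise ValueError(f"variability must be non-negative, got {v}")
    if n_items < 1:
        raise ValueError("n_items must be at least 1")
    if v == 0:
        return np.full(n_items, float(mu))
    if n_items < 2:
        raise ValueError(
            "a non-zero orientation SD needs at least 2 items "
            f"(got n_items={n_items}, v={v})"
        )
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    while True:
        z = rng.standard_normal(n_items)
        z -= z.mean()
        s = z.std(ddof=0)
        if s > 0:
            break
    return float(mu) + z * (v / s)


def sample_trial_sequence(
    config: ExperimentConfig, seed: int | None = None
) -> list[TrialDesign]:
    """Generate a full trial sequence for one observer.

    Factorial cells are balanced within every block.  Blocks are split
    half-and-half into neutral vs biased (when cued) and forced vs
    optional (when an opt-out scheme is active), with the block order
    shuffled under the sequence seed.  On biased trials the cued
    direction is drawn uniformly and the category matches it with
    probability ``cue_validity``; the mean orientation is then drawn from
    the category's Gaussian.  Means of exactly zero are resampled so that
    correctness (sign of the realized mean) is always defined.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    cells = list(
        itertools.product(
            config.contrast_levels, config.variability_levels, config.set_sizes
        )
    )
    reps_per_block = config.block_size // len(cells)

    # Block-type assignments, shuffled under the sequence seed.
    if config.cue_scheme == "neutral_and_biased":
        cue_blocks = np.array(
            [False] * (config.n_blocks // 2) + [True] * (config.n_blocks // 2)
        )
        rng.shuffle(cue_blocks)
    else:
        cue_blocks = np.zeros(config.n_blocks, dtype=bool)
    if config.opt_out_scheme == "half_blocks":
        optional_blocks = np.array(
            [False] * (config.n_blocks // 2) + [True] * (config.n_blocks // 2)
        )
        rng.shuffle(optional_blocks)
    else:
        optional_blocks = np.zeros(config.n_blocks, dtype=bool)

    trials: list[TrialDesign] = []
    trial_id = 0
    for block in range(config.n_blocks):
        block_cells = cells * reps_per_block
        order = rng.permutation(len(block_cells))
        for idx in order:
            contrast, variability, set_size = block_cells[idx]
            if cue_blocks[block]:
                cue_dir = 1 if rng.random() < 0.5 else -1
                category = (
                    cue_dir if rng.random() < config.cue_validity else -cue_dir
                )
                cue_p_cw = (
                    config.cue_validity
                    if cue_dir == 1
                    else 1.0 - config.cue_validity
                )
            else:
                cue_dir = 0
                category = 1 if rng.random() < 0.5 else -1
                cue_p_cw = 0.5
            mu = 0.0
            while mu == 0.0:
                mu = rng.normal(
                    category * config.generative_mean_offset,
                    config.generative_mean_sd,
                )
            items = sample_array_orientations(mu, variability, set_size, rng)
            trials.append(
                TrialDesign(
                    trial_id=trial_id,
                    block=block,
                    contrast=contrast,
                    variability=variability,
                    set_size=set_size,
                    cue_p_cw=cue_p_cw,
                    category=category,
                    mu_deg=mu,
                    item_orientations=items,
                    is_optional=bool(optional_blocks[block]),
                )
            )
            trial_id += 1
    return trials


def trials_to_frame(
    trials: Sequence[TrialDesign],
    experiment: str = "exp",
    participant: int = 0,
) -> pd.DataFrame:
    """Tabulate trials, serialising item orientations as ';'-joined floats."""
    rows = []
    for t in trials:
        rows.append(
            {
                "experiment": experiment,
                "participant": participant,
                "block": t.block,
                "trial": t.trial_id,
                "contrast": t.contrast,
                "variability": t.variability,
                "set_size": t.set_size,
                "cue_p_cw": t.cue_p_cw,
                "category": t.category,
                "mu_deg": t.mu_deg,
                "item_orientations": ";".join(
                    repr(float(o)) for o in t.item_orientations
                ),
                "is_optional": int(t.is_optional),
            }
        )
    return pd.DataFrame(rows, columns=TRIAL_TABLE_COLUMNS)


def frame_to_trials(frame: pd.DataFrame) -> list[TrialDesign]:
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialTableError(f"missing required column(s): {', '.join(missing)}")
    trials = []
    for pos, (_, row) in enumerate(frame.iterrows()):
        try:
            items = np.array(
                [float(s) for s in str(row["item_orientations"]).split(";")]
            )
            trials.append(
                TrialDesign(
                    trial_id=int(row["trial"]),
                    block=int(row["block"]),
                    contrast=float(row["contrast"]),
                    variability=float(row["variability"]),
                    set_size=int(row["set_size"]),
                    cue_p_cw=float(row["cue_p_cw"]),
                    category=int(row["category"]),
                    mu_deg=float(row["mu_deg"]),
                    item_orientations=items,
                    is_optional=bool(int(row["is_optional"])),
                )
            )
        except (TypeError, ValueError) as exc:
            # +2: header line plus 1-based indexing.
            raise TrialTableError(
                f"malformed trial table row at line {pos + 2}: {exc}"
            ) from exc
    return trials


def write_trial_table(
    trials: Sequence[TrialDesign] | pd.DataFrame,
    path,
    experiment: str = "exp",
    participant: int = 0,
) -> None:
    """Write trials (or an already-tabulated frame) as UTF-8 CSV."""
    if isinstance(trials, pd.DataFrame):
        frame = trials
        missing = [c for c in TRIAL_TABLE_COLUMNS if c not in frame.columns]
        if missing:
            raise TrialTableError(
                f"missing required column(s): {', '.join(missing)}"
            )
    else:
        frame = trials_to_frame(trials, experiment=experiment, participant=participant)
    frame = frame.copy()
    for col in ("contrast", "variability", "cue_p_cw", "mu_deg"):
        # shortest-roundtrip repr guarantees lossless float round trips
        frame[col] = [repr(float(v)) for v in frame[col]]
    frame.to_csv(path, index=False)


def read_trial_table(path, as_frame: bool = False):
    """Read a trial table; returns TrialDesigns, or the raw frame if asked."""
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise TrialTableError(f"cannot parse trial table {path}: {exc}") from exc
    missing = [c for c in TRIAL_TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialTableError(f"missing required column(s): {', '.join(missing)}")
    if as_frame:
        return frame
    return frame_to_trials(frame)
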