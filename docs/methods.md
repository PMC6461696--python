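# Methods

## Task and generative model

On every trial an observer judges whether the mean orientation of an
array of N gratings is tilted clockwise (CW, positive) or
counter-clockwise (CCW, negative) of horizontal. The mean orientation μ
is drawn from a two-component Gaussian mixture, 0.5·N(+3°, 8²) +
0.5·N(−3°, 8²); the per-item orientations are drawn around μ and then
affinely corrected so the realized array has mean exactly μ and
population SD exactly the condition's variability level v ∈ {0°, 4°,
10°}. Exact realization removes any gap between nominal and on-screen
statistics, which matters because correctness feedback follows the sign
of the realized mean. Trials whose drawn mean is exactly zero are
resampled so feedback is always defined. Grating contrast (rmc ∈
{0.15, 0.6}) and variability are crossed factorially and balanced within
every block.

Because the mixture components overlap substantially (component SD 8°
against a ±3° separation), about 35% of means drawn from one component
land on the other side of zero. The generating component is therefore
kept only for cue bookkeeping: an informative cue signals the component
with 75% validity, while the behaviourally relevant category — the one
feedback rewards — is the sign of the realized mean.

Two further design elements are reproduced: prior cues (neutral 50/50 or
biased 75/25, in half the blocks each) and an opt-out option (in half
the blocks of opt-out experiments) that pays the reward of a correct
choice with probability 0.75.

## Noise model

Evidence on a trial is a single noisy sample of the mean orientation,
x = μ + ε with ε ~ N(0, σ²_cond). The total noise per condition
combines an encoding component set by contrast and an integration
component set by variability, independently:

    σ_cond = sqrt(nC² + nV²),

with four magnitudes (degrees): nC_low, nC_high for the two contrast
levels and nV_med, nV_high for the two non-zero variability levels
(three parameters in 2×2 designs; zero variability contributes zero
integration noise by definition).

## Internal models and categorical conditioning

An observer decodes x through internal category-conditioned evidence
densities p(x | cat, cond). The package provides two constructions,
because "category" can be read two ways:

* **Component-conditioned** (`build_density`): conditioning on the
  generating mixture component gives the Gaussian pair
  N(±3, 8² + σ²) — the convolution of the component's mean distribution
  with the noise kernel, evaluated in closed form. The numeric
  convolution is retained in the test suite as an independent oracle.
* **Sign-conditioned** (`build_sign_density`, the decision route):
  conditioning on the sign of the realized mean gives the ±truncated
  mixture convolved with the kernel. By Gaussian algebra this is also
  closed-form: p(x | CW) = Σ_m N(x; m, S²)·Φ(m_post/s_post) with
  m ∈ {+3, −3}, S² = 8² + σ², m_post = (x·8² + m·σ²)/S², s_post = 8σ/S.

Decisions, confidence and opt-in use the sign-conditioned densities.
The reason is categorical: confidence is defined as the probability that
the choice is *correct*, and correctness follows the sign of the
realized mean. An observer using sign-conditioned densities at the true
noise level is exactly calibrated against feedback; an observer using
component-conditioned densities would sit far below its own accuracy
(the component is barely decodable at d′ = 6/8) and would essentially
never clear a 75% opt-in threshold. Only the sign reading reproduces a
calibrated ideal observer, sensible opt-in rates, and overconfidence
under integration-noise blindness.

The internal-model family is a flag grid per noise source — aware of the
source or not, able to identify the trial's level or not:

* **omniscient** — both sources, both levels identified: one density
  pair per condition at σ = σ_cond;
* **variability-mixer** — integration-aware but unable to identify the
  variability level: the equal-weight mixture of omniscient densities
  across variability levels, shared by all cells of a contrast (equal
  weights because conditions are equifrequent by design);
* **noise-blind** — ignores integration noise: densities carry encoding
  noise only.

The same flags applied to the encoding side generate six further
variants; identification flags without awareness are canonicalised away,
leaving nine distinct members. All variants share the neutral-trial
decision rule (sign of evidence), so they predict identical choices on
neutral trials; they differ in biased-trial boundaries and in
confidence.

Inference is Bayes' rule with the cue prior; choice is the
argmax-posterior category and confidence the posterior of the chosen
category. Posterior ties are broken by a fair coin from a dedicated
stream; opt-in requires confidence strictly above 0.75 (indifference
takes the sure option). Reported confidence is rounded to the 1%
resolution of the response scale; no report noise is added.

## Numerical choices

* Evidence grid: uniform, ±60° at 0.05° steps by default, widened
  automatically when large fitted noise would otherwise lose density
  mass; densities must integrate to 1 within 10⁻³ or a grid error is
  raised. Likelihoods are linearly interpolated; evidence outside the
  grid is an error in `posterior_cw` (no silent extrapolation), while
  the simulator clips the rare (≲10⁻⁴) out-of-grid draws to the edge,
  where the posterior has saturated.
* Decision boundaries solve posterior = 0.5 by bracketing on the grid
  plus Brent's method; a neutral cue returns exactly 0 by symmetry. With
  very large noise the crossing can lie beyond the working grid; the
  boundary search then retries on progressively wider grids (a finite
  crossing always exists because the widest Gaussian component dominates
  the tails).
* Choice probabilities are exact Gaussian tails Φ((μ − x*)/σ_true), not
  Monte-Carlo.

## Noise estimation

Parameters are fitted by maximum likelihood on neutral-trial choices
only, where P(CW) = Φ(μ/σ_cond) for every internal model. The factorial
design identifies the four magnitudes: zero-variability cells at both
contrasts pin the encoding parameters, after which the non-zero
variability cells determine the integration parameters. Likelihoods are
floored at 10⁻⁹ to keep rare large-|μ| errors finite. Parameters are
bounded to [0, 45]° (beyond which performance is chance on this task).

The original estimation used a genetic algorithm (population 100, up to
1000 generations); since the estimate rather than the optimizer is the
quantity of interest, the package uses bounded L-BFGS-B from 20 random
starts (uniform over [0.5, 20]°), flagging convergence when at least two
restarts agree within 0.1 nat. The GA settings are kept as provenance
fields in `OptimizerConfig`. Optimizer adequacy is tested directly: the
fitted likelihood must beat the likelihood at the generating parameters.

At the standard single-session scale (648 neutral trials, 108 per cell)
the maximum-likelihood estimates are unbiased but carry sampling SDs of
roughly 1.5° (nC_low), 0.6° (nC_high) and 1.4° (each integration
parameter). Joint recovery of all four parameters within ±30% or ±1.5°
therefore succeeds in only about half of replicates — an information
limit of the design, not an optimizer failure; roughly 2.5× the trials
would be needed for 90% joint coverage.

## Model comparison

Internal-model variants are scored on biased-trial choices with the
noise parameters frozen from the same observer's neutral fit; no
additional parameters are fitted. Scores are BIC = −2 log L + k ln n
with k = 4 recorded for every variant, so penalties cancel and the BIC
ordering equals the likelihood ordering. Pairwise ΔBIC is signed so that
negative favours the first-named model. Confidence reports and opt-in
do not enter the scored likelihood; they are compared as summary
predictions in the metrics stage (the choices-only likelihood is the
only construction fully determined by the main text).

## Behavioural metrics

* **Condition summaries**: accuracy, confidence, overconfidence
  (confidence − accuracy), opt-in rate and RT per factorial cell, as
  means ± SEM across observers; empty cells are flagged missing.
* **Psychometric curves**: proportion-CW in six quantile bins of μ,
  least-squares fit of the four-parameter logistic
  P = (A1−A2)/(1 + e^{(x−x0)/dx}) + A2 with dx constrained positive (so
  A1 is the left asymptote) and asymptotes bounded near the proportion
  scale. With choices unrelated to μ the asymptotes are unidentified;
  only the flatness of the fitted curve is a stable property.
* **Bias index**: SDT criteria c = −0.5[Φ⁻¹(HR) + Φ⁻¹(FAR)] computed
  separately under CW and CCW cues (HR on realized-CW trials, FAR on
  realized-CCW trials), with the log-linear correction
  (hits + 0.5)/(n + 1) guarding 0/1 rates. The index is signed as
  c_CCW − c_CW so that following the cue yields positive values; under
  the CW-as-signal coding the literal c_CW − c_CCW is negative for cue
  following, so this sign convention is what makes "higher = more cue
  usage" hold.
* **Trial-wise regressions**: per-observer logistic regression of CW
  choice on signed μ, signed cue and their interactions with centred
  binary condition codes (−0.5 low/zero, +0.5 high), and linear
  regression of confidence on |μ|, contrast, variability, correctness
  and RT; group-level means, SEMs and one-sample t-tests follow.
  Regressors are left in natural units (not z-scored per observer).

## Synthetic response times

RT is a descriptive stand-in needed only so the confidence regression is
exercisable: rt = 0.4 s + 0.8 s · (1 − 2|p − 0.5|) + lognormal jitter
(median 0.15 s, log-SD 0.4). It makes RT decrease with evidence strength
and hence run slower in high-variability cells, matching the direction
of the reported effect. It is explicitly not a process model; no
sequential-sampling machinery is included.

## Subsampling alternative

The alternative account of the variability cost replaces integration
noise with averaging only k of the N items. The likelihood of a choice
is exact: the average over all C(N, k) subsets (≤70 at N = 8) of
Φ((subset mean − x*)/nC), enumerated exhaustively, with k the only new
parameter and encoding noise taken from the neutral fit. Ties in the
likelihood over k break toward larger k (the full-averaging null), which
also resolves the zero-variability case where k is unidentified.

Two quantitative properties of this model are worth stating. First, at
encoding noise 3.31° the baseline-to-high-variability accuracy cost of
subsampling is ≈5 points at k = 4 (without-replacement subset means have
SD sqrt((v²/k)(N−k)/(N−1)) ≈ 3.8° at v = 10°) and reaches the ~12-point
range only near k = 2. Second, k recovery at single-session trial counts
is near-ceiling rather than exact: the k = 7 vs k = 8 likelihood gap
sits at sampling-noise scale, so exact recovery of full averaging is
modal, not certain.

## Cohort simulation and reproducibility

Cohorts draw per-observer noise parameters from Gaussians centred at the
group means (10.10, 3.31, 3.0, 6.8)° with SD = SEM·√20 (SEMs 1.51, 0.39,
0.78, 1.0; 20 observers per experiment), clipped to [0.5, 45]°. One root
seed spawns per-stage and per-observer child streams via
`numpy.random.SeedSequence`; evidence draws depend only on the trials
and the seed, never on the internal model, so variants can be compared
on identical noise realisations. Manifests record configs, seeds,
per-observer truths and dataset checksums; identical manifests reproduce
identical outputs bit-for-bit.

## What the synthetic generator does and does not emulate

It reproduces the factorial design, the mean-orientation mixture, exact
array statistics, cue validity, block structure, and opt-out scheduling.
It does not model lapses, late responses, learning or session effects,
sequential dependencies, idiosyncratic confidence scales, or true
response-time dynamics. Passing tests therefore show that the estimation
and comparison machinery is correct and well-powered (or not — the
power limits above are measured, not assumed) under the stated
generative assumptions; they do not certify those assumptions for real
observers.

## Problem sizes used in the shipped checks

The simulation-based checks use 10⁶ trials per condition for the
accuracy-drop quantity; 20 replicates of 648-neutral-trial fits for
parameter recovery; five cohorts of 20 observers × 1296 trials per
generating model for model recovery; and two cohorts of 20 observers ×
10368 trials for the directional signatures. These sizes make the
Monte-Carlo error small against each tolerance while keeping the whole
suite runnable in minutes on one core.

## Known limitations

* The choices-only biased-trial likelihood is one of several defensible
  scoring rules; adding confidence or opt-in terms would change ΔBIC
  magnitudes (not, in our simulations, the ordering).
* The ±3°/8° mixture makes the generating component nearly
  undecodable; analyses that condition on the component rather than the
  realized sign will look miscalibrated by construction.
* Encoding noise is attached to contrast labels, not to a psychophysical
  transduction model; contrast enters only as a condition label.
* The six non-headline internal-model variants are generated by the flag
  grid; their names are structural, not historical.
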