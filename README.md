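# noiseblind

Bayesian observer models of *noise blindness*: the failure of human
observers to account for the noise their own cognition adds when
integrating variable pieces of information.

In the orientation-averaging task this package models, observers judge
whether the mean orientation of an array of gratings tilts clockwise
(CW) or counter-clockwise (CCW) of horizontal. Mean orientations are
drawn from the mixture 0.5·N(+3°, 8²) + 0.5·N(−3°, 8²). Two noise
sources are manipulated factorially: **encoding noise** (via grating
contrast) and **integration noise** (via the orientation variability of
the array, SD ∈ {0°, 4°, 10°}). Evidence on a trial is a single noisy
sample x = μ + N(0, σ²_cond) with

    σ_cond = sqrt(nC² + nV²),

where nC is set by the contrast level and nV by the variability level.
Observers decode x through internal category-conditioned evidence
densities p(x | cat, cond) and choose by the cue-weighted posterior. The
model family differs only in the internal densities:

* **omniscient** — both noise sources, condition identified: calibrated;
* **variability-mixer** — integration-aware but mixes densities across
  variability levels;
* **noise-blind** — densities carry encoding noise only: overconfident
  and cue-neglecting exactly when variability is high.

The package is aimed at computational psychophysicists who want to
simulate this task, fit the noise decomposition by maximum likelihood on
neutral-trial choices, compare internal models by BIC on biased-trial
choices, compute the behavioural signatures (SDT bias index,
psychometric fits, overconfidence, opt-in rates, trial-wise
regressions), and test the subsampling alternative (averaging k of N
items) with an exact subset-enumeration likelihood.

## Worked example

Simulate a small noise-blind cohort at the group-mean noise magnitudes
and run the full analysis pipeline (noise fits → model comparison →
behavioural panels):

```python
import noiseblind as nb

truth = nb.ObserverNoiseParams(nC_low=10.1, nC_high=3.31, nV_med=3.0, nV_high=6.8)
dataset, manifest = nb.run_experiment(
    nb.EXP1_CONFIG, nb.NOISE_BLIND, truth, seed=7, n_observers=5
)
report = nb.run_full_analysis(dataset, seed=0)
print(nb.format_report(report))
```

Abridged output:

```
mean pairwise ΔBIC (negative favours first-named):
  omniscient - variability_mixer: +12.92
  noise_blind - omniscient: -16.77
  noise_blind - variability_mixer: -3.85

bias index by condition:
 contrast  variability  bias_index_mean  bias_index_sem  n_observers
     0.15          0.0         1.961395        0.158212            5
     0.15         10.0         1.668310        0.148405            5
     0.60          0.0         1.239604        0.132369            5
     0.60         10.0         0.677714        0.123809            5

condition summary (columns abridged):
 contrast  variability  accuracy_mean  confidence_mean  overconfidence_mean
     0.60          0.0       0.890741         0.894046             0.003306
     0.60         10.0       0.784259         0.913861             0.129602
```

Reading the numbers: the cohort was generated noise-blind, and the
noise-blind model wins the comparison (mean ΔBIC −16.8 against the
omniscient model; negative favours the first-named model). The bias
index — the SDT criterion shift between opposite cue conditions, signed
so that larger means more cue usage — *falls* as variability rises
(1.24 → 0.68 at high contrast), the base-rate-neglect signature. And in
the high-variability cell the cohort reports 91% confidence against 78%
accuracy: +13 points of overconfidence, while the zero-variability cell
is calibrated to within half a point.

A command-line interface mirrors the pipeline stages:

```bash
noiseblind simulate --model noise_blind --observers 5 --seed 7 --out cohort.csv
noiseblind fit-noise --trials cohort.csv --out fits.yaml --restarts 20
noiseblind compare-models --trials cohort.csv --fits fits.yaml --out scores.csv
noiseblind report --records cohort.csv
```

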