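# contourpass

A research pipeline for contour-integration psychophysics with external
orientation noise: stimulus generation, a synthetic two-group observer
cohort, double-pass internal-noise estimation, signal-detection and
Bayesian-bootstrap behavioral statistics, and spatial point-pattern
analysis of gaze positions.

## The scientific problem

In a contour-in-noise task, observers detect a straight contour of 12
Gabor elements (mean orientation 60 degrees from horizontal) embedded in a
hexagonal field of 975 randomly oriented Gabors, with no positional cue —
every element sits exactly on the grid. External noise is injected by
tilting half of the contour elements by +delta and half by -delta
(delta in {0, 10, 20, 30, 45, 60} degrees), which preserves the mean
contour orientation exactly while increasing its orientation variance.
Repeating two blocks with an identical stimulus order (the double-pass
paradigm) separates stimulus-driven from internally generated response
variability: the pair (percent agreement p_a between passes, percent
correct p_c) constrains the ratio sigma_i / sigma_e of internal to
external noise, summarized by the log-linear relation

    p_c = m * log10(p_a / 100) + 100

and, quantitatively, by inverting a linear-amplifier observer model whose
two passes share the frozen external noise (decision-variable correlation
rho = 1 / (1 + r^2), r = sigma_i / sigma_e). Gaze positions recorded
during the brief (200 ms) presentations are analyzed as spatial point
patterns: quadrat tests of spatial randomness, inhomogeneous Poisson
models with a log-quadratic intensity and group/noise/stimulus-class
covariates, Ripley's inhomogeneous K with simulation envelopes, variance
ellipses, and pairwise-distance and dispersion summaries.

The package is aimed at researchers who want to exercise or extend this
analysis chain end to end. Because no raw participant data are publicly
deposited for studies of this design, a first-class synthetic-cohort
module generates a full study — two groups (24 vs 32 subjects) with
planted group differences in stimulus-dependent internal noise, template
quality, reaction times, and gaze dispersion — so every downstream stage
is testable and its sensitivity measurable.

## Worked example

```python
import numpy as np
from contourpass import simulate_cohort, analyze_doublepass
from contourpass import gaze as gz

data = simulate_cohort(master_seed=1)          # 56 subjects x 480 trials
res = analyze_doublepass(data.trials)

for (group, level), fit in sorted(res["fits"].items()):
    print(f"{group:>4} {level:>4.0f} deg  m = {fit.m:6.1f} "
          f"[{fit.ci_low:6.1f}, {fit.ci_high:6.1f}]")
for level, cmp in sorted(res["comparisons"].items()):
    print(f"slope difference at {level:.0f} deg: "
          f"t = {cmp['t_ratio']:.2f}, p = {cmp['p']:.3f}")

pattern, excluded = gz.clip_to_window(data.gaze)
dist = gz.group_pairwise_distances(pattern.data)
for group, s in dist.items():
    print(f"{group}: median pairwise gaze distance "
          f"{s['median']:.3f} deg [{s['q1']:.3f} - {s['q3']:.3f}]")
```

Output (seed 1):

```
 ASD   10 deg  m =  121.5 [ 110.6,  132.4]
 ASD   45 deg  m =  145.8 [ 134.2,  157.4]
  TD   10 deg  m =  142.8 [ 112.2,  173.3]
  TD   45 deg  m =  167.0 [ 155.1,  178.8]
slope difference at 10 deg: t = -1.34, p = 0.189
slope difference at 45 deg: t = -2.62, p = 0.011
ASD: median pairwise gaze distance 0.224 deg [0.156 - 0.300]
TD: median pairwise gaze distance 0.138 deg [0.089 - 0.206]
```

The ASD-like group — built with a larger stimulus-dependent internal
noise coefficient — shows a significantly lower agreement/accuracy slope
at the high external-noise level (45 deg) but not at the low one
(10 deg), the signature of stimulus-dependent (multiplicative) rather
than additive internal noise, and a larger spread of mean gaze positions.
(The slope m is meaningful as a comparative index; its absolute scale
depends strongly on where the (p_a, p_c) points sit relative to the
relation's fixed point at (100, 100).)

The full chain — simulation, RT filtering, accuracy/RT bootstrap
summaries, SDT categorization, double-pass fits, gaze point-pattern tests,
correlations, figures — runs as

    contourpass run-all --seed 1 --out-dir results/

writing tidy CSV tables, `results.json`, and summary figures. Individual
stages are available as `simulate`, `design`, `render`,
`analyze-behavior`, `analyze-doublepass`, `analyze-gaze`, and `report`.

## Layout

    src/contourpass/stimulus.py    hex grid, contour, jitter, rendering, design
    src/contourpass/cohort.py      observer model and synthetic cohort
    src/contourpass/doublepass.py  agreement/accuracy, slope fits, LAM inversion
    src/contourpass/behavior.py    RT filter, SDT, Bayesian bootstrap, correlations
    src/contourpass/gaze.py        point patterns: quadrats, ppm, K, ellipses
    src/contourpass/pipeline.py    config, table I/O, orchestration, figures
    src/contourpass/cli.py         command-line interface
    docs/methods.md                models, parameters, numerical choices
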