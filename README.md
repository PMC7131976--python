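# mazepoint

Pointing-error analysis for spatial learning in virtual mazes.

When people learn a maze-like environment and are then asked to point from
one landmark location to another, their directional errors carry two very
different signals. Random scatter around the true direction reflects noisy
but structurally correct survey knowledge. *Systematic* deviations — a
second cluster of judgments aimed somewhere else entirely — suggest a
distorted mental map: a forgotten corridor segment, a mis-remembered leg
length, a sub-route rotated in memory. `mazepoint` implements the full
chain for separating the two and testing a specific distorted-map
hypothesis, for researchers in spatial cognition working with directional
judgment data.

## What it does

- **Maze geometry** — describe a maze intrinsically (leg lengths + signed
  turn angles), realize it as planar coordinates with hedge-wall corridors,
  and compute true target azimuths and absolute angular errors
  (`min(|Δ| mod 360, 360 − |Δ| mod 360)` ∈ [0°, 180°]).
- **2.5-D visibility** — line-of-sight over finite-height hedges,
  visible/non-visible classification of all ordered pointing pairs, and
  isovists (the visible region of a viewpoint; its area fraction is the
  viewpoint's *geographic scale*).
- **Circular statistics** — von Mises mixtures (K ∈ {1, 2}) fitted by EM,
  the density `f(θ) = Σⱼ wⱼ exp(κⱼ cos(θ − μⱼ)) / (2π I₀(κⱼ))`; BIC model
  selection with weight and mode-separation floors decides unimodal vs
  bimodal per pointing trial; bootstrap confidence sectors for mode
  directions; labeling of the systematic (farther-from-correct) mode.
- **Alternative-maze modeling** — distortions as composable route edits
  (delete a leg, rescale a leg, rotate a sub-route), and a per-participant,
  per-session comparison of correct vs distorted layouts by mean pointing
  error over bimodal trials, aggregated into preference percentages by
  group × sense-of-direction level × session.
- **Cohort rules** — Raw TLX workload scoring, Tukey-fence exclusion on
  visible-trial errors (Q3 + 1.5 IQR), median split on sense-of-direction
  scores.
- **Synthetic cohorts** — a generator producing participant cohorts and
  pointing records with exactly the statistical structure the analysis
  assumes, so the entire pipeline is testable without human data.

The packaged nine-location maze is a constrained reconstruction (the
original coordinates are unpublished); see `docs/methods.md` for what is
constrained and what is a repository choice.

## Worked example

```python
from mazepoint import *

layout = reference_layout()                       # packaged reconstruction
pairs = classify_pointing_pairs(layout, GROUND_EYE_HEIGHT)
print(int(pairs.visible.sum()), int((~pairs.visible).sum()))
# 16 56        <- of the 72 ordered pointing trials, 16 are intervisible

# simulate a reference cohort and test one trial for bimodality
alt = alternative_layout(layout.route)            # distorted representation
profiles, records = simulate_cohort(reference_config(), layout, alt, seed=7)
trial = records[(records.origin == 3) & (records.target == 6)
                & ~records.visible]
fit = select_modality(trial.judged_deg.to_numpy(), seed=7, trial=(3, 6))
print(fit.verdict)
for c in fit.components:
    print(f"  weight {c.weight:.2f}  mean {c.mean_deg:.1f}  kappa {c.kappa:.1f}")
# bimodal
#   weight 0.46  mean 129.1  kappa 4.6
#   weight 0.54  mean 44.1   kappa 6.5
```

The trial pools every participant's judged azimuth for "standing at
location 3, point to location 6". The mixture finds two modes: one at
44° — pointing noise around the correct direction (40.2°) — and one at
129°, right where the distorted layout predicts (129.3°). That second,
farther mode is the systematic error:

```python
print(true_direction(layout, 3, 6), true_direction(alt, 3, 6))
# 40.2 129.3
print(label_systematic_mode(fit, true_direction(layout, 3, 6)))
# 0            <- component 0 (the 129 deg mode) is the systematic one
```

Geographic scale shows why the task is hard at ground level:

```python
print(isovist(layout, 4, GROUND_EYE_HEIGHT).scale_ratio)   # 0.038
print(isovist(layout, 4, ELEVATED_EYE_HEIGHT).scale_ratio) # 1.000
```

From 1.4 m the hedges limit location 4's view to under 4% of the
environment; from 5.3 m, everything is visible.

## Command line

```sh
mazepoint run --config study.yaml          # full pipeline, writes a manifest
mazepoint simulate --seed 7 --out-dir run/
mazepoint visibility --eye-height 1.4 --out pairs.csv
mazepoint isovist --location 4 --eye-height 5.3 --out iso.geojson
mazepoint fit-mixtures --records run/pointings.csv --out fits.json
mazepoint compare-models --records run/pointings.csv --fits fits.json \
    --participants run/participants.csv --out comparison.csv
```

A pipeline config is YAML:

```yaml
layout: reference          # or a maze JSON document
simulate: {seed: 7}        # or records: pointings.csv
thresholds: {w_min: 0.15, s_min: 30.0}
out_dir: run1
```

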