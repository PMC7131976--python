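# Methods

`mazepoint` analyzes directional judgments ("point to the Payphone") made
at the nine landmark locations of a hedge-maze virtual environment, and
asks whether the errors in those judgments are noise around the true
direction or the signature of a *distorted* mental map. This note records
the models, the numerical choices, and the reasoning behind the places
where the design was genuinely open.

## Maze model

A maze is described intrinsically: an ordered chain of locations joined by
straight legs, with a signed turn angle (degrees, + = clockwise) at each
interior location. Planar coordinates follow deterministically with
location 1 at the origin and an initial heading due north; this gauge is
arbitrary and none of the analysis outputs depend on it (rotating both
layouts and the judged azimuths together leaves every model-comparison
output unchanged; this is asserted in tests).

The packaged reconstruction has nine locations, seven right-angle turns,
leg lengths (10, 12, 9, 11, 22, 18, 10, 8) m, corridor width 3 m, and
hedge height 2.5 m. The published maze drawing carries no numeric
coordinates, so these lengths are repository constants chosen to satisfy
every constraint the source text states: the two legs between locations 5
and 7 are strictly the longest; leg 6–7 differs from leg 8–9; the route is
orthogonal and non-self-intersecting; and ground-level intervisibility
holds for exactly the route-consecutive location pairs, reproducing the
16 visible / 56 non-visible split of the 72 ordered pointing trials. The
slightly irregular lengths are deliberate: with all-equal legs, diagonal
sightlines between corner locations graze mitred wall corners exactly, an
avoidable degeneracy.

Hedge walls are mitre-joined offset curves of the route centerline at
±1.5 m, capped half a corridor width beyond both ends so the first and
last locations sit inside the corridor. Eye heights are 1.4 m (ground) and
5.3 m (elevated); the 2.5 m hedge sits strictly between them, so hedges
block ground sightlines and clear elevated ones.

Landmarks are vertical columns at the location coordinates. Heights are
tuned constants: 9 m at locations 3 and 7, 1 m elsewhere. The tall set
{3, 7} is forced: requiring that the elevated viewpoint at each of
locations 2, 4, 6 and 8 reveals *exactly one* landmark beyond the
ground-visible set (own plus route-adjacent) has no solution with zero or
one tall landmark, and {3, 7} is the minimal set satisfying all four
constraints at once. Short landmarks must be well below hedge height — a
sightline descending from 5.3 m can still be above 2.5 m at its last wall
crossing if the column is only slightly below the hedge, so 1 m is used.

## Visibility

A sightline between two eye points clears the maze when, at every wall
segment its planar projection crosses, the interpolated sight height
strictly exceeds the wall height. Endpoints exactly on a wall count as
blocked; intersection tests are inclusive at segment endpoints, so grazing
contacts block rather than leak. Pointing-pair visibility is evaluated
location-to-location with both endpoints at ground eye height (1.4 m),
the perspective at which the pointing task was administered.

Isovists (the planar region visible from a viewpoint; its area divided by
the bounds area is the *geographic scale* of the viewpoint) are computed
by an angular ray sweep, default resolution 0.25°, against the walls at
least as tall as the eye height, clipped to the layout bounds. The sweep
converges to the exact visibility polygon as the resolution shrinks; tests
bound its error at 2% against a brute-force oracle that rasterizes the
bounds at ~220² grid points and runs an independent line-of-sight test to
each.

## Circular statistics

Pointing directions pooled over participants (and both sessions) for one
ordered origin→target trial are modeled as a von Mises mixture with K ∈
{1, 2}. K = 1 is closed-form maximum likelihood. K = 2 is fitted by EM;
all restarts (default 20) advance in lock step as one batched computation,
with component means initialized from randomly chosen data points — which
also makes the fit exactly rotation-equivariant, since the initialization
rotates with the data. The concentration M-step solves A₁(κ) = R̄ by three
Newton steps from the Best–Fisher closed-form approximation; the
refinement matters because the approximation alone is inexact enough to
break the EM ascent property near convergence, and the log-likelihood
trace (retained on every fit) is asserted non-decreasing. κ is capped at
500 for degenerate clusters, with a warning.

A trial is declared bimodal when the K = 2 fit wins on BIC *and* both
weights are ≥ 0.15 *and* the mode directions are ≥ 30° apart. The weight
and separation floors keep a shoulder or a few strays from counting as a
second mode; all three thresholds are config-exposed (`MixtureConfig`).
Under the packaged simulation conditions (n = 60, κ = 8) the detector's
specificity is ≥ 95% and its sensitivity at 90° separation ≥ 90%
(asserted over 200 seeded replicates each).

Confidence sectors for mode directions are percentile-bootstrap arcs
(default B = 1000, level 95%): resample, refit warm-started from the point
estimate, match components by nearest mean direction, take circular
percentiles of the signed deviations. Arcs are widened to contain the
point estimate if a skewed bootstrap distribution would otherwise exclude
it. In a bimodal trial the *systematic* mode is the component whose mean
deviates more from the correct direction; an exact tie goes to the
lower-weight component (systematic errors are the minority regime in the
data this models), with a warning.

## The alternative maze

Distortions of the cognitive map are composable edits of the route spec,
never coordinate surgery: `DeleteLeg` (endpoints fuse; represented as a
zero-length leg so location ids stay stable; the turns at the fused joint
compose automatically through the heading bookkeeping, i.e. forgetting a
segment preserves the remembered turns), `SetLegLength` (explicit value or
"match that other leg"), and `RotateSubroute` (adds a signed angle to one
turn, carrying the downstream component rigidly). The packaged composite
distortion is delete leg 5–6, shrink leg 6–7 to leg 8–9's length, rotate
the final three-location component 90° at location 7. The rotation
handedness is not pinned down by the source; the default −90°
(counter-clockwise, toward the maze body) realizes without corridor
collisions, while +90° would fold the tail back onto the corridor of leg
4–5.

Model comparison scores each participant × session by mean absolute
angular error of the judged azimuths against each layout's true
directions, over bimodal trials only (per-record errors are computed
first, then averaged; deflected-but-unimodal trials are excluded). The
smaller mean wins; ties prefer the correct layout (conservative toward the
null representation). Trials whose endpoints coincide in the edited layout
(origin 5 → target 6) have no defined direction there and are excluded
upstream. Aggregation reports the percentage preferring the alternative
per group × SOD level × session — empty cells as missing, not zero — plus
overall per-session rates and the mean error-reduction fraction
(1 − alt/correct) among alternative-preferring participants.

## Cohort rules

Raw TLX is the mean of the six workload subscale ratings on the 10-point
scale. Exclusion uses the Tukey fence: participants whose mean *visible*-
trial error lies strictly above Q3 + 1.5·IQR (linear-interpolation
quartiles — the common statistical default; the underlying studies do not
name their rule) of their experiment pool are dropped. The SOD median
split orders each experiment pool by (score, participant id) — the id
makes ties deterministic — and labels the lower half "low"; at odd pool
size the extra participant goes to the low half.

The source studies reused the ground-only cohort of experiment 1 in
experiment 2's analysis; the generator creates disjoint cohorts instead
(G and G+E form pool 1, E forms pool 2), so pool 2 is split on E alone.

## Synthetic cohorts

The generator emulates the study design: three groups (default 24 each),
two sessions, 72 ordered trials per participant-session. Visible trials
draw judged ~ vonMises(true direction, κ = 200; circular sd ≈ 4°).
Non-visible trials on eligible pairs — any pair touching locations 6–9
that is resolvable in both layouts — take the alternative layout's
direction with probability p_alt and the correct one otherwise, plus
vonMises noise; ineligible non-visible trials always center on the correct
direction. The study gives no distributional parameters for any of this,
so the defaults are repository choices engineered to reproduce the
qualitative structure the analysis assumes:

- κ_nonvisible: G group {low: 3, high: 8}; G+E and E {6, 6} — an ability
  gap at ground level that elevated access bridges. Session 2 multiplies
  κ by 1.4 (practice).
- p_alt: G {low: 0.85/0.65, high: 0.25/0.15} (session 1/2); G+E
  {0.55/0.40, 0.45/0.30}; E {0.60/0.45, 0.50/0.35} — the low-vs-high
  adoption gap is largest in G, and session-2 adoption is lower
  everywhere.
- SOD scores: truncated normals on [1, 7], strata means 3.2 / 5.2,
  sd 0.6 — separated enough that the median split recovers the latent
  stratum almost perfectly.
- TLX items: truncated normals, session means 5.3 / 4.8, sd 1.2.
- 4% of participants are compliance outliers (visible-trial κ = 1),
  placed to be caught by the Tukey fence.

Adoption is Bernoulli per trial by default — a "cognitive collage" in
which distortion is per-relation. `per_participant_adoption=True` instead
draws one latent representation per participant-session. The per-trial
default is the weaker assumption, but note its consequence: a participant
making many trials under p_alt = 0.8 will almost *always* be classified
as alternative-preferring, because averaging over trials drives the
preference decision to 0 or 1. The pipeline-recovery study therefore uses
the per-participant mode, in which the generating p_alt *is* a preference
probability and the recovered cell fractions can be compared to it
directly; recovery within ±10 percentage points per cell (24 participants
per group × SOD cell, averaged over 20 seeds) is asserted in tests.

Every cohort is deterministic given the master seed: participants own
independent child streams of one `SeedSequence`, so changing the cohort
size does not reshuffle earlier participants' data.

What the generator does *not* emulate: learning-phase dynamics, workload
coupling to performance, distance-dependent pointing precision,
participant-specific biases, or any interaction between visible and
non-visible accuracy beyond the outlier mechanism. Passing tests
demonstrate that the pipeline recovers structure *of the kind it assumes*;
they say nothing about whether human pointing data satisfy those
assumptions.

## Problem sizes and runtime choices

The packaged simulations are sized for a laptop CPU: modality-detector
operating characteristics use 200 replicates at n = 60; the isovist oracle
uses 220² grid cells; the pipeline-recovery study uses 20 seeds at 144
participants each. EM restarts default to 20; the pipeline accepts a
`thresholds` block to adjust them. The 56-trial mixture-fitting stage of a
reference-size pipeline run takes a few seconds.

## Known limitations

- The maze reconstruction matches the published constraints, not the
  unpublished coordinates; quantities that depend on exact leg lengths
  (isovist areas, specific direction separations) are reconstruction-
  specific, while the 16/56 split and the ordering results are not.
- BIC-guarded EM replaces the Bayesian mixture machinery used in the
  original analysis; with well-separated modes the two agree on modality,
  but posterior-derived quantities (e.g. credible intervals) are
  approximated here by bootstrap analogues.
- Mixtures are limited to K ≤ 2 by design; a trial with three genuine
  modes would be reported as the best two-mode description.
- The angular-sweep isovist is resolution-limited; features narrower than
  the ray spacing at their distance can be missed.
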