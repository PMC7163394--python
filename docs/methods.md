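# Methods

`capribite` turns 2-min trough-weight recordings from individually penned
dairy goats into cumulative dry-matter-intake (DMI) profiles, characterizes
each goat-day by eleven aggregate feed-intake-pattern traits, and estimates
how repeatable those traits are within and between physiological periods.
This note documents the models, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Recording model and profile construction

A scale under each trough reports the as-fed mass of feed remaining every
2 min, at 5-g resolution, from the afternoon feed delivery until refusals
are removed 22 h (1320 min) later.  Cumulative intake at time *t* is
`(weight(0) − weight(t)) · DM-fraction / BW`, in g DM per kg of body
weight, so goats of different size and diets of different dryness are
comparable.  Windows are half-open `[0, d)` with *t* = 0 at delivery: the
15-h analysis window (0–900 min) holds exactly 450 measures at 2-min
sampling, and a complete 35-goat × 4-period × 4-day design holds 560
goat-day profiles.

Load cells drift and occasionally tick upward; the raw cumulative curve is
made monotone by a running maximum.  This is idempotent, never changes an
already-monotone series, and never changes the final cumulative value.
Isotonic least-squares was considered and rejected: at 5-g noise the two
differ negligibly and the running maximum is trivially auditable.  Gaps of
up to 3 consecutive missing samples are filled by linear interpolation;
larger gaps disqualify the goat-day (mirroring how trials discard
recordings lost to practical problems).

## Exponential intake model

Each 15-h profile is fitted with `y(t) = a(1 − e^(−bt))`: `a` is the
intake plateau (g DM/kg BW), `b` the fractional rate of intake (min⁻¹),
and `a·b` the initial rate of intake.  Fitting is nonlinear least squares
(trust-region reflective, positive bounds) with `a` started at the final
cumulative value and `b` at a half-rise moment estimate, plus three
perturbed-`b` restarts before a fit is flagged unconverged.  The origin
point (0, 0) is included, unweighted.  RMSE is √(SSE/n) without a
degrees-of-freedom correction; at n = 450 the distinction from √(SSE/(n−2))
is far below any tolerance used.  The RMSE is itself a trait: the model
fits one decelerating meal well, so residual error grows with the number of
separate eating bouts.

## Segmentation-clustering

The cumulative curve is approximately piecewise linear: bouts are
constant-slope stretches, pauses are flat.  Segmentation minimizes
`SSE + penalty · (number of segments)` exactly by dynamic programming over
all breakpoint placements (O(n²) with prefix-sum segment costs), minimum
segment length 2 samples.  The default penalty is the known-variance BIC
charge for one extra segment, `3σ̂² log n` (two line parameters plus one
breakpoint), with σ̂² estimated from second differences by a trimmed RMS
(top 2% of |Δ²y| removed — those are the change-points themselves).  A
likelihood-style BIC with unknown variance, `n log(SSE/n) + 3k log n`, was
tried and abandoned: quantized recordings can be fitted to SSE → 0 by
chasing the 5-g staircase, which that criterion rewards without bound.

Pooled segment slopes of a whole run (all goats × days, so labels are
comparable across animals) are classified into eight ordered clusters,
8 = fastest eating, 1 = no eating.  Clustering is k-means on
`log10(slope + 10⁻³)`: rates are ratio-scale and the distinctions that
matter biologically — true pause (≈ 0), slow nibbling (≲ 0.04 g/kg/min),
committed eating (≳ 0.1) — live at different orders of magnitude.  The
model's defining property is that clusters 1–2 hold the "almost no intake"
slopes, and plain k-means does not guarantee that: on raw slopes it
sometimes pushed the slowest eating band into cluster 2; on log slopes it
sometimes spent three or four clusters inside the near-zero band.  The fit
is therefore band-aware: the widest balanced gap of the raw slope
distribution (below-gap mass between 15% and 85%) is taken as the
no-intake/eating divide, and if the plain solution does not place exactly
two centroids below that divide — and is not an essentially exact fit of
well-separated slope groups — the model is refitted constrained: two
clusters below the gap, six above, with the gap as the cluster-2/3 decision
boundary.  Ties at any boundary go to the lower-slope cluster.

**First meal.** Scanning segments in time order, intake of eating segments
(cluster ≥ 3) accumulates until a near-zero stretch of at least 30 min;
shorter low-slope stretches neither end the meal nor add intake.  The
pause criterion is applied to a *maximal run* of consecutive cluster ≤ 2
segments rather than a single segment: the optimal segmentation may
legitimately cut one homogeneous slow stretch in two (the quantization
staircase gives it freedom to), and the 30-min rule concerns the stretch,
not the arbitrary pieces.  If no qualifying pause occurs the meal extends
to the window end and is flagged.

## The eleven traits

Per goat-day: DDMI (intake over the full 22-h window), DMI90, DMI180,
DMI900 (cumulative intake at 90, 180, 900 min; boundary reads use the last
sample strictly before the boundary, consistent with the 450-measure
convention), P90 = DMI90/DMI900, P180 = DMI180/DMI900, the exponential
`a`, `a·b` and RMSE, the first-meal DMI, and the NDF sorting index.  The
sorting index is a fibre mass balance: NDF eaten = NDF offered − NDF
refused; its concentration in the eaten fraction divided by the offered
diet's NDF fraction is < 1 when the goat sorts against fibre.  It is
computed for every day with refusal composition data and is NaN otherwise;
goat-period trait values are arithmetic means of available days.

## Statistical layer

All effects are fixed, as befits a designed trial with custom error-term
mapping, rather than a REML mixed model — the F-test construction is then
explicit and auditable:

* **Full model** (daily records): breed, goat-within-breed,
  day-within-goat, period, breed×period.  The day term against the
  residual measures within-period repeatability: a *large* p-value (> 0.95
  by default) means measurement days agree.
* **Simplified model** (goat-period means): the same without the day term;
  breed is tested against the goat-within-breed mean square, period and
  the interaction against the residual.

Sums of squares are sequential (term order as listed), computed by least
squares on growing dummy design matrices with rank tracked per term — this
handles the rank deficiency of nested dummies and mild unbalance from
missing goat-days without special cases.  Between-period trait
correlations are pairwise-complete Pearson coefficients on per-goat period
means.  Between-period repeatability is the intraclass ratio
s²ᵦ/(s²ᵦ+s²ᵥᵥ) from a one-way method-of-moments decomposition of the
goat-period means by goat, with the between-goat component `(MSB − MSW)/n₀`
truncated at zero.

PCA of the eleven goat-period mean traits uses the correlation matrix —
the traits mix g/kg BW, ratios and per-minute rates, so unit-variance
scaling is the only defensible choice — with a deterministic sign
convention (largest-magnitude loading positive).  Component scores feed
back into the simplified ANOVA and the repeatability ratio, and per-goat
barycentres (means of the period scores) place each animal on the
fast-eater/slow-eater continuum.

## Synthetic herds

No recordings are distributed with the package; a seeded generator stands
in for them.  Each goat carries latent traits — 15-h intake level
(g DM/kg BW), initial eating rate (g DM/kg BW/min), eagerness (fraction of
the 15-h intake in the first meal), fibre-sorting intensity, body weight —
drawn around breed means chosen so that Alpine goats eat more per kg BW
but start more slowly than Saanen, with lactation-period intake means in
the 30–40 g DM/kg BW band.  Variance components per trait: between-goat
SD, a random goat×period deviation (without it goats never re-rank between
periods and every between-period repeatability is ≈ 1), a
within-goat-between-day SD, plus deterministic period shifts mirroring the
fixed-effect treatment of period.  The implied repeatability of the latent
goat-period means is `s²_goat / (s²_goat + s²_goat×period + s²_day/n_days)`
(≈ 0.65 for the intake level at the defaults), and a Monte-Carlo test
recovers it from the generator's truth tables.

A goat-day realizes as: a first bout from *t* = 0 holding the day's
eagerness fraction at the initial rate; 0–6 later bouts at 40–80% of that
rate separated by pauses, a quarter of which are shorter than 30 min (so
the pause rule is genuinely exercised); slow background nibbling in many
pauses; and an optional late-night bout after the 15-h mark.  Three
calibration bounds make the first-meal problem well-posed: eating bouts
are never slower than 0.10 g DM/kg BW/min, nibbling never faster than
0.04, and bouts shorter than 12 min are not planted — i.e. "eating" and
"almost no intake" are separated classes on the rate axis, which is what
the eight-cluster rule presumes of real recordings.  Nibbling is capped at
10% of the day's intake.  The trough weight is the offered mass minus
cumulative as-fed intake, plus N(0, 2 g) scale noise and occasional
transient positive bumps (probability 0.002 per sample, exercising the
monotone cleaning), quantized to 5 g.  The realized bout schedule, the
per-day latent values and the refusal composition are stored as truth, so
meal detection and trait recovery can be scored exactly.  Refusals close
the dry-matter balance exactly; their NDF fraction is enriched over the
offer in proportion to sorting intensity and the fraction eaten, capped so
the implied intake NDF mass stays non-negative.

What the generator does **not** emulate: morning feeding (only the
afternoon window is analysed), water intake, rumination, diurnal rhythm
within the window, social competition (the emulated trial housed goats
individually), sensor drift slower than the recording, and any correlation
structure among the latent traits beyond what the breed means induce.
Passing tests therefore demonstrate that the pipeline recovers what it
measures under this bout model and noise model — not that real goats obey
the bout model.

## Problem sizes and defaults

The test suite and the acceptance script run the full reference geometry
(35 × 4 × 4, 541 profiles after the standard 19-cell missing pattern) once
per invocation — a run takes a few seconds — and use 10-goat × 20-day
herds for meal-recovery scoring, 200 replicates for the ICC-recovery and
type-I simulations (directly simulated trait tables, which is what those
estimators consume), and 30–50 small random profiles for the
brute-force segmentation oracle.  Key defaults: 2-min interval, 1320-min
window, 900-min analysis window, 90/180-min early reads, 8 clusters,
30-min pause, penalty `3σ̂² log n`, repeatability threshold 0.95, 5-g
resolution, 2-g scale noise.  All randomness flows from a single seed.

## Known limitations

* The segmentation penalty assumes roughly homogeneous noise along a
  profile; strongly heteroscedastic sensors would need a per-segment
  variance model.
* The band-aware clustering needs either a clear pause/eating gap or
  k well-separated slope groups; data that fills the gap densely falls
  back to plain k-means, whose low clusters may then not be "almost no
  intake".
* The fixed-effects F-tests are exact under balance and normality; with
  heavy unbalance the sequential sums of squares depend on term order
  (the documented order is always used).
* `ndf_sorting` is undefined for a day with zero intake or missing refusal
  composition; downstream statistics silently use the available days.
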