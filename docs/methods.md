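# Methods

## Arena model and conventions

The arena is modelled as a 1-D long axis (x, mm, origin at the left end)
with a bounded transverse coordinate (y). Quadrants are half-open
intervals `[b_{i-1}, b_i)` between the three borders (defaults L/4, L/2,
3L/4 for L = 55 mm), so a frame exactly on a border belongs
deterministically to the right-hand quadrant. A frame is *lit* iff its
quadrant is in the epoch's lit set (default {0, 2}) and the epoch is not
dark; occupancy scoring is binary by nominal border position even though
the physical light border has a finite gradient (mean 0.67 mm, range
0.42–1.04). Choice zones span ±3 mm around each border; the arena
invariants guarantee they are disjoint and interior.

Tracks are plain CSV tables (`fly_id, t_s, x_mm, y_mm`, one row per fly
per frame, nominal 25 frames/s). Out-of-range or non-finite coordinates
are flagged invalid — never clamped — and excluded from every time,
occupancy and speed sum. Invalid runs up to 0.2 s are bridged by linear
interpolation so smoothing stays continuous; longer dropouts stay
invalid. All metrics integrate actual inter-frame intervals (with long
gaps credited one nominal frame) rather than counting frames, so mildly
irregular sampling degrades gracefully. The frame rate is taken from the
timestamps (median Δt), not assumed.

Smoothing is a centered triangular window spanning 1 s (25 frames at
25 fps), with weights renormalised at track edges and across invalid
frames, so every smoothed sample is a convex combination of valid
samples (it can never leave the data's min–max envelope).

## Per-fly metrics

All metrics are scored on the smoothed track over the **last 30 s** of
each epoch.

**PI** = (Σdt lit − Σdt unlit)/Σdt over valid window frames. A fly whose
valid epoch frames are all one lit-state, and whose within-epoch path
length exceeds 2 mm, is assigned the extreme PI (±1.0) and flagged
`extreme_assigned`. The 2 mm "moved within the zone" threshold is this
package's choice (about half an arena-width of net motion over a
minute); the assignment rule itself needs no threshold for the PI value
— a single-sided fly's measured PI is already ±1 — the threshold only
distinguishes *moving* single-sided flies from parked ones in the flag.

**LSR** = log₂(mean lit speed / mean unlit speed). Per-frame speed is
the 2-D step displacement over dt, attributed to the lit-state of the
step's start frame. Censoring: `no_movement` (path ≤ 2 mm over the
epoch), `single_zone` (no usable speed samples in one of the two
states), with a division guard if a zone's mean speed is zero despite
movement. Censor flags are evaluated on the analysis window, since a fly
that moved in a zone only outside the window has no window mean there.

*Cruise-sample restriction.* Zone mean speeds use only samples that are
(i) outside choice zones, (ii) ≥3 mm from the arena ends, and (iii)
≥0.25 s from any border crossing or heading-reversal event (crossings:
lit-state flips; turns: sign changes of the 0.2 s block-averaged
x-velocity above 1 mm/s, so pause jitter does not register). The reason
is a measurement artifact of position smoothing that we quantified with
a deterministic shuttle track (8 mm/s in the dark, 4 mm/s in the light):
the naive all-frame estimator returns LSR −0.80 instead of the true
−1.0. Two mechanisms drive it. First, the smoothed trajectory is
displaced toward the slower side at each crossing, so the
intermediate-speed ramp frames of *both* crossing directions are
attributed to the faster zone, deflating its mean. Second, smoothing
turns every direction reversal into a ~1 s speed dip, and border (and
wall) encounters per unit occupancy scale with the local walking speed,
so border-localised dips attenuate the faster zone disproportionately.
Both biases shrink |LSR| toward 0 and grow with crossing rate. Excluding
boundary-adjacent and event-adjacent samples removes them; the 0.25 s
buffer is deliberately shorter than the 0.5 s kernel half-width because
demanding a fully event-free kernel support discards short fast bouts
and re-biases the fast zone downward (a selection effect we measured on
simulator ground truth). With these rules the pipeline recovers
programmed log₂ speed ratios of −1/0/+1 to within ±0.05/±0.02/±0.12 on
average (100-fly groups).

**Choice-zone transits.** A transit opens when the head enters a zone
from outside and closes at the first frame outside again; entry and exit
sides take the lit-state of the quadrant adjacent to the border on that
side. A partial transit underway at epoch start is discarded (entry side
unknown), as is one still open at epoch end. Re-entry within 2 frames of
an exit at the same border merges into the prior transit (tracking
chatter). ChI, PEDL and PELD follow the count formulas; a fly with no
transits is censored from the choice analysis entirely. For *parameter
recovery* the package also provides transit-pooled proportions: the
unweighted mean of per-fly proportions overweights flies that crossed
quickly (few entries) and is biased upward, whereas the ratio of total
counts is the right estimator for a common per-transit probability.

**Conditioning score.** Each testing phase yields a half PI from the
last 30 s of positions relative to the chamber midline (time on the CS+
side minus CS− over total, pooled over the flies in the chamber); the
full PI is the mean of the two swapped-side phases, so fixed side biases
cancel. Positive = preference for the CS+ odor.

## The walker simulator

Quasi-1-D: motion is dominantly along x with bounded lateral wobble,
since every published metric depends only on x. Per 40 ms frame:

1. **Pauses** — a two-state Markov chain: enter at `pause_rate`
   (0.2 s⁻¹), leave with mean dwell `pause_duration_mean` (1 s).
2. **Speed** — `base_speed` (8 mm/s) × the light multiplier m
   (interpolated linearly across the 0.67 mm gradient band) ×
   i.i.d. lognormal noise (CV 0.3, unit mean).
3. **Heading** — spontaneous reversals at `heading_persistence`
   (0.1 s⁻¹). Reversals (spontaneous, drawn, or at a wall) are executed
   as constant-speed semicircular arcs lasting 0.32 s — a walking fly
   swings around rather than stopping dead — which keeps the head moving
   through turns as in real tracks.
4. **Choice zones** — on each entry during a lit epoch the transit
   outcome is drawn once from the side-appropriate crossing probability
   (`p_cross_dark_to_light` is the target PEDL, `p_cross_light_to_dark`
   the target PELD). A drawn crossing steers the fly through; a drawn
   reversal carries it to within ±(0.5–1.0) mm of the border — the light
   edge is what the fly can actually sense — before the turn arc. The
   draw commits the fly: any in-progress arc is cancelled, and
   spontaneous reversals are suppressed until zone exit. During dark
   epochs zones have no behavioural meaning.
5. **Confinement** — specular walls in y; in x the fly presses into the
   arena end and swings around.
6. **Lateral wobble** — y steps are Gaussian with SD
   `lateral_jitter_sd` × (current step / base step). Scaling with the
   instantaneous step length matters: speed-independent jitter adds a
   constant to the 2-D displacement and therefore inflates slow-zone
   speeds relatively more, distorting the measured speed ratio by
   construction.

Randomness: one root `SeedSequence`; per-fly streams are spawned by
counter, so adding a fly never perturbs the others, and identical
(params, seed) reproduce byte-identical tracks. The two valence
mechanisms are deliberately orthogonal — real flies presumably couple
them, but the orthogonal design is what lets the screen analysis
demonstrate the dissociation cleanly.

What the generator does *not* emulate: 2-D turning kinematics beyond the
arc approximation, inter-fly interactions, tracking noise and identity
swaps, arousal decay over epochs, and any coupling between speed and
boundary behaviour. Passing recovery tests therefore certifies the
estimators against these idealised dynamics, not against every artifact
of real video tracking.

## Estimation statistics

The effect size is the unstandardised mean difference against the
*average of the two control means* (not the pooled-observation mean),
applied identically inside every bootstrap draw. The bootstrap unit is
the fly; the three groups are resampled independently with replacement
(3,000 draws). BCa: bias correction z₀ from the fraction of draws below
the point estimate; acceleration from the jackknife skewness of the
concatenated leave-one-out estimates (each observation left out of its
own group). Degenerate inputs (constant draws, all draws on one side,
zero acceleration denominator) fall back to the percentile interval with
a logged warning. Hedges' g uses the two controls concatenated and the
small-sample correction 1 − 3/(4·df − 1). Mann–Whitney p-values are
two-sided, exact below a combined n of 20 (ties permitting), otherwise
the tie-corrected normal approximation with continuity correction; the
power simulation uses a vectorised implementation of exactly that
approximation (cross-checked against scipy to 10 significant digits).

Power at the published design: at Hedges' g = 0.6 and α = 0.05 the
study's operative comparison — 45 test flies against the two pooled
45-fly control groups — has Mann–Whitney power ≈ 0.89, and the
conventional t-based 45-vs-45 figure is ≈ 0.80. The 45-vs-45 *rank-test*
power is ≈ 0.785, slightly below the t-test by its Pitman efficiency
3/π under normal shift; the test suite pins all three numbers.

BCa calibration is verified on 500 simulated null three-group datasets
(the 95% interval excludes zero in 3–8% of runs), and the interval
arithmetic is checked two ways: an independently written textbook BCa on
the same resample stream (exact agreement) and scipy's multi-sample BCa
on an independent stream (agreement within Monte-Carlo slack).

## Aggregation

Fixed-effects meta-analysis is the closed-form inverse-variance weighted
mean. The replicate variance sᵢ² ("pooled control+test variance") is
operationalised as the variance of the replicate's bootstrap Δ
distribution — the natural estimate of var(test mean) + var(control
reference mean) for a difference of independent means — isolated in
`screen.replicate_variance` so an alternative convention is a one-line
change. Percent-of-control divides an intervention's ΔPI by the simple
average of replicate control ΔPIs at the same intensity (undefined, and
flagged, at zero control mean); cross-intervention summaries are
unweighted means of percents, with a precision-weighted variant behind a
flag. Effect-size regressions are OLS with R², adjusted R² =
1 − (1 − R²)(n − 1)/(n − 2), and a BCa CI on R² from resampling lines in
pairs. Co-zonal pairing emits a pair for every PAM × MBON line
combination sharing at least one zone with staining intensity ≥ 3; the
shipped staining tables are synthetic stand-ins (marked in their
filenames) with the shape of a real anatomical scoring table.

## Problem sizes and numerical choices

The bundled drivers and tests use 45 flies per group (the published
group size), 60 s epochs, and 100–200 flies for recovery studies; the
synthetic screen uses 12 lines × 3 groups × 45 flies. Bootstrap CIs use
3,000 resamples (500–1,000 where only the point estimate matters), power
estimates 10,000 replicates. Tolerances: metric-oracle agreement 1e−9;
closed-form arithmetic 1e−12; LSR recovery ±0.15 in log₂ units;
proportion recovery at binomial 95% bounds held family-wise (Šidák)
across the six simultaneous checks. Ties in the Mann–Whitney matrix path
are delegated row-wise to scipy (they cannot arise for continuous
draws). Seeds are explicit everywhere; every stochastic test and script
is reproducible bit-for-bit.

## Known limitations

- The cruise-sample LSR estimator discards boundary-adjacent data; for
  flies that never cruise (pathological pausers, wall-huggers) the LSR
  is censored rather than estimated from contaminated samples.
- Binary occupancy at the nominal border ignores the physical light
  gradient; flies idling inside the gradient band are scored by the
  nominal border, exactly as in the assay's own scoring.
- The conditioning score assumes a fixed midline; odor-delivery
  asymmetries beyond side swapping are not modelled.
- Percent-of-control is a ratio estimator and becomes unstable as the
  control mean approaches zero; the flag, not a guard value, signals it.
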