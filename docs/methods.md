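# Methods

## Efficiency computation

Raw frames carry two channels: donor emission and sensitized acceptor
emission (the FRET channel). The pipeline applies, in this fixed order:

1. **Smoothing** — a k×k moving average per channel (default k = 5,
   edge-replicated borders). k = 1 disables smoothing; validation tests
   use k = 1 so per-pixel values can be compared to ground truth without
   mixing across region borders.
2. **Background subtraction** — either user-supplied scalars per channel
   or the mean of a user-supplied background ROI on the first frame. The
   acquisition protocol behind the method does not pin down a specific
   background estimator, so the simplest scriptable contract was chosen.
3. **Bleedthrough correction** — I_FRET = I_F − β·I_D, with β calibrated
   from a donor-only specimen as the ratio of masked means
   (mean(I_bth)/mean(I_D) after background subtraction). Ratio-of-means
   rather than mean-of-ratios: near-zero donor pixels would otherwise
   dominate the estimate.
4. **Ratio** — η = I_FRET/(I_D + I_FRET).

**Validity rather than clipping.** A pixel is invalid (NaN) when the
denominator I_D + I_FRET falls below `min_denominator` (default 1 ADU,
guarding against division blow-ups in background areas) or when η falls
outside [0, 1] by more than 1e−9; excursions within 1e−9 are attributed
to floating-point error and clipped. Invalid pixels are excluded from
region means, never zero-filled, and each frame's valid+invalid counts
partition the pixel count.

**Sensor floor.** The lowest reliable efficiency is calibrated from a
sample of the ATP-insensitive sensor variant: a Gaussian is fit to the
sample (by moments, or by least squares on a histogram — both are
implemented and agree within 1% on Gaussian data) and the floor is
mean − 2·SD. The canonical value used throughout is 0.2827.

## Region schemes

Two extraction schemes coexist, matching how the imaging was analysed:

* **Nine-circle organizer scheme** — circles of 20 µm diameter: three
  along the AP boundary, three along the DV boundary (the central circle
  at the boundary intersection shared by both, so five distinct
  organizer circles), four in the quadrants away from the boundaries.
  Composite regions average ROI-wise (unweighted mean of circle means):
  APB and DVB over their three circles, ORG over the five distinct
  organizer circles, NO over the four outer circles. Whether the
  original analysis weighted ROIs by valid-pixel count is unknowable
  from the method description; unweighted was chosen and is asserted by
  tests. Circle rasterization includes a pixel iff its center lies
  within the radius — reproducible and orientation-independent. ROI
  spacing along a boundary is 1.5× the diameter by default (circles
  disjoint), configurable. The outer-circle placement (quadrant
  midpoints of the pouch bounding box) is likewise a convention, since
  only "outside the boundaries" is specified by the field's practice.
* **Compartments** — dorsal/ventral polygons (supplied as JSON
  landmarks, not interactive drawing, so analyses are scriptable) with
  anterior/posterior sub-compartments cut by the AP boundary line.
  Anterior is the half-plane to the left of the line's direction vector;
  pixels exactly on the line count as posterior (deterministic
  tie-break). Compartment means pool pixels — a single region, no
  sub-ROI averaging.

## Decay model and fitting

The post-inhibition decline of a region's mean efficiency is summarised
by the four-parameter logistic f(t) = base + (max − base)/(1 + (t½/t)^n)
with **base fixed** at the calibrated floor (0.2827) and **max bounded**
above by 0.7, the highest reliable efficiency observed in healthy
tissue. Free parameters: max, t½ > 0 (bounded by 10× the observation
window), and the Hill coefficient n ∈ [−50, 50]. n's sign is left free:
decays give n < 0 and a more negative n is a steeper transition at t½
(asserted by a finite-difference test); an increasing trace yields
n > 0 and is flagged.

**Time origin.** t is minutes since drug addition; frames at or before
the addition are excluded, so the first fitted point sits at one frame
interval and the t = 0 singularity of the formula never enters the
residual. At t = 0 the implementation returns the continuous limit
(max for n < 0).

**Optimisation.** Bounded trust-region least squares (SciPy `trf`),
tolerances 1e−10, deterministic: no random restarts, only a fixed
restart grid on the initial Hill guess {−1, −2, −5} when the first
attempt fails. Initial guesses: max₀ = mean of the first five post-drug
points (capped at 0.7), t½₀ = first crossing of (base + max₀)/2 (else
half the window), n₀ = −2. Missing frames are dropped from the
residual, not interpolated. A fit is reported non-converged when the
optimiser fails, when t½ pins at its upper bound, or when the fitted
curve declines by less than 1% of its dynamic range within the window
(e.g. a constant trace) — in the latter cases the parameters are
meaningless even though the residual is tiny. A fitted t½ beyond the
last observed timepoint is flagged (`t_half_exceeds_window`): the value
is still the least-squares optimum but its upper confidence limit is
unbounded. Traces lying entirely below base + 0.01 are rejected as
already at the floor.

Cohorts are fitted per disc × region, plus one fit of each region's
mean trace (unweighted mean over discs per timepoint); both the
per-disc distribution and the mean-trace fit are emitted, since
published half-lives could originate from either summary.

## Synthetic scenes

The generator inverts the analysis formulas so the pipeline can be
validated end to end. A rectangular virtual pouch (curved anatomy does
not enter any formula — only region membership does) is crossed by an
axis-aligned vertical stripe (APB, conventionally just anterior of the
AP line) and horizontal stripe (DVB) of 20 µm width; their crossing is
the organizer intersection, the quadrants are non-organizer regions.
Each region follows its own 4PL with the defaults: plateau 0.6 (the
typical resting efficiency), floor 0.2827, Hill −2.3, half-life 45 min
in organizer stripes vs 30 min elsewhere — the OxPhos-inhibition
contrast the analysis is designed to detect. Pre-drug frames sit flat
at the plateau, since control tissue is stable over the culture window
and fits start at drug addition.

Per pixel of efficiency η and total corrected intensity T (default
2000 ADU): I_D = (1−η)·T, I_FRET = η·T; raw channels add backgrounds
(100/120 ADU), donor bleedthrough β·I_D (β = 0.15) and additive
Gaussian noise (σ = 5 ADU), seeded for bit-identical re-renders. The
default acquisition grid is 130 frames at 1 frame/min with drug at
10 min — a 2 h time-lapse whose 1-min interval is implied by the
121–130 min analysis bracket convention of the imaging protocol — at
0.22 µm/px. Additive Gaussian noise (not Poisson) is used because EMCCD
data at these intensities is well approximated by it and the analysis
is noise-model agnostic; the noise model is a named field so other
models can be added. Not emulated: optical PSF, photobleaching,
z-structure, tissue movement, disc-to-disc parameter variability — so
passing recovery tests demonstrates correctness of the computation, not
robustness to drift or segmentation error in real microscopy.

Cohort-level experiments (tens of discs × many runs) are generated at
trace level (`simulate_cohort_traces`): true 4PL curves plus Gaussian
trace noise of σ = 0.005 efficiency units, the empirical frame-to-frame
scatter scale of region-mean traces. Rendering full image stacks for
thousands of virtual discs would add nothing to a statistic computed on
traces.

## Statistics

Region comparisons delegate to SciPy: Kruskal–Wallis (tie-corrected H,
chi-square p) across regions, two-sided Mann–Whitney (exact on small
tie-free samples), Welch and paired t, and an unpaired mean difference
with a Welch–Satterthwaite 95% CI (estimation-plot style). All
degenerate cases are explicit: identical data gives H = 0/p = 1 with a
warning, zero-variance paired differences raise. The published figure
style applies Kruskal–Wallis to paired two-group data; it is
implemented as printed, with the paired alternative available. Exact
permutation enumerations live in the test suite as oracles: the
Mann–Whitney p matches exhaustive enumeration exactly; the
Kruskal–Wallis H matches the rank formula exactly, while its chi-square
p is an asymptotic approximation that agrees with the exhaustive
permutation p to within 0.05 at six samples per group (at three per
group the approximation is visibly off for strong separations, which is
inherent to the chi-square reference, not to the implementation).

## Problem sizes in the validation suite

Recovery targets use 120-point, 1-min noiseless traces (and 20
noise-replicates at σ = 0.005); image round trips use 64×64–96×96
scenes of 40–80 frames; cohort significance uses 26 virtual discs per
region and 100 seeded null runs; the Kruskal–Wallis type-I check uses
5,000 null replicates at n = 26 per group. These sizes make every
property sharply testable while keeping the whole suite around a
minute on one CPU.

## Known limitations

* Geometry is axis-aligned and rectangular; curved boundaries only
  affect region membership, which callers can supply via landmarks.
* No drift/registration correction and no automatic boundary detection
  from the acceptor channel; landmarks are user input.
* Confidence intervals on fit parameters are not computed beyond the
  identifiability flag; the package compares parameter distributions
  across discs instead.
* The β calibration assumes a spatially uniform bleedthrough fraction.
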