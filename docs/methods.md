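# Methods

## The measurement model

The pipeline treats the apical midline of the intestinal primordium as a
one-dimensional profile sampled from a two-channel fluorescence image.
Three intensity populations matter: the apical midline signal, the
intestinal cytoplasmic background, and the off-specimen slide level.
All quantities are computed after subtracting the per-image slide
background (mean intensity of three large off-specimen rectangles); no
clamping is applied when a corrected value dips below zero, since only
normalized values feed the downstream logic.

A midline measurement is one sample along a segmented line, taken at
uniform arc-length spacing (`step_px`, default 1.0 px) with
`width_px` bilinearly interpolated sub-samples averaged perpendicular to
the local path direction. Even widths use symmetric half-pixel offsets
(width 2 → ±0.5 px) rather than an asymmetric pixel pair, so the
measurement is centred on the drawn line. The default width is 2 px; the
`fig3` profile uses 4 px and requires a single cytoplasm reference line
longer than 10 μm.

Each measurement is normalized against the cytoplasmic background mean
of its own image and channel, `(x − μ_cyto)/μ_cyto`, which removes
per-image illumination scale: the entire gap-calling chain is invariant
under multiplying all raw intensities by any k > 0 (a tested property).

## Gap calling

The background-level threshold is calibrated per channel and per embryo:
2 sample standard deviations of the normalized cytoplasmic background
above 0. Under the Gaussian background model the expected fraction of
background samples below this cutoff is Φ(2) ≈ 0.977, and the
calibration reports the observed coverage as a diagnostic. Comparisons
at the threshold are strict (`<`); a value exactly at threshold is not
background level.

A point is background level only when both marker channels are below
threshold simultaneously; a gap is a maximal run of ≥ 3 consecutive
background-level points. Maximality means two runs separated by even a
single above-threshold point are two gaps — no bridging or smoothing is
applied, because the definition supplies no merging rule. Gap calling
always operates on the raw sampling grid; length-normalized profiles
(resampling onto 100 points spanning [0, 1] of arc length) exist only
for cross-embryo overlay plots. Because the physical meaning of "3
consecutive measurements" depends on the sampling step, every gap
reports both its point count and its physical length, where each point
owns one sample spacing (a 3-point run at 0.11 μm spacing spans
0.33 μm).

Time-lapse series use a 4-minute frame interval. Gap calls in
consecutive frames belong to the same locus when their index ranges
share at least one point; a locus is *persistent* when it is present in
the final frame **and** has lasted ≥ 24 min (duration =
(frames − 1) × interval), otherwise *transient*. Both clauses are
required: a gap that lasts 24 min but resolves before the movie ends is
transient, as is a gap appearing only in the final frame (duration 0). A
locus that disappears and a later gap at the same position are distinct
loci.

Colocalization of a third marker with a called gap uses a mean-over-gap
rule: the marker is "localized" when its mean normalized intensity over
the gap interval reaches its own background threshold. This is a
deterministic operationalization of what is by-eye scoring in practice;
it is deliberately the simplest rule consistent with "above background
on average" and is exposed as a function rather than buried in the
pipeline.

## Interface bookkeeping

Interface positions along the trace are inputs (from a membrane-marker
annotation, or from the generator's ground truth) — the package does not
segment membranes. The default map has 8 interfaces between 9 rings with
star-cell sites {int1/2, int7/8, int8/9}; when star-cell divisions are
blocked the star set is {int1/2, int7/8}, embryos carry 14–16 cells (the
QC window; 20 otherwise), and 14-cell maps drop one middle non-star
interface — which one is not determinate from the cell count alone, so
the generator removes int4/5 and documents the choice.

A gap *spans* an interface when some interface index lies in its
half-open index range (± a configurable tolerance, default 0). Class
assignment: star if any touched interface is a star site; a gap touching
interfaces of both classes counts as star (it affects a star cell); a
gap touching no interface takes the class of the ring segment strictly
containing it (rings 1, 8, 9 are star territory; 1 and 8 when blocked).
Site-frequency tables count one gap per touched potential site, so a gap
spanning two sites contributes to both; a per-gap tally (each gap once,
by class) is emitted alongside, since either reading of per-site
counting is defensible. Gaps touching no interface enter class
proportions but not site tallies. Cell separation is always an input
annotation on a gap, never inferred from intensity.

## Statistics

Fisher's exact test is two-sided by the point-probability rule: the
p-value sums hypergeometric probabilities, over all tables with the
observed margins, of tables whose point probability is at most the
observed one, with a relative tie tolerance of 1e-7. It is computed with
log-gamma factorials and verified in the test suite against exact
integer enumeration for every 2×2 table with total ≤ 60, and against an
independent library implementation on random tables. ANOVA is the
standard one-way F test; Tukey's HSD reports all pairs regardless of the
omnibus outcome (matching how such panels are reported); t-tests default
to Welch (unequal variances, since group sizes are routinely unequal)
with a pooled option, and Bonferroni correction multiplies by the number
of tests, capped at 1. Degenerate inputs fail loudly (zero total
variance, n < 2 per group) except the zero-variance-equal-means t-test
pair, which returns p = 1 by convention with a log entry.

## The synthetic generator

`synthgen` emulates exactly the statistical structure the analysis
assumes, not microscopy realism. Per channel and point, intensities are
independent Gaussians: apical points `N(apical_mean, cyto_sd)`, gap
points and background samples `N(cyto_mean, cyto_sd)`, all plus a
uniform additive slide offset. Defaults: 200 points at 0.11 μm/point
(~22 μm midline), apical 500 AU, cytoplasm 100 ± 10 AU, offset 20 AU —
a 6-SD apical/background separation so detection failures are
attributable to the calling rule, not signal overlap. Gaps implant
cytoplasm-distributed values, never zeros, because a real gap still
contains cytoplasm. Implanted gap lengths default to 8–20 points
(≈0.9–2.2 μm), the physical scale of an interface-spanning gap.

Per-point sensitivity of the background classifier is Φ(2) per channel
and ≈ Φ(2)² ≈ 0.955 for the two-channel conjunction, so the probability
that a k-point implant contains a 3-point called run falls with k:
≈ 0.95 at k = 5, ≈ 0.99 at k = 6–7, > 0.997 at k ≥ 8. The ≥ 99%
recovery guarantee tested over 1,000 embryos therefore holds at the
default length range; very short implants near the 3-point limit are
detected less reliably by construction — the calling rule is
deliberately conservative.

Image rendering places a Gaussian-cross-section midline (SD
`line_sigma`, default 5 px) whose on-path peak equals the generating
trace value at the nearest path point, atop a cytoplasm haze inside a
specimen mask and the slide offset everywhere. For z-stacks the base
image is shared across slices and only the midline bump is attenuated
away from the central slice, so the max-projection reproduces the
single-plane rendering exactly. With the default `line_sigma`, the
2-px-wide extraction recovers the generating trace within 1% at zero
noise; a much narrower midline would be attenuated by the width
averaging itself.

What the generator does **not** emulate: optics (PSF anisotropy,
photobleaching, depth attenuation), spatially correlated noise, midline
curvature in z, intensity gradients along the intestine, or
segmentation/annotation error in interface positions. Passing tests
therefore demonstrate the correctness and calibration of the
measurement and calling logic under the stated noise model, not
robustness to every property of real microscopy data.

## Reproducibility and problem sizes

All randomness flows from explicit integer seeds; cohort generation
expands one root seed into per-embryo child seeds, and re-running any
pipeline command with the same config and seed reproduces every output
byte for byte. The test suite uses cohort sizes matching the study
design it mirrors (22 control / 18 depleted embryos, 7–8 time-lapse
embryos, 200-point traces), 1,000 embryos for the recovery suite,
10,000 draws for calibration checks, and exhaustive Fisher enumeration
to table total 60 — sizes chosen so every suite completes in a couple of
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted tolerances.

## Known limitations

- Interface positions must be provided; there is no membrane
  segmentation or automatic midline tracing.
- The colocalization and multi-site-counting rules are documented
  choices where the underlying scoring was manual or under-specified.
- Sub-point gap boundaries are not refined; a gap's extent is quantized
  to the sampling grid.
- The Gaussian, independent-noise background model is an idealization;
  heavy-tailed or correlated background would make the 2-SD threshold
  cover less than Φ(2) and inflate false positives.
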