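# Methods

## Model and definitions

A time-lapse stack is a single-channel grayscale array `(time, y, x)` with a
frame interval (30 or 60 s) and a pixel size supplied by the caller; vendor
metadata is never parsed. Times are minutes from frame 0; coordinates are
0-based `(row, col)`.

**Spore detection (step 1).** Dormant spores are phase-bright. Frame 0 is
thresholded (researcher-set bright threshold, or Otsu's method by default),
connected components are filtered to a configurable area range, and each
component becomes a marker ordered deterministically by centroid. Touching
spores are kept as one marker rather than split: the analysis targets
isolated spores, and merged objects get censored at collision later. Manual
exclusion lists are applied by id and recorded.

**Germination event (step 2).** The centre trace is the mean over a disk of
radius `center_radius_px` (default 2 px, the scale of a spore core at
100× / ~0.065 µm/px) at the marker centroid. A spore is a candidate only
if the trace ever falls below the dark threshold (default: background median
minus a quarter of the bright/background contrast). The settled plateau
intensities are medians: the pre-plateau is estimated in two passes (median
of the first 5 frames, then all frames before the first drop of more than
`settle_tolerance` below that estimate), the post-plateau spans up to 10
frames starting at the first frame within `settle_tolerance` of the trace
minimum. The drop range is `I_pre − I_post`; the start of germination is the
last down-crossing of the 90% level before the transition midpoint and the
end is the first down-crossing of the 10% level after it, each linearly
interpolated, so timing is sub-frame. A trace already below the dark
threshold at frame 0 is flagged pre-germinated and excluded from timing
statistics. Traces that recover towards the bright plateau after the
transition are processed on their first sustained drop with a warning.

**Growth tracking (step 3).** Each frame is segmented globally:
`|frame − background| > area_threshold`, with the background taken as the
per-frame median intensity (spores and colonies cover a small minority of
pixels). The threshold defaults to half the bright/background contrast so
both phase-bright spores and phase-dark colonies segment. Components are
associated to markers by maximal overlap with the previous frame's
component, falling back to the component at (or within 5 px of) the seed. A
germinating spore necessarily crosses the background intensity mid-transition
and briefly vanishes from this segmentation, so a component may go missing
for up to 5 consecutive frames before the trace is censored as lost; the gap
frames simply record no area. Measurement stops — is censored, half-open,
the censoring frame excluded — at the first frame where the component
dilated by `collision_margin_px` (default 2 px) overlaps another tracked
component or the image border, or where two markers resolve to the same
component.

**First division.** Automatic detection scans the tracked footprint (from
the end of germination) for the first frame where a watershed split of the
distance transform yields ≥ 2 basins, each at least `min_spore_area_px`,
persisting for two consecutive frames. The peak separation scale is
`0.6 × sqrt(area/π)`, which merges the plateau of a single convex footprint
but resolves a two-lobe one. The underlying protocol is a manual call, so a
manual division table overrides per spore and the output records the source.

**Outgrowth time** is first division minus end of germination; a negative
value means inconsistent annotations and raises.

**Coat burst.** Within (end of germination, first division], a frame-to-frame
relative area increase ≥ `burst_jump_fraction` (default 0.2) that also
exceeds the local growth trend (median frame-to-frame ratio in a ±5-frame
window) is reported as a burst.

**Generation time.** Ordinary least squares of `log2 A` on `t` (minutes)
over the fit window; the slope is in doublings/min and the generation time
is `1/slope`. `r` is the Pearson correlation of the fit; fits with
`|r| < fit_min_r` (default 0.99) or non-positive slope are flagged and
contribute no generation time. The automatic window starts at first
division and grows in 10-frame blocks: each new block must stay within the
rasterization tolerance of the straight line fitted to the window so far,
where the per-point tolerance is the log2 effect of a perimeter-sized area
error, `log2(1 + sqrt(πA)/A)`. This tolerance shrinks as the colony grows,
so a plateau is caught within about one block, while the pixel-quantised
areas of a small young colony (which can sit constant across a whole block
during perfectly exponential growth, making any per-block correlation test
meaningless) do not end the window spuriously. Manual windows override.
Vegetative mode runs the same tracking and fitting for cells marked at
t = 0, with the window starting at the beginning of the movie.

**Population statistics.** Fractions of germinated (= outgrown +
germinated-but-not-outgrown) and outgrown spores are percentages of all
assessed (non-excluded) spores; timing metrics are distributions over the
spores where the event was actually measured, so n varies per metric — in
particular, the number of spores contributing timing statistics can be
smaller than the germinated count, because only detected events with valid
settled plateaus contribute. Distribution fits are maximum-likelihood
normal or lognormal with the log-likelihood returned for family selection.
Two conditions are compared per metric with a two-sided variance-ratio
F-test; if it does not reject at α = 0.05 the pooled t-test is used,
otherwise Welch's. The significance level is fixed at 0.05 and no
multiple-testing correction is applied across the four metrics.

## The simulator

The synthetic-movie module is the test bed: bright disks (default intensity
180) on a mid-gray background (100) with germinated material dark (40).
Germination is a logistic intensity drop centred at
`t_start + duration/2` with scale `duration/(2 ln 9)`, chosen so the 90% and
10% crossings of the drop range fall exactly at the scripted start and end —
the timing definition holds for ground truth by construction. Colony areas
follow `A(t) = a0 · 2^((t − t_div)/G)` exactly; footprints are rendered as a
filled disk before division and two overlapping disks (centres 1.6 lobe
radii apart, analytic union area equal to the scripted area) after, which
is the minimal geometry that exercises contour tracking, watershed division
detection and collision censoring. A coat burst is a single-frame relative
area jump. Gaussian pixel noise is added last; one seed drives placement
and noise.

Population sampling uses deterministic fate counts (`round(fraction · n)`),
so scripted fractions are exact, with the default parameters describing an
untreated heat-activated population (94.0% germinating, 84.7% outgrowing,
start of germination mean 63 min sd 56, germination time 3.5 ± 0.9 min,
outgrowth 254 ± 34 min, generation time 62 ± 14 min) and a wet-heat-stressed
preset (52.9% / 36.3%, start 82 ± 68 min, germination 5.3 ± 1.7 min). Start
times are drawn lognormal at those moments: with sd of the order of the
mean, a normal would put ~13% of its mass below zero, and start-of-
germination distributions are the canonical lognormal candidate among the
two families used here. Durations are normal truncated at 0.5 min.

What the simulator deliberately omits: phase-halo optics, shading, focus
drift, intra-colony cell resolution, and irregular colony shapes. Passing
tests therefore validate the measurement chain's logic and numerics — event
timing, censoring, fitting, statistics — not robustness to real optical
artefacts, which still requires the manual-override paths on real data.

## Numerical choices and problem sizes

- Crossing times are interpolated on the bracketing segment, so a step
  transition between two frames yields a duration of 0.8 frame intervals
  (the 90%→10% fraction of the segment), never zero.
- Recovery checks use noise-free movies rendered at 120–280 px fields and
  160–420 frames, sizes at which every stage's tolerance (one frame interval
  for germination timing, two for division) is dominated by rasterization,
  not runtime compromises; the statistical calibrations use 200–1000
  Monte-Carlo replicates.
- With 5% multiplicative area noise, a fit's attainable `|r|` is bounded by
  the window's dynamic range: `r > 0.99` requires spanning about 1.75
  doublings or more. Generation-time recovery populations are therefore
  fitted over 4-hour traces (241 one-minute points), the scale colonies are
  actually followed for; there the median absolute relative error is ~0.2%
  and every fit exceeds `|r| = 0.99`.
- The F-then-t protocol's type-I error calibrates to 5% within ±1.5% over
  1000 null replicates. Its power at the untreated-vs-stressed
  start-of-germination moments (63 ± 56, n=171 vs 82 ± 68, n=152) is
  analytically ~0.78 (`z = 19/sqrt(56²/171 + 68²/152) = 2.72`), and the
  Monte-Carlo detection rate lands there; a 19-minute shift at those
  variances is simply not a ≥95%-power effect at these sample sizes.
- All randomness flows from one integer seed (split into per-stage child
  seeds); reruns with identical inputs and seed are byte-identical in every
  CSV output.

## Known limitations

- Colony area proxies total cell mass including inner gaps; the generation
  time is the colony-average, not any individual cell's.
- Stage drift is assumed negligible; markers do not track across drift.
- Merged objects at t = 0 are not split.
- The automatic division detector assumes the first division produces a
  footprint with a visible waist; filamentous or stacked growth defeats it
  (use the manual division table).
- Multi-channel/fluorescence stacks are out of scope.
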