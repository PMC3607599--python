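# sporetrace

Quantitative analysis of bacterial spore germination and outgrowth from
phase-contrast time-lapse microscopy.

Dormant *Bacillus* spores are phase-bright: their dehydrated core scatters
light into the phase ring. When a spore germinates it takes up water,
releases dipicolinic acid and turns phase-dark; the emerging cell then
bursts out of the spore coat, divides, and grows into a monolayer
microcolony. These transitions are highly heterogeneous between individual
spores — some germinate within minutes, some after hours, some never — and
that heterogeneity is what makes the behaviour of spores in, say, pasteurised
food so hard to predict. `sporetrace` turns a time-lapse image stack of a
field of spores into per-spore event times and population statistics, and
includes a forward simulator with per-spore ground truth so every stage of
the measurement chain can be validated end to end.

## The measurements

For each spore detected in frame 0 of a stack (one frame per 30 or 60 s,
several hours long):

- **Germination timing.** The mean intensity of a small disk at the spore
  centre is traced over time. The *drop range* is
  `I_pre − I_post`, the difference between the settled intensities before and
  after the bright→dark transition. Germination starts when the trace
  crosses `I_post + 0.9·drop` and ends at `I_post + 0.1·drop`, both linearly
  interpolated between frames; the **germination time** is the 90%→10%
  crossing interval.
- **Outgrowth time.** Time from the end of germination to the first cell
  division. Division is detected automatically as a persistent
  watershed split of the tracked footprint; a manual override table takes
  precedence and is recorded in the output.
- **Generation time.** The colony footprint area `A(t)` doubles once per
  generation during balanced growth, so `log2 A(t)` is linear in `t` and the
  generation time is `1/slope` (slope in doublings/min). The fit window runs
  from first division to the end of the linear part; fits must reach
  `|r| ≥ 0.99` to be accepted. Measurement of a colony is **censored** at
  the first frame where it would touch another colony or the image boundary.
- **Coat burst.** A jump-like single-frame area increase during outgrowth,
  reported when it exceeds both a configured fraction and the local growth
  trend.
- **Fate classification.** Each spore ends as `outgrow`,
  `germinate_only`, or `dormant` (plus bookkeeping fates `pre_germinated`
  and `excluded`); populations are summarised as % germinated and % outgrown.
- **Two-condition comparison.** Per metric, an F-test on the variances
  selects the pooled or Welch t-test for the means, both at α = 0.05.

A vegetative-cell mode skips germination detection and fits generation
times of cells marked at t = 0.

## Worked example

`examples/growth_fitting.py` renders one outgrowing spore (germination at
10 min lasting 4 min, first division at 60 min, generation time 40 min),
tracks it and fits the growth:

```
first division detected at 60.0 min (scripted 60.0, source=auto)
fit window 60-140 min, 160 points
generation time 41.0 min (scripted 40.0), |r| = 0.9911
```

The division frame is recovered exactly, and the generation time to 2.5%
(the residual error is area rasterization on a colony a few pixels wide).
`examples/population_comparison.py` classifies two scripted populations at
realistic scale and compares their start-of-germination distributions:

```
control:  94.0% germinated, 84.9% outgrown (n=218)
stressed: 52.9% germinated, 36.3% outgrown (n=325)
drop: 41.1 pp germinated, 48.6 pp outgrown
start of germination: 63+-59 vs 86+-65 min; F p=0.175 -> pooled t-test, p=0.0007
```

The other examples show the simulator (`simulate_movie.py`), sub-frame
germination timing (`germination_timing.py`), and the full two-condition
pipeline over rendered movies (`full_pipeline.py`).

## Command line

```
sporetrace simulate --out sim/ --n-spores 90 --population control --seed 1
sporetrace analyze --manifest stacks.csv --out analysis/
sporetrace compare analysis_a/records.csv analysis_b/records.csv
```

`analyze` takes a manifest CSV (`path,condition,frame_interval_s,pixel_size_um`)
and writes a master per-spore record table, per-condition summaries,
F-then-t comparisons, deltas, and overlay/histogram plots.

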