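# Methods

This note documents the models, the numerical choices and the synthetic
study system, in the order the pipeline runs them. It states what each
stage assumes and what the tests do and do not demonstrate.

## Rain-event classification

A rainfall record (1-min depths, 0.1-mm quantisation) is segmented into
maximal wet episodes separated by at least 8 h of strictly zero depth; an
episode qualifies as a rain event iff some sliding 8-h window inside it
accumulates strictly more than 1 mm. Decisions worth making explicit:

* *Sliding* (not anchored) 8-h qualification window — the stricter reading;
  an anchored window would only relabel borderline drizzle episodes.
* "Dry" means exactly 0.0 mm recorded; the gauge quantisation makes a
  depth-epsilon redundant.
* A gap of exactly 8.0 h terminates the event; a total of exactly 1.0 mm
  does not qualify.
* Event start/end are the first/last wet minutes of the merged episode.

A sampling event needs at least one instrumented inlet above its stage
trigger during the event window; the downstream samplers (collector shaft,
stream) require two triggering inlets. Missing stage data yields an
*unknown* trigger, never a false one.

## Surface-runoff connectivity

Terrain conditioning carves road cells down by `road_carving_depth`
(default 0.15 m, Monte Carlo range 0.05–0.30 m) — roads concentrate runoff
through ruts and verges that a 2-m DEM cannot resolve — and fills
depressions by priority-flood with a 1e-6-m drainage increment. A filled
depression whose required fill depth exceeds `sink_fill_depth` (default
0.10 m, range 0.02–0.25 m) is reverted and acts as an infiltration sink.

Flow directions follow Tarboton's D-infinity construction: the steepest
descent over eight triangular facets, flow split between the two facet
neighbours in proportion to the angular position. Contributing areas route
each cell's unit area down this field until a destination absorbs it
(inlet cells, stream cells, an optional WWTP mask, or sinks — including
flow that would leave the grid). Cells get the hard label of the
destination receiving their largest share (the field reports crisp
contributing areas); fractional shares are kept for area accounting, and
the per-destination fractional areas partition the catchment exactly.
Receivers with positive weight are strictly lower than their source, so
processing cells in elevation order is a valid topological order; the
routing is validated against exhaustive path enumeration on small grids
(1e-9).

The 100-m spray-drift radius is measured as Euclidean distance from the
plot polygon (boundary, equivalently the polygon for exterior points) to
the site point; "roads draining to the site" are road cells whose D-infinity
destination is that site, so the drift rule reuses the same terrain model.

Parameter uncertainty: 100 Monte Carlo runs redraw both conditioning depths
uniformly from their ranges and re-execute the full delineation; the
reported quantities are the per-run fractions of agricultural area draining
directly to the stream, via inlets, or into sinks, with median and
quartiles.

## Discharge

The weir rating is a power law `Q = a·h^b` (stage h in cm, Q in L/min) with
defaults a = 0.2694, b = 2.659 chosen so that the two field anchors hold
simultaneously: 2 cm ↔ ~1.7 L/min and 3 cm ↔ ~5 L/min. The calibrated
range ends at the stage giving 0.5 L/s (~5.9 cm). Above it, the truth is
unknown, so three scenarios continue the power law with exponent
multipliers ×0.8 / ×1.0 / ×1.2 (configurable); they coincide below the
limit and diverge monotonically above it, giving ordered event-volume
triples under trapezoidal integration over the event window plus a 2-h
recession tail (the record is minute-resolved; the tail captures inlet
recession after the last wet minute).

Stream quickflow uses the Lyne–Hollick recursive filter,
`f_k = α f_{k-1} + (1+α)/2 (Q_k − Q_{k-1})` clamped to [0, Q_k], in the
standard three-pass forward–backward–forward scheme with the first
quickflow value set to 0. The filter parameters (0.9 / 0.925 / 0.95)
describe recession at the scale of tens of minutes to hours, so the 1-min
stream record is averaged to 15-min steps before filtering; quickflow
volume is then non-decreasing in α on storm hydrographs, making the three
parameters a low/moderate/high quickflow estimate. Stream discharge
uncertainty is neglected — the relative uncertainty of the inlet rating
dominates.

Ratios pair bounds conservatively: r_Q,fast,min divides the inlet *minimum*
sum by the *high* quickflow estimate, and vice versa, so the triple brackets
the ratio. Catchment extrapolation scales the four measured inlets by
(total / sampled) connected road area, connected agricultural area, or
inlet count; a zero sampled weight marks the method unavailable rather than
producing an infinity.

## Loads under censoring

A concentration below the substance LOQ is interval-censored in [0, LOQ].
Event loads are triples f = (Q_min·c_min, Q_mod·c_min, Q_high·c_max) — the
moderate estimate deliberately uses the censoring lower bound, so the
moderate load of a fully censored sample is 0. Load ratios cross-pair the
bounds; a fully censored stream sample makes r_high undefined (division by
f_stream,min = 0), which is flagged, and such cells are excluded from the
per-cell mean aggregate with the exclusion count reported. The per-cell
mean (r_f,μ,subst) averages over all included cells, detections or not;
the sum aggregate (r_f,μ,sum) needs no exclusions because the bound sums
stay positive.

Uncertainty attribution holds one source at its moderate value: discharge
frozen at Q_mod isolates the LOQ contribution to the max–min spread,
uncensored concentrations frozen at c_min isolate the discharge
contribution; shares are partial/total spread. The two shares need not sum
to one.

Grab samples (taken from the stagnant water when an event produced runoff
below the sampling trigger) substitute for the missing composite at the
event concentration — within-event concentrations in road runoff are
approximately constant, so a single sample represents the event. A flag
preserves the sample type.

The load analysis is restricted to events with full downstream sampling,
ranked by the concentration sums measured in the inlets (default: the top
three such events); this mirrors selecting the events for which the stream
record is temporally resolved enough for load integration.

## Concentration model

Response: log10 of the inlet concentration, censored values substituted by
the LOQ before the transform (consistent with the concentration summaries;
LOQ/2 is available as an option). Fixed effects: days since the most recent
application with transport potential to that inlet (falling back to the
most recent in-catchment application), log10 cumulative mass applied, log10
K_foc, DT50_water, DT50_soil, log10 event discharge, and the 4-level
transport category (reference A); random intercept per inlet; REML
estimation via statsmodels `MixedLM`. The frame keeps only substances with
properties available and at least one application inside an inlet's
contributing area; rows without any prior application, with zero applied
mass or zero event discharge are dropped and counted.

K_foc and K_ow are near-collinear for realistic panels. When their
correlation exceeds 0.7 the model is fitted twice by maximum likelihood,
deleting each covariate in turn, and the one whose deletion yields the
lower AIC is removed (for a causal K_foc with K_ow a noisy proxy, this
removes K_ow in ≥95% of simulation seeds at a 40-substance panel).

Fixed-effect p-values are Wald normal-approximation values. A
Satterthwaite-style denominator-degrees-of-freedom correction would be
preferable at few grouping levels, but no installed backend provides it for
this model class; with the row counts the pipeline produces (hundreds of
rows, 4–6 inlets) the approximation error is small, and the test suite
cross-checks the fixed effects against an lme4 REML fit. A singular fit
(random-intercept variance collapsing to zero) is flagged and reported as
variance 0.

## The synthetic study system

The generator emulates the study conditions, not any specific landscape:

* **Geometry.** 150×250 cells at 2 m (~0.15 km²) by default — a scaled
  footprint that preserves per-object density rather than absolute area,
  since every statistic the pipeline computes is a ratio or a per-object
  property. 158 inlets on a network of horizontal farm tracks (one concrete
  road), field plots tiling the bands between roads, the stream along the
  bottom edge. The DEM is a 5% mean slope toward the stream plus a small
  lateral gradient (so carved road trenches drain along-road) plus
  correlated Gaussian micro-relief (σ = 0.20 m, 5-cell correlation) and
  optional explicit pits.
* **Rainfall.** Poisson storm arrivals (0.30/day) over 1 Apr–19 Aug,
  lognormal totals (median 3.5 mm, σ_log = 1.0, capped at 45 mm) and
  durations, gamma-shaped intensity profiles, quantised on the cumulative
  curve to 0.1 mm so light rain survives quantisation. The default window
  yields 31–46 classifiable events across seeds (37 at seed 1).
* **Applications.** 1–4 applications per substance at 0.02–0.3 g/m² on
  random plots, dates clustered in spring; at least 96% of the total mass
  falls inside the study window by construction, the remainder is placed
  before it.
* **Hydrology.** Event-scale runoff coefficients per surface class
  (concrete 0.8 > farm track 0.5 > field 0.15) applied to the rainfall
  excess over a per-inlet activation total drawn from 1.3–3.6 mm — the
  study's observed activation range. Hydrographs are piecewise-linear
  triangles on the minute grid (their trapezoidal integral is exact, which
  is what makes the noise-free recovery test meaningful to 1e-12). The
  stream carries all inlet runoff times a factor 3 for other fast sources
  (drainage, urban runoff, pre-event water) plus constant baseflow
  (300 L/min). A snowmelt flag can mark the first event with amplified
  road runoff.
* **Concentrations.** Soil wash-off pools per (application, destination)
  decay at ln2/DT50_soil and release 0.5% per active event (road-deposited
  drift: 80%); spray drift deposits 0.2% of the applied mass within 100 m
  (split equally over eligible destinations); rare background pulses
  (p = 0.01) emulate spills and unreported use; each inlet's stagnant water
  retains 20% of every load and re-emits half of the stored pool per event
  (the reservoir mechanism), decaying at ln2/DT50_water between events.
  Concentration = load/volume with multiplicative lognormal noise
  (σ_log10 = 0.2); values below the substance LOQ (20 ng/L by default) are
  recorded censored with the LOQ retained. With these rates roughly half
  of all sample values are censored and maxima reach a few hundred µg/L.
* **Ground truth.** True per-site loads (application-derived and total),
  volumes, category labels (computed with the same contributing-area map
  and predicates the analysis uses), the mass-balance accumulator, and the
  full contributing-area map.

What the generator does **not** emulate: within-event chemographs (inlet
concentrations are constant per event, following the constant-concentration
observation for road runoff), wind-driven drift physics, soil erosion and
particulate-phase transport, tile-drainage chemistry, and sampler bias
between water-level- and time-proportional compositing. Passing tests
therefore demonstrate that the analysis chain is internally correct and
recovers known inputs under the stated mechanisms — not that those
mechanisms capture every process in a real catchment.

## Problem sizes used by the tests

The acceptance tests run the full pipeline on reduced grids (50×80 to
60×100 cells, 24–40 inlets, 4–6 substances) so that 100-seed studies
complete in minutes; the equation and routing oracles run at 10⁴ random
fixtures and ≤8×8 grids. The acceptance script runs the default-scale
system (150×250, 158 inlets, 12 substances, 100 Monte Carlo runs). These
sizes are package defaults chosen for tight feedback loops; all of them are
configuration, not code.

## Known limitations

* The rating-scenario exponents (×0.8/×1.2) are a documented stand-in for
  a calibrated extrapolation envelope; with field data they should be fit
  per weir.
* Interval censoring is handled by bounds and substitution, not by a
  likelihood-based censored regression; the LMM inherits the LOQ
  substitution.
* Hard majority-rule contributing areas discard sub-cell flow splitting at
  reporting time (fractional areas are kept internally).
* The collector shaft is modelled as the union of its member inlets; real
  collector shafts also receive tile drainage, which is represented only as
  an attribution annotation, not as a flow path.
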