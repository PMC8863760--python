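# Methods

## Model

A stimulus is a set of `n` shaped elements inside a circular or square
arena of radius `r` (half the side, for squares), described in continuous
Cartesian stimulus units with the origin at the arena centre and the y axis
up.  "Pixels" appear only at render time: the constraint mathematics is
never quantised to a grid, and a pixel target is simply a target in
stimulus units that the renderer later maps one-to-one (or to any other
scale) on the canvas.

The six controlled variables are numerosity `n`, mean pairwise
centre-distance `ID`, perimeter-based convex-hull area `CH`, density
`D = n/CH`, total area `TA`, total perimeter `TP`, plus the per-element
size `R`.  `CH` is computed as the hull of sampled perimeter points — 256
per element by default, with polygonal shapes always contributing their
exact vertices.  A regular 256-gon underestimates a disc's area by
`1 − (N/2π)·sin(2π/N) ≈ 1.0×10⁻⁴` relative, comfortably below the finest
tolerance regime the generator is asked to certify (1×10⁻⁶ relative on the
*mean*, 1×10⁻⁶ of slack per array being the refinement stopping band);
doubling the sampling changes the result by less than 0.01%.  For `n = 1`
the hull degenerates to the element itself and its exact area is returned,
and `ID`/`D` raise a typed `UndefinedDescriptorError` rather than returning
a NaN that would propagate silently into constraint checks.

## Feasibility rules

At most one spatial target (ID, CH or D) and one magnitude target (TA or
TP) can be active.  TA+TP is rejected because the two scale as `R²` and `R`
respectively; CH+D is rejected because they are one degree of freedom;
D-targets are rewritten internally as `CH = n/D` so the sampler handles only
ID and CH.  A Gaussian radius policy with `sigma = 0` is normalised to the
equal-radius policy.  A constraint set with no targets at all is legal and
yields plain uniform arrays.  CH (and hence D) targets require `n ≥ 3`: the
centre-stage hull of one or two points has zero area, so the two-passage
scheme below has nothing to calibrate.

## Generation pipeline

**Centre sampling.**  Candidate centres are drawn uniformly inside the
arena, shrunk by an edge margin equal to the expected maximum element
extent (computed from the radius policy, or from the closed-form
equal-radius solution when a magnitude target fixes it) so that shaping can
never push an element across the boundary.  When a spatial target is set,
each draw is calibrated by the exact homothety about its centroid that maps
the descriptor onto the target — ID scales linearly with the configuration
scale, the centre hull quadratically — and is then rejected if the
calibrated points no longer fit inside the margin-reduced arena or violate
the optional `min_gap`/`max_gap` neighbour-distance limits.  Pure
reject-only sampling would need on the order of 10⁶ draws *per accepted
configuration* at a 10⁻⁶ relative band; the calibrate-then-test form keeps
the seeded generate-and-test character (acceptance still depends on the
arena-fit test) while making tight tolerances cheap.  A configurable cap
(10⁶ raw attempts per configuration) turns pathological settings into a
loud `BudgetExhaustedError` carrying the best candidate found.

**Radius policies.**  `equal` gives one common radius (solved from the
magnitude target when present); `free` draws uniformly from a configurable
range (default 1–5 units); `gaussian` draws from Normal(mean, sigma)
truncated to the pins via the analytic truncated-normal sampler.  When
`fixed_min`/`fixed_max` pins are set, the smallest and largest draws are
replaced by the pin values exactly, so Rmin and Rmax are bit-identical
across arrays and numerosities.  Pins are assigned to the currently
smallest/largest draws to distort the Gaussian sample minimally, and sigma
is a property of the *draw*, not of the post-fit radii.

**Magnitude fitting.**  TA and TP targets are met in closed form by
scaling the free radii by `sqrt(target/current)` resp. `target/current`.
Pinned radii never move; the residual target is solved over the free ones,
and a rescaled free radius that would cross a pin is clipped onto it and
the scale re-solved (the loop pins at least one radius per pass, so it
terminates in at most `n` passes).  If the pins alone meet or exceed the
target the configuration fails with `PinsExceedTargetError`.

**Hull refinement.**  Shapes extend outward from their centres, so the
shaped hull exceeds the centre hull the sampler calibrated.  With a CH
target, every centre is moved towards the unweighted centre of mass by a
constant fraction (default 0.005) of its current distance per iteration —
a homothety, which preserves the configuration's shape and all ID ratios —
until the perimeter-based hull is inside the tolerance band.  A step that
would land below the band is halved and retried; the hull area is monotone
non-increasing throughout, and the step only ever shrinks, so the
procedure terminates inside a band of any width (iteration cap 10⁴).
The unweighted mean was chosen as "centre of mass" because it is the
definition under which the homothety is exact.

**Overlap.**  Two visibly fused elements read as one, so pairwise
boundary disjointness is enforced by default (`allow_overlap=False`):
exact centre-distance tests for all-circle arrays, shapely polygon
intersection otherwise (circles approximated by 128-gons there).  A
configuration that overlaps after shaping, or is forced to overlap during
refinement, is returned as `discarded` with its reason; `generate()`
replaces discarded configurations with fresh samples and reports
`sampled = kept + discarded`, so the discard rate is never hidden.

## Determinism

All randomness flows from `ConstraintSet.seed` through two
`numpy.random.SeedSequence` children (one for centre sampling, one for
radius draws), so identical constraint sets give bit-identical stimuli.
Rendering uses no randomness at all; identical inputs give byte-identical
PNGs.  Protocol sequences are seeded the same way.

## Rendering

The canvas is specified in pixels *and* physical centimetres
(`canvas_px`, `canvas_cm`), and the arena's desired physical diameter
(`arena_cm`) fixes the units→pixel scale; with `arena_cm=None` the arena
auto-fills 90% of its panel.  Paired layouts split the canvas evenly with
a configurable gap.  Anti-aliasing supersamples 4× and box-filters down;
a hard-edge mode produces exact binary masks.  Filled discs are drawn with
a half-pixel inset compensating the rasteriser's boundary convention,
which brings the integrated pixel mass of a disc within ~0.2% of `πR²` at
1 px/unit.  Metadata tables copy the stored `achieved` values verbatim —
they are never recomputed, so file and in-memory audit cannot drift.

## Protocols

The sequencer is display-agnostic: it emits deterministic trial tables
(CSV) that any presentation layer can execute.  Habituation trials sample
exemplars without replacement within a cycle (reshuffling when exhausted),
so continuous properties change every trial while numerosity is constant;
dishabituation must present a different numerosity.  Dual-choice sessions
counterbalance the left/right assignment to `|#left − #right| ≤ 1` and
randomise exemplars per side.  On-screen presentation and response
collection are intentionally out of scope.

## Benchmark configurations

The acceptance script generates 20 arrays per numerosity `n ∈ {5, 10, 20}`
under the joint CH = 150,000 units² and TA = 20,000 units² control with
equal radii at 0.0001% tolerance, inside a circular arena of radius 350
units (chosen so the hull target occupies about half the usable field —
large enough for acceptance, small enough that arrays do not hug the
boundary).  The congruency suite generates 10 arrays per condition of 40
equal circles at TA ∈ {600, 1200, 300} units² (balanced / congruent /
incongruent relative to a 20-element base at 600) in a radius-100 arena at
0.01% tolerance.  These pool sizes keep the full run in seconds while the
per-array errors are already at the tolerance bound; the reported values
are means of independent descriptor audits, not the solver's own
bookkeeping.

## What the generator does and does not emulate

Generated arrays reproduce the *geometric* statistics real stimuli are
controlled for.  They do not model luminance, spatial-frequency content,
screen gamma or viewing distance, and passing tests say nothing about
those; users who need equated spectra must add that control downstream.
Discard rates at high density (e.g. 20 large circles under a tight hull)
can exceed 90% — correct but slow; relax the magnitude target or allow a
larger arena if throughput matters.

## Known limitations

* CH targets need `n ≥ 3` (see Feasibility rules).
* The no-overlap test for polygonal shapes inscribes circles as 128-gons
  when mixed with polygons; contacts within ~3×10⁻⁴·R of tangency may be
  misclassified.
* `refine_to_hull` only shrinks; a shaped hull *below* the CH target (which
  cannot arise from the pipeline's own sampler, whose centre hull already
  equals the target) raises instead of growing.
* Equal-radius policies combined with both a pin and a magnitude target let
  the magnitude target win; the pins are redundant in that mode.
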