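# numstim

Controlled non-symbolic numerosity stimuli for numerical-cognition research.

When humans or other animals compare the number of items in two visual
arrays, continuous physical variables co-vary with numerosity — five dots
normally cover more surface, more contour, and a different spatial extent
than three.  Any experiment probing the approximate number system therefore
needs stimuli in which those continuous variables are fixed, randomised, or
deliberately pitted against number.  `numstim` generates such arrays with
stated-percent-tolerance control, renders them to images with exact physical
scaling, and sequences them into the two classical paradigms
(habituation/dishabituation and simultaneous dual choice).

## The controlled variables

For an array of `n` elements (circles, squares, diamonds or equilateral
triangles, each with size parameter `R` — circle radius, or side length)
inside a circular or square arena:

* **ID** — mean Euclidean distance between element centres over all
  `n(n−1)/2` unordered pairs (undefined for `n = 1`);
* **CH** — area of the convex hull of the elements' *perimeters* (for
  `n = 1`, the single element's area);
* **D** — density, `D = n / CH` (undefined for `n = 1`);
* **TA** / **TP** — total area / total perimeter, the sums of per-element
  surfaces and contours;
* **Rmin / Rmax** — optional exact pins on the smallest and largest radius.

At most one *spatial* target (ID, CH or D) may be combined with at most one
*magnitude* target (TA or TP) and a radius policy (equal, free, or Gaussian
with optional pins).  Geometry forbids more: TA grows with `R²` while TP
grows with `R`, so the two can never be fixed jointly, and D is `n/CH` by
definition.  `validate()` reports exactly which requested combination is
infeasible and why.

## How generation works

1. **Centre sampling** — uniform seeded draws inside the arena (minus an
   edge margin reserved for the element extents), each draw homothetically
   calibrated about its centroid so the spatial descriptor matches the
   target, and rejected if the calibrated configuration leaves the arena.
2. **Shaping** — radii drawn per the policy, rescaled in closed form to hit
   the TA/TP target (pins never move; the residual target is solved over the
   free radii), elements placed on the centres.  Overlapping elements would
   change perceived numerosity, so intersecting configurations are
   discarded and counted, never kept.
3. **Hull refinement** — shapes extend outward, so the shaped hull exceeds
   the centre-point hull; when CH is targeted, all centres move by small
   homothetic steps towards their centre of mass until the perimeter-based
   hull matches the target within the accepted error.
4. **Audit** — every kept array carries the independently recomputed
   descriptor values and their relative errors in percent.

## Worked example

```python
import numstim as ns

cs = ns.ConstraintSet(
    n=10,
    arena=ns.Arena("circular", 350.0),
    shape="circle",
    spatial_target={"CH": 150000.0},     # units^2
    magnitude_target={"TA": 20000.0},    # units^2
    radius_policy=ns.RadiusPolicy(mode="equal"),
    accepted_error=0.0001,               # percent
    generations=3,
    seed=1,
)
result = ns.generate(cs)
print(f"kept {len(result.arrays)} arrays, "
      f"{result.discarded} discarded of {result.sampled} sampled")
for i, arr in enumerate(result.arrays):
    a = arr.achieved
    print(f"array {i}: CH={a['CH']:.1f}  TA={a['TA']:.1f}  ID={a['ID']:.1f}  "
          f"D={a['D']:.2e}  R={arr.elements[0].R:.4f}")
```

prints

```
kept 3 arrays, 8 discarded of 11 sampled
array 0: CH=150000.0  TA=20000.0  ID=259.3  D=6.67e-05  R=25.2313
array 1: CH=150000.0  TA=20000.0  ID=262.2  D=6.67e-05  R=25.2313
array 2: CH=149999.9  TA=20000.0  ID=251.9  D=6.67e-05  R=25.2313
```

Every array hits the hull target within 0.0001% and the total-area target
exactly (equal radii admit a closed-form solution, `R = √(TA/(nπ))`); ID is
free and varies from array to array, D is pinned implicitly through CH.
The discard count is the price of the hard no-overlap constraint at this
density.

The same pipeline runs from the shell:

```sh
numstim create --config constraints.yaml --out stimuli/
numstim render --set a.json --set b.json --layout pair_horizontal \
               --canvas 800x400 --cm 20 --out pair.png
numstim sequence --paradigm dual_choice --sets a.json --sets b.json \
                 --trials 20 --seed 7 --out session.csv
```

`create` writes one PNG per array, a CSV metadata table (one row per
stimulus with all achieved values and errors), and a JSON set file that
round-trips exactly.  Congruency manipulations use
`derive_congruency_target(base_value, base_n, new_n, mode)` with modes
`balanced` (constant across numerosities), `congruent` (scales with n) and
`incongruent` (scales against n).

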