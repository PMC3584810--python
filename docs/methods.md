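# Methods

## Root-system data model

A root system is a forest of polyline roots in the rhizotron frame
(x rightward, y downward, origin at the top-left of the 50 × 50 cm face; all
lengths in cm). Each node carries a local diameter. Branching order follows
the field convention: order 1 for axes arising at the plant base, order
n + 1 for laterals of an order-n root; orders above 3 are rejected, which
matches what is observed on 20-day maize in rhizotrons. Validation checks
that the parent graph is a forest, orders are consistent with parentage,
insertion positions lie on the parent, diameters are non-negative and
coordinates finite. Fragments produced by splitting may carry parentless
laterals of recorded (or unknown) order; `validate_system(...,
allow_orphans=True)` accepts exactly that state and nothing more.

### Segment geometry

For a segment with node diameters d₁, d₂ and length L:

- lateral surface `π · (d₁+d₂)/2 · L` — a cylinder at the mean diameter,
  with no slant correction for taper. Per-segment taper is small (a few
  percent of the diameter), so the correction would be far below tracing
  error.
- volume `(π/12) · L · (d₁² + d₁d₂ + d₂²)` — the exact conical frustum.
- projected area `(d₁+d₂)/2 · L` — what a flatbed-scan mask measures; kept
  separate from the lateral surface because mask comparisons must use it.

### Merging partial tracings

`merge_tracings` translates every fragment by its registration offset, then
re-attaches each parentless non-first-order root to a candidate parent:
roots of order one less where the child's order is known, otherwise any
root of order < 3. The candidate with the smallest distance from the
child's first node to the parent polyline wins, with ties broken by
lexicographic root id (the data give no better criterion, and determinism
matters more than the choice). Attachment requires that distance to be
within `attach_tolerance`, default 0.5 cm — the registration accuracy of
aligning fragments to a hand-traced acetate sheet is a few millimetres.
The insertion position is the arc length of the nearest-point projection
onto the parent polyline; how the original interactive workflow chose the
insertion point is not documented, and projection is the natural
deterministic choice. Laterals beyond tolerance are kept as orphans and
listed in the merge report (the interactive workflow fixes these by hand);
nothing is resampled, so length and surface are conserved to machine
precision. Fragments traced with overlapping content would produce
duplicated roots; disjoint fragments are a precondition, as in the physical
protocol.

## Traits

- **Distal cumulative measures.** At arc position s on a root: the part of
  the root tipward of s (the spanning segment is clipped exactly, with
  linearly interpolated diameter) plus the whole subtrees of children with
  insertion position ≥ s. The boundary choice (≥, so a lateral inserted
  exactly at s counts as distal) is a convention; nothing downstream is
  sensitive to it.
- **Depth profiles.** Segment length is apportioned to horizontal slabs of
  `bin_size` (default 1 cm) by exact clipping, so per-order bin sums equal
  per-order totals and refinement of the bins never changes the totals.
  Horizontal segments fall entirely into the slab containing their y; a
  deepest point exactly on a slab edge belongs to the slab above it.
- **Diameter comparison.** Each root is summarized by its length-weighted
  mean diameter; orders are compared pairwise with Welch's
  unequal-variance t-test at α = 0.01 and no multiplicity correction
  (three orders give three comparisons; a correction would be cosmetic and
  the plain t-test is the field's convention). Letters come from the
  insert-and-absorb compact-letter-display algorithm on the non-rejection
  graph; orders with fewer than two roots are reported without letters.
- **Orientation.** At each node the direction is the secant over a
  centered arc-length window (default 1 cm, clamped at the ends); the
  angle is the unsigned angle to vertical-down in [0°, 180°]. The window
  suppresses node-to-node tracing noise; 1 cm is about twice the polyline
  step of typical tracings.
- **Fitter indices.** Links are internodes between branching points and
  tips. Magnitude is the tip count, altitude the longest base-to-tip link
  path, exterior path length the sum of base-to-tip link counts over tips.
  Children inserted at identical positions still create distinct link
  vertices (ordered by position, then id), so the indices are
  deterministic.

## Soil-water crossing

The analysis grid is built by exact k × k block means (`downsample_grid`),
refusing non-integer factors rather than cropping; block means conserve the
global mean exactly. The reference workflow reduces a 50 × 50 cm map to
50 × 50 pixels of 1 cm².

`distance_map` measures from pixel centers `((col+0.5)·h, (row+0.5)·h)` to
the nearest segment of the root centerline. Root radius is ignored:
lateral diameters (~1 mm) are far below the 1 cm pixel scale. Ties between
roots break to the smallest root id. The distance map is computed once and
reused for all timestamps — root growth over a three-day observation
window is negligible.

`join_soil_root` produces one row per (pixel, timestamp);
`distance_binned_series` aggregates water content into distance bins
(default 1 cm steps, 0–15 cm, with an overflow bin at ≥ 15 cm), carrying
counts and mean distances so bin means recombine exactly to the global
mean. `fit_depletion_profile` fits `W(d) = W₀ − A·exp(−d/ℓ)` to one
timestamp's bin means by weighted least squares (weights √n, abscissa the
per-bin mean distance, which removes almost all within-bin averaging bias
in ℓ).

## Synthetic generators

The generator's purpose is fixtures with known ground truth, not growth
modelling. First-order axes start at the top-center seed position — the
primary heading straight down, seminal axes at 10–35° and adventitious at
40–75° from vertical, alternating sides — and grow in 0.5 cm steps. Each
step the heading loses a fraction g of its angle to vertical (gravitropic
pull) and gains gaussian noise; defaults g = 0.02/0.01/0 per step and
noise 3°/10°/14° per step for orders 1–3, chosen so axes hold their
emergence angles across the 50 cm face (strong pull collapses every axis
into a vertical central bundle, which is not what rhizotron-grown maize
looks like) while laterals wander visibly. Laterals arise as a Poisson
process (0.8 cm⁻¹ on axes, 0.3 cm⁻¹ on order-2) outside an apical
unbranched zone (4 cm / 2 cm), one order higher, branching at 50–80° off
the parent heading. Per-order target lengths are drawn uniformly from
35–50 / 3–8 / 0.5–2.5 cm; growth stops at the rhizotron boundary. Base
diameters 0.45 / 0.20 / 0.10 cm taper linearly by 20% tipward with ~8%
per-root jitter. These diameters are deliberately on the thick side of
real maize so that laterals remain resolvable when rasterized at
5–10 px/cm; analyses that depend on absolute diameter scale should treat
them as synthetic. All draws come from one `default_rng(seed)` stream in
a fixed order (axis counts, then each axis depth-first), so output is
bit-reproducible per seed.

`split_system` mirrors the physical dissociation: one fragment per
first-order axis with its whole subtree, already registered (offsets 0).

`render_mask` rasterizes by pixel-center coverage: a pixel is foreground
iff its center lies within half the stroke width (the segment's local mean
diameter, floored at 1 px) of the segment — a stroked line with round
caps. This rule keeps the expected mask area equal to the stroked-union
area at every orientation; naive thick-line drawing is biased by double
digits at some width/angle combinations. Mask-vs-vector area comparisons
rasterize each split fragment separately and sum, as the physical workflow
scans fragments one by one precisely so that roots do not overlap; a
single whole-system mask under-counts area through root-on-root occlusion
(the acceptance script reports that occlusion ratio separately).

The water model is phenomenological:
`W(pixel, t) = clip(W₀(t) − A(t)·exp(−d/ℓ) + ε, 0, 1)` with d from the
distance map. W₀ declines linearly with cumulative daytime hours (default
0.005 h⁻¹ from 0.75; flat at night) and the amplitude A rises toward
`amplitude_max` (0.35) with a 4-daytime-hour timescale — transpiration
switches on over the morning — and is reduced by a fraction 0.3 at night
timestamps, emulating nocturnal redistribution of water from the bulk soil
back toward the depleted zone. Day is 06:00–20:00; timestamps default to
every 4 h over 72 h. ε is iid gaussian pixel noise (sd 0.01). There is no
Richards-equation physics here: no lateral redistribution dynamics, no
hysteresis, no dependence of uptake on local potential. What passing tests
show is that the *analysis chain* (downsample → distance map → join → bin
→ fit) recovers the generating parameters; they say nothing about how well
the exponential form describes real rhizotron imagery.

## Problem sizes and numerical conventions

- Depletion-recovery runs generate maps at 0.025 cm/pixel (2000²) over a
  sparse two-axis system, then block-average to the 1 cm analysis grid:
  the fine grid gives each distance bin the pixel support needed for the
  per-bin means to order strictly even at the weakest early-morning
  timestamp under pixel noise; the sparse system populates bins out to
  ~13 cm. Oracle-equivalence suites use 20–50 generated systems and
  30 × 30 grids; the mask regression uses 30 systems at 10 px/cm.
- Geometry agreement tolerances are 1e-9 cm (exact up to float error);
  conservation checks 1e-6 to 1e-9 depending on the accumulation depth.
- RSML is written with unit cm, `%.12g` floats and deterministic element
  ordering, so writing is byte-stable and read/write round trips preserve
  coordinates and diameters to better than 1e-9 cm. Declared units are
  converted on read (m/dm/cm/mm/µm/inch, divided by the optional
  `resolution`); unknown units are format errors rather than guesses.
- Degenerate inputs: zero-length roots are rejected by
  `orientation_profile`; zero-length segments contribute zero measures;
  single-node roots act as points in distance maps; empty systems are
  errors for distance maps and proportions but render as empty masks.

## Known limitations

- The merge attaches by proximity only; a lateral whose true parent is
  farther than a wrong-order candidate within tolerance would be
  mis-attached. The merge report exists so such cases can be audited.
- No deduplication of roots traced twice in overlapping fragments.
- Fitter indices treat every root as ending in a tip link; broken tracings
  (a root split into two collinear roots) inflate magnitude.
- The depletion fit assumes a single exponential profile shared across the
  map; heterogeneous substrates or overlapping depletion zones of unequal
  strength are averaged into one effective ℓ.
- 2D only: no third coordinate, no TIFF world files, no time-resolved
  growth (the generator emits final architectures only).
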