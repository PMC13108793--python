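# Methods

## The class map and its geometry

The package tessellates a bounded plot window into Euclidean Voronoi cells,
one per case, and colors cells by class. The window D is the data bounding
box expanded by `margin_frac` (default 0.05) of each axis range per side; a
degenerate zero-range axis is expanded by 1.0 absolute per side. Fixing a
finite window reproduces the visual framing of a plot panel and makes every
cell area finite.

Cells are constructed by half-plane clipping: the window rectangle is
clipped against the perpendicular bisector toward each of the point's
Delaunay neighbors (the full candidate set for small or degenerate inputs),
which yields the exact clipped Voronoi cell, since an unbounded Voronoi
cell is precisely the intersection of the bisector half-planes toward the
point's Delaunay neighbors. The Delaunay triangulation comes from
scipy/qhull; inputs it cannot triangulate (e.g. collinear points) fall back
to the all-pairs candidate set, as do all inputs with n ≤ 16, so the
degenerate textbook configurations (grids, cocircular squares, collinear
chains) are handled exactly.

**Neighbor relation.** Two cases are Voronoi neighbors when their clipped
cells share a boundary segment of positive length. The shared segment is
measured analytically on the bisector line of the pair: each cell
contributes the interval of its vertices lying on that line (membership
tolerance 1e-7 × window diagonal) and the overlap of the two intervals is
the shared length; lengths at or below 1e-9 × window diagonal are treated
as zero. This makes cocircular configurations deterministic: the diagonal
cells of a point square meet in a single point and are *not* neighbors.

Consequences worth knowing:

* Adjacency is computed from the *clipped* cells, so two hull points whose
  unbounded cells would meet far outside the window are not neighbors.
  Because the window follows the axis-aligned bounding box, a generic
  rotation of the data can change adjacency among hull cells (interior
  adjacency is unaffected); translations and quarter-turn rotations leave
  the graph identical. The test suite pins exactly this.
* Duplicate points are a hard error naming the offending case identifiers —
  cell ownership would be undefined. Callers must resolve duplicates.
* `locate` breaks bisector ties toward the lowest point index, for
  determinism.

## Voronoi islands

A case is an island when it has at least one neighbor and no neighbor
shares its label. Islands are always computed on the same classification
that fills the cells (`fill_voronoi`), never on the point-color
classification, so the subtitle metric describes the visible map. Island
status depends only on the neighbor graph and the labels; a case with even
one same-class neighbor — e.g. two discordant same-class points that happen
to be adjacent — is not an island, which is the intended behavior: the
metric measures complete local isolation, not general spatial segregation.
Rates are formatted as percentages rounded half-up to one decimal (4/80 →
"5.0%", 2/72 → "2.8%", 4/72 → "5.6%"). With a single point there are no
neighbors and the report is empty with rate 0. Missing labels are rejected
at input.

## Confidence ellipses

The ellipse is {x : (x−μ)ᵀΣ⁻¹(x−μ) ≤ c} with c the chi-squared (df = 2)
quantile at the confidence level (default 0.95; c = −2 ln(1−level)). The
default is a **data ellipse**: μ and Σ are the group's sample mean and
covariance (divisor n−1), so the region covers observations, matching
standard score-plot practice and the equation as written. A mean-confidence
variant (Σ/n) is available via `kind="mean"` for users who want the region
for the group mean — the two readings are often conflated in applied
writing, so both are exposed and the default is the one the figures show.
Groups with fewer than 3 points or singular covariance are skipped with a
warning; the plot proceeds. Boundary membership uses a 1e-9 relative
tolerance so analytically-on-the-shell points count as inside.

## Projections

* **PCA** — SVD of the column-centered (optionally autoscaled, divisor n−1)
  matrix; scores are the first two left-singular directions scaled by the
  singular values; explained-variance fractions are attached to the axis
  names.
* **PLS-DA** — PLS2/NIPALS: X autoscaled, Y the column-centered one-hot
  class indicator. Each component starts from the Y-residual column with
  the largest sum of squares, iterates to a 1e-9 relative tolerance on the
  score vector (max 500 iterations, error naming the component otherwise),
  and deflates both blocks by the X-score regression. If the class
  information is exhausted before the requested components, the remaining
  directions are driven by the residual feature structure; a fully deflated
  X yields zero scores with a warning (the single-feature case).
* **Sign convention** — every component is flipped so its
  largest-magnitude loading entry is positive; plots and tests are
  therefore bit-reproducible. Different PLS implementations may differ from
  these scores by rotation/reflection; island counts on other software's
  projections are expected to transfer only approximately.
* **Clustering** — k-means is Lloyd's algorithm with a seeded best-inertia
  restart scheme (default 100 restarts, matching the demonstration's
  parameters); single linkage is agglomerative minimum-distance clustering.
  Both are thin wrappers over scikit-learn.

## Synthetic benchmarks

The generators fix the study conditions; the same seed yields a
bit-identical dataset.

* **Two-class** (n = 80, classes 40/40, nine variables A–E, G–J): A is the
  strong separator, N(4,1) vs N(8,1); B is inversely related across
  classes, N(1.2, 0.9) vs N(4.0, 0.9); E and G are class-separated uniforms
  with bounds μᵢ ± 1 shifted by a per-class Uniform(−0.25, 0.25) jitter;
  C and D are weighted draws from the integers 1..10 with weights ∝
  position^(class index) plus N(0, 0.1) jitter (partial overlap); H is
  Uniform(0, 10) for everyone, I = 0.8·H + 1 + N(0, 0.3), and J is N(0, 1)
  noise completing the nine columns (eight letters are named; the ninth
  column carries no class signal by design).
* **Label switch**: exactly `k_per_class` (default 3) cases per class get
  the opposite label; features untouched. Selection is made on the
  generator's original class structure (stored in metadata), which makes
  the operation an involution — flipping twice with the same seed restores
  the labels — and is identical to selecting on current labels for the
  intended use (flipping a freshly generated dataset).
* **Three-class** (n = 75, classes 20/40/15): A ~ N(μᵢ, σᵢ²) with
  μ = (4, 6, 8), σ = (2, 4, 3); B uses scaled versions of the same
  parameters — both mean and spread halved, with the same 0.9 variance
  shrink (scaling only the mean would leave B too weak a separator to be
  reliably significant given these σ, contradicting its role as a class
  signal variable); E, G, C, D, H, I, J as in the two-class set. Measured
  over 50 seeds, A, B, E and G are Kruskal–Wallis-significant (p < 0.05) in
  ≥ 80% of seeds, H and I in ≈ 5–10%.
* **Permuted variant**: each column independently permuted, re-permuting
  any column with Kruskal–Wallis p ≤ α (default 0.05, max 100 tries per
  column) — the output is non-significant in all nine variables *by
  construction*, while every column keeps its multiset of values and the
  class vector is unchanged.
* **Lsun-style set** (n = 400; 150/150/100): a 1×4 vertical uniform brick,
  a 3×1 horizontal brick offset below it by a 0.5 gap, and an isotropic
  Gaussian (sd 0.35, truncated at radius 1) centered at (2.8, 2.5). The
  per-class counts of the original benchmark suite are not published;
  150/150/100 keeps two dominant bricks plus a smaller sphere. Gaps are
  large relative to within-cluster nearest-neighbor spacing, so single
  linkage recovers the classes (ARI 1.0), while the elongated bricks are
  not a fixed point of Lloyd's algorithm — brick ends are closer to foreign
  centroids — so k-means (k = 3, 100 restarts) always misassigns points and
  scores ARI < 1.

**What the generators do and do not emulate.** They reproduce the *shape*
of the benchmark conditions — sample sizes, class proportions, separation
strengths, signal/noise variable split — not any particular realization:
the original seeds are unpublished, and the exact parametrizations of the
weaker variables (C, D, E, G, H, I) are fixed here to satisfy their stated
qualitative roles. Passing tests therefore demonstrate the method's
behavior under these controlled conditions (label noise in a well-separated
projection yields islands drawn from the flipped cases; destroying class
association empties the map of structure), not performance on any real
assay, where projection quality, batch effects and class overlap dominate.

## Plotting

Three views share window, palette and legend: the ellipse scatter, the
Voronoi map (cells at `voronoi_alpha` 0.3, points overlaid), and the
combination. Dual classification is supported throughout: `color_points`
and `fill_voronoi` independently select the primary or alternative label
vector (e.g. prior classes as points over cluster assignments as cells).
The default palette is the 8-color Okabe–Ito colorblind-safe cycle in the
order orange, sky blue, bluish green, yellow, blue, vermillion, reddish
purple, grey; beyond 8 classes the cycle repeats with each full cycle
lightened toward white by an additional 30% (capped at 80%). Legend entries
follow first appearance in the data. Case labels use greedy radial
offsetting (rings of 8 angles at growing radius, accepting overlap in
pathological crowding) — label positions are cosmetic, collision handling
is deliberately simple. `label_islands_only` restricts labels to island
cases and requires `show_island_count`.

## Problem sizes and numerical choices

The replicate experiments run at the benchmark's own scale (n = 80 or 400
points; 50–60 replicate seeds for the stochastic checks), which keeps the
full suite and the acceptance script in the seconds range. Tolerances:
duplicate detection 1e-9 relative; area partition 1e-6 relative; shared
edge threshold 1e-9 × window diagonal; NIPALS 1e-9 relative; ellipse
membership 1e-9 relative. Tie-breaks: `locate` → lowest index; NIPALS start
vector → largest sum-of-squares column, lowest index on ties.

## Known limitations

* Only d = 2 and Euclidean distance; no weighted/Laguerre diagrams.
* Island status of extreme hull points depends on the window margin (their
  cells are clipped); a different margin choice can change adjacency at the
  hull, never in the interior.
* The island metric counts single-cell enclaves only; multi-point
  same-class enclaves inside foreign territory are visible in the map but
  not counted (a deliberate scope boundary).
* No significance model for island counts — the count is a descriptive,
  visualization-intrinsic quantity.
* UMAP or other external projections are supported only as precomputed
  coordinates fed through the table reader.
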