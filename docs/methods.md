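# Methods

This note documents the models, conventions and design choices behind the
package; it states nothing the tests or `scripts/acceptance.py` do not
themselves compute.

## Network substrate

The street network is an undirected planar graph N = (V, L) built from
polylines in one projected metric CRS. Nodes are created at shared
polyline endpoints (coordinates matched within 1e-6 m); an optional
noding pass (`node_at_crossings`) splits lines at interior geometric
crossings for layers that are not already noded — road data usually is,
so the default assumes noded input. Multiple connected components are
allowed; locations in different components are at distance ∞, which is a
value, not an error: such pairs are never neighbors and never exchange
kernel mass.

Points live on the network as (edge, offset) pairs, offsets in meters
from the edge's first node along its polyline. Snapping assigns each raw
x/y point to the geometrically nearest edge via an STR-tree; exact
distance ties go to the lowest edge id, making the assignment
deterministic and order-independent. Points farther than `max_snap_m`
(default 100 m, generous for GPS offsets) are flagged and excluded, never
silently dropped.

Subdivision tiles every edge with ⌈length/unit⌉ pieces — fine *lixels*
(default 40 m) as density output units, coarser *segments* (default
100 m, the usual road-management unit) as analysis units. Pieces are
half-open intervals [start, end) except the final piece per edge, which
is closed; total piece length equals total network length to 1e-9
relative.

Shortest-path distances between on-edge locations use the endpoint
decomposition d(a, b) = min over entry nodes of b's edge of
(node distance + along-edge remainder), plus the direct along-edge
candidate when both points share an edge. Inserting extra on-edge
locations as temporary nodes never changes the metric (a degree-2 node
splits an edge without altering lengths), so the insertion argument is
accepted for interface fidelity and is a no-op.

**Weight matrices.** The distance-band matrix sets w_ij = 1 when the
network distance between segment centers is within the threshold
(default 300 m). The threshold is *inclusive* (≤, with a 1e-9 guard): on
the canonical 100 m-segment corridor this yields exactly three neighbors
per side (center gaps 100/200/300 m); a strict-< flag is available. The
node-based alternative links segments sharing an endpoint location (a
graph node or a subdivision boundary). ψ = ΣΣw/(n(n−1)) and the
complement W̄ = J − W − I derive from the matrix.

## Weighted network KDE

λ(q) = (1/n) Σ wᵢ Kᵢ(q) evaluated at lixel midpoints (one-point
quadrature per lixel). Kᵢ is the equal-split kernel: the base kernel at
the shortest-path distance divided by Π (degree − 1) over intersection
nodes interior to the path (termini excluded; degree-2 nodes contribute
factor 1). Among equal-length shortest paths, the lexicographically
smallest node-id sequence defines the split product — a deterministic
tie-break that matters only on exactly symmetric geometries. The
implementation runs one Dijkstra-with-path-tracking traversal per event
out to the bandwidth radius and is contract-tested to agree with the
per-pair definition to 1e-12.

**Kernel normalization.** Base kernels (quartic default; Epanechnikov,
uniform, truncated Gaussian with σ = h/3) have compact support [0, h] and
integrate to 1 over the full support [−h, h] — i.e. ∫₀^h k = 1/2 per
direction. The kernel mass leaves an event into both directions of its
edge, and the equal-split division conserves mass at every intersection,
so on a boundaryless network a unit-weight event contributes total mass
exactly 1 (verified to 1% at 1 m lixels on a 2000 m ring, h = 200 m).
Mass is lost only at dead ends; no edge correction is applied. Kernel
*form* matters far less than the bandwidth; the default h = 200 m sits in
the 100–300 m range appropriate for urban street networks.

**Attribute weights.** Quantile-rank normalization maps the k-th largest
distinct attribute value to (k−1)(r_max−r_min)/(n_d−1) + r_min, ties
sharing a rank; n_d is the number of distinct values — the only reading
that keeps ranks in 1..n_d with several tie groups. As printed, the
formula sends the *largest* value to r_min, which is counterintuitive for
loss weighting; both directions are implemented (`order="as-printed"`
default, `order="inverted"`), and the intent is left to the analyst. A
constant attribute or a collapsed interval yields the interval midpoint
everywhere. Default interval [1, 10].

## Network cross K-function

K_ba(d) counts event–POI pairs within network distance d (strict <, as
the indicator is defined), scaled by n_a and the event density
ρ_b = n_b / total length — so K saturates exactly at the total network
length beyond the diameter. The reference points are held fixed and the
events re-simulated under CSR (edges drawn ∝ length, offsets uniform):
the question is whether events cluster around the fixed features.
Pointwise envelopes take the ⌈α/2·(n_sim+1)⌉-th curve value from each
tail per grid point (default α = 0.05, 999 simulations, grid 20–1000 m by
20 m); no global envelope correction is applied, so under CSR about 5% of
grid points fall outside the 95% band on average — the pointwise verdict
is exploratory, not a corrected test. Per-POI node-distance tables are
computed once and reused across simulations.

## Differential local Moran's I

Rate changes rᵢ = vᵢ(t₂)/L_{t₂} − vᵢ(t₁)/L_{t₁} (period lengths in days;
weekday/weekend = 5/2) are standardized with the population (divide-by-n)
standard deviation; a zero-variance change vector is a degenerate input
and is reported as such rather than silently producing NaNs. Iᵢ = zᵢ·lagᵢ
under the binary distance-band matrix; isolated segments get Iᵢ = 0, are
excluded from inference and reported NS with a flag.

**Inference.** Conditional permutation: zᵢ stays fixed, its neighbor
slots are filled with draws (without replacement) from the remaining
values, p = (1 + #as-or-more-extreme)/(1 + n_perm), 999 permutations by
default. The default `alternative="directional"` takes the tail on the
side of the observed statistic — the convention of the widely used LISA
implementations. Because the tail is chosen after seeing the statistic,
this is liberal by construction: under exchangeable noise a nominal 5%
cut rejects at ≈ 2α (measured ≈ 0.11 on the ~100-segment grid). The
`"two-sided"` alternative (twice the smaller tail, capped at 1) is
calibrated (measured ≈ 0.03–0.05) and is what the calibration checks
exercise; choose it when type-I control matters more than map
convention. No multiple-testing correction is applied by default, since
the statistic is read as an exploratory map at raw α = 0.05.

Labels: significant segments with z and lag both positive are HH, both
negative LL, sign mismatches HL/LH; exact zeros yield NS.

## GIMA / LIMA rank concordance

All concordance statistics are computed by explicit pair enumeration on
the sign matrix concordance(i,j) = sgn(Δv_t1)·sgn(Δv_t2):
τ = (C−D)/(n(n−1)/2); the tie-adjusted
τ′ = (C−D)/√((C+D+E_t1)(C+D+E_t2)) with E_t1 the pairs tied only in the
second period and E_t2 those tied only in the first (pairs tied in both
enter no count — the standard tie convention); the exact decomposition
τ = ψ·τ_w + (1−ψ)·τ_w̄ (identity holds to 1e-12 for untied data, any W);
and the three local statistics τᵢ (focal vs all), τ̃ᵢ (focal vs
neighbors; NaN for isolated segments) and τ̃̃ᵢ (all ordered pairs m ≠ n
within NS_i = {i} ∪ neighbors(i), denominator |NS_i|(|NS_i|−1); NaN when
|NS_i| < 2). The neighborhood sum runs over ordered pairs m ≠ n — the
reading consistent with its denominator; including the focal segment in
both pair slots is immaterial because sgn(0)·sgn(0) = 0. All statistics
are invariant under strictly monotone transforms of either period's
values.

**Inference.** Local: the focal pair (v_t1, v_t2) stays fixed, the
remaining pairs are jointly permuted over the other segments; directional
p by default, two-sided available, same trade-off as above — though for
the LIMA statistics the discreteness of the ±1-concordance mean makes the
directional variant measure near nominal (≈ 0.055) under a continuous
exchangeable null, since simulation ties land in both tails. Global τ_w
significance permutes segment locations wholesale (W fixed, 999 draws,
two-sided). The period-pair matrix helper assembles the symmetric k×k
τ_w table over k period vectors (e.g. the six hour-of-day bins).

## Temporal organization

Hour-of-day bins are closed-open local-clock intervals [2,6), [6,10),
[10,14), [14,18), [18,22) and [22,2), the last wrapping midnight;
weekday/weekend splits use the local calendar. Timestamps are
timezone-naive local time throughout; no timezone math is performed.

## Synthetic data

The generator emulates the study inputs: street networks (grid, ring —
the boundaryless substrate for mass-conservation checks — and connected
random planar networks from Delaunay triangulations), events sampled
uniformly by length (CSR) or with intensity multiplied on named hotspot
segments, timestamps from a 24-hour profile with a deep 2–6 trough and a
daytime plateau, and a zero-inflated loss attribute (92% zeros, lognormal
tail) mirroring the dominant-zero shape of real collision loss tables.
Two-period counts are independent Poisson draws per segment-period —
the simplest null consistent with CSR — with a planted rate multiplier on
selected segments in period 2; defaults (2 events/segment-day, period
lengths 5/2 days, multiplier 3 on 5 contiguous segments) define the
power experiments. All generation flows from `numpy.random.default_rng`
seeds and reproduces bit-identically.

What the generator does *not* emulate: real road geometry (curvature,
lane structure, complex interchanges), inhomogeneous background intensity
(traffic volume), spatially correlated counts beyond the planted signal,
and measurement error in event positions. Passing tests therefore
demonstrate correctness of the statistics and their inference under their
own null and alternative models, not performance on any particular city's
data.

## Problem sizes and experiment configurations

Calibration experiments use a 7×7 grid of 100 m cells (112 segments,
distance-band cardinality ≈ 33): 20 replicates × 999 permutations for the
Moran type-I rate; 50 replicates × 199 simulations for the cross-K
envelope exceedance. The planted-hotspot power experiment uses a
100-segment single-road corridor (cardinality ≈ 6): a contiguous
5-segment hotspot is a stretch of one road, and the corridor is the same
canonical layout as the distance-band worked example. This choice
matters: on the dense grid the same effect size is diluted over ~33
neighbors and recovery drops to roughly two-thirds of seeds — local
Moran power falls as the neighborhood grows relative to the cluster, a
real sensitivity of distance-band weights worth knowing when choosing
thresholds.

## Numerical conventions and degenerate inputs

- Endpoint noding tolerance 1e-6 m; subdivision conserves length to 1e-9
  relative; oracle agreement asserted at 1e-9 (distances) and 1e-12
  (kernel splits, concordance).
- Snapping ties → lowest edge id; equal-length shortest paths → smallest
  node-id sequence; both deterministic and order-independent.
- Zero events → valid all-zero density field; empty point sets for
  cross-K → invalid input; zero-variance changes and all-tied pair sets →
  degenerate-input errors naming the condition.
- Pseudo p-values are (1 + extreme)/(1 + n_perm), floored at
  1/(n_perm+1), never 0.
- Seeds: every stochastic routine takes an integer seed or Generator;
  identical seeds reproduce results bit-identically.

## Limitations

No edge correction at network boundaries and dead ends (kernel mass is
lost there; K-functions are uncorrected). No uniform-network
transformation, no inhomogeneous cross-K, no automatic bandwidth
selection, no planar fallback, and no space-time interaction tests. The
pointwise Monte-Carlo envelopes carry no simultaneous coverage guarantee.
Shapefile I/O is not included — inputs move as GeoJSON or CSV in a
projected metric CRS, and reprojection is out of scope.
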