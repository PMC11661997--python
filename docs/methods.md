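# Methods

This note documents the model, the parameter choices and the numerical
conventions of `curveanon`, including the points where the design was
genuinely open and what the synthetic test fixtures do and do not show.

## Data model and alignment

A curve is an ordered list of `(t, v)` samples, `t` in seconds and
strictly increasing, at least two points. A dataset of curves of one
quantity is aligned onto a common frame `[min first t, max last t]` by
holding each curve's first value back to the frame start and its last
value forward to the frame end. Padding adds at most two samples per
curve and never leaves the curve's own value range. It exists for a
privacy reason: if one member of a k-member class ended early, the
class would only be (k−1)-anonymous for the remaining time. Padded
samples participate both in distance computations and in hull
rendering; they lie inside the member's own range, so they cannot widen
a hull beyond what the member already spans.

The on-disk dialect is fixed as semicolon-delimited UTF-8 CSV with LF
endings, "." as decimal mark, three header lines (subject UUID, ISO
start datetime, `Time [s];<quantity> [<unit>]`), one value column.
Floats are written with `repr`, i.e. shortest round-trip precision, so
write→read is the identity and repeated writes are byte-identical.

## Fréchet distance

The discrete Fréchet distance (over sample sequences, not polyline
interiors) is computed by the standard O(p·q) free-space dynamic
program, vectorized over anti-diagonals: on the diagonal `i+j = const`
every cell depends only on the two previous diagonals. An independent
nested-loop implementation of the same lattice serves as the test
oracle.

Mixing seconds and signal units in one Euclidean ground distance is not
well defined, so the axis scaling is explicit: the ground distance is
Euclidean on `(t·time_scale, v·value_scale)` with `time_scale = 0` by
default — the distance is then computed on values at coupled indices of
the identically-resampled curves on the common frame, which sidesteps
the unit question while keeping the coupling (monotone traversal)
semantics. Curves on different sampling grids (the oximetry case) are
linearly resampled onto the union grid first.

## Distributions, EMD and the t bound

Distribution clustering is a greedy single pass in ascending curve-id
order: a curve joins the first cluster whose reference lies within
`s_d`, else founds a new cluster. The scan order is a convention (the
source only fixes the reference as the first member added); ascending
id keeps the algorithm deterministic. Singletons merge into the nearest
cluster, iterated to a fixed point; merged members may exceed `s_d` —
the merge rule overrides the threshold. A single-curve population
remains a singleton, having nothing to merge with.

EMD is solved exactly as a transportation linear program
(scipy/HiGHS) on unit-normalized histograms; cluster counts are small,
so exactness is cheap. Ground distances between cluster references are
normalized by the largest pairwise reference distance by default, so
t ∈ [0, 1] for any class; the same normalizer divides the estimated
bound. A single-cluster population has no reference pairs; its
normalizer is 1 and every class is trivially 0-close.

The a-priori bound treats every curve drawn from bucket `j` as if it
were the bucket reference at worst-case error `err_j` (the largest
reference-to-member distance), giving `t_i ≤ Σ_j err_j · p_j` with
`p_j` the bucket's dataset share. **Limitation:** this bound accounts
for within-bucket spread only. When per-class quotas are rounded by
largest remainder (class size 3 against a 50/50 two-cluster population
gives a 2:1 quota), the rounding itself moves probability mass across
clusters, and the exact t of a small class can exceed the bound even
under strictly proportional filling. The bound is reliable in the
regime the method is normally run in — few population clusters relative
to the class size — and the invariant tests exercise exactly that
regime; the report always carries the exact t alongside the bound.

## Trees

Bucket Tree splits use farthest-pair seeding: the two mutually farthest
members seed the children, every other member joins the nearer seed,
and members with the smallest assignment margin are moved until each
child holds at least `min(ceil(f·n), n//2)` members (the ceil rule
alone is unfulfillable for small odd buckets). All ties break toward
ascending curve ids. The child reference is its seed; the root
reference is the smallest id. The usable depth is the minimum leaf
depth — the deepest level whose nodes still partition the dataset.

ECS nodes halve their target size (±1) per level; per-bucket counts are
apportioned by largest remainder (ties toward the lower bucket index).
Splitting stops at a component of 1 or when a child target would drop
below `k`. Classes are instantiated at the ECS leaves. Consequently the
in-phase class splitting (threshold `s_eqc`) can only fire on a class
that carries a non-leaf ECS node; at the default `s_eqc = 1.0` the
mechanism is disabled anyway (the GLM never exceeds 1), matching the
default evaluation setting in which neither dropping nor splitting
occurs.

## The greedy flag

Two filling disciplines are implemented behind `Params.greedy`:

- `greedy=True` (default): each insertion takes the minimum-loss curve
  across *all* buckets with remaining data. This keeps similar curves
  together (well-separated groups come out as pure classes) and
  minimizes information loss; the proportionality to the population is
  then only approximate, and t must be (and is) measured exactly after
  the fact.
- `greedy=False`: buckets are drawn round-robin according to the
  class's per-bucket quota (the bucket lagging furthest behind its
  quota share is drawn next), the discipline the t over-approximation
  presumes.

The greedy pick inside a candidate set minimizes the class's
post-insertion GLM with ties toward the ascending curve id; note that
for an empty class every candidate ties at loss 0 (a single member has
no generalization), so the first member of a class is the smallest
remaining id.

## Phases, marking and constraints

A class is marked when it reaches its target size with at least `k`
non-dropped members; when the buckets run dry first, a class is marked
at ≥ k live members (in proportional mode additionally only if its
per-bucket takes stayed within ±1 of the quota proportions scaled to
the achieved size). Dropped members (insertion loss above `d`) stay in
the class roster — the class is their best available host — but are
excluded from the hull, GLM, MRE and t computations and are enumerated
in the report.

The "maximum cost" constraint of the redistribution phases is
operationalized as a cap on the post-insertion GLM, `max_cost`,
defaulting to `s_eqc` so that the three loss knobs stay ordered
(`max_cost ≤ d`) and the default configuration (`s_eqc = d = 1`) is
unconstrained. Unmarked redistribution dissolves the smallest unmarked
class into the other unmarked classes and stops when all are marked or
a whole iteration adds nothing (the donor is then restored, leaving the
state unchanged). Constrained marked redistribution moves what fits
into the marked classes and keeps the rest; relaxed redistribution
waives the cost cap but keeps the drop threshold, so it always empties
the unmarked queue — members that fit nowhere only exist when no
marked class exists at all, and are then reported unanonymizable.

Segments are anonymized independently (own distribution, trees,
classes; no cross-segment state), which is what allows a curve to
change classes between segments and what makes per-segment parallelism
possible. A curve may also be dropped in one segment and used in
another; cross-segment drop tracking is out of scope.

## Hulls and the report

"Hull" means the pointwise lower/upper envelope on the resolution grid
(grid step `hull_resolution`, last point clamped to the segment end) —
a true 2-D convex hull would not be a function of time, and the
evaluation metrics are defined against upper/lower bounds per time
step. Member values at grid times are interpolated linearly for
interpolable datasets, else by the previous or nearest sample. The MRE
uses the same grid as the hull. The hull is additive: merging two
classes is a pointwise (min lower, max upper).

The aggregate information loss weights each segment's mean class GLM by
its share of the total duration. The "cleaned" variant omits segments
shorter than the hull resolution (their loss is an artefact of
under-resolution) and is suppressed when the omitted segments exceed
25 % of the total duration. The dataset MRE is the median over
per-class MREs. A degenerate value domain (all values identical)
defines the GLM as 0 with a warning.

## Splitting

Fixed-length splitting keeps a final remainder shorter than the
configured threshold inside the last segment, else it becomes its own
segment. Windowed-Fréchet splitting evaluates candidate windows at
`frame_start + i·step`, scores each by the mean pairwise Fréchet
distance of the curve restrictions, and takes the lowest-mean windows
as segment start boundaries. Conventions the source leaves open, fixed
here: the boundary is the *window start*; two boundaries may not be
closer than one window length (avoiding degenerate micro-segments);
ties break toward the earlier offset; boundaries are strictly inside
the frame. Manual splitting accepts an ordered, non-overlapping
interval list and excludes gap data from the anonymization. Curve
restrictions to an interval include linearly interpolated endpoint
samples so every restriction has at least two points.

## Synthetic fixtures

The generator produces `v(t) = A·sin(2π·RR/60·t + φ) + ε` with
per-cluster rate and amplitude and per-curve jitter; the seed fully
determines the output. A sinusoid is a sufficient surrogate because
the pipeline responds only to the similarity structure, not to
waveform physiology. The emulated dataset shapes (12 curves × 8 s ×
50 Hz; 28 × 4 s × 50 Hz; 12 × 400 s at irregular 1–3 s intervals)
match the evaluation data's sizes. What the fixtures do **not**
reproduce: real ventilation morphology (inspiration/expiration
asymmetry), artefacts, sensor drop-outs, or non-stationary rates —
passing tests show the algorithmic guarantees (k-anonymity, hull
containment, determinism, bound consistency), not clinical utility on
real recordings.

Problem sizes in the test suite and acceptance script (12–18 curves,
100–400 points, up to 16 segments) were chosen as the smallest sizes
at which every mechanism (multi-level trees, multi-segment splits,
redistribution) is actually exercised.

## Numerical conventions

- All order-dependent steps scan in ascending curve-id order; every
  tie-break is documented at its site (first-fit clustering, smaller-id
  seed, lower bucket/cluster index, earlier window offset).
- Interval arithmetic uses an absolute tolerance of 1e-9 seconds;
  equality of EMD inputs uses 1e-15 on normalized masses.
- The anonymization core takes no random seed; randomness exists only
  in fixture generation.

## Known limitations

- The t bound ignores quota-rounding flow (see above); rely on the
  exact t in the report for small classes over multi-cluster
  populations.
- Greedy filling can concentrate clusters in classes, trading
  t-closeness for information loss; choose `greedy=False` when the
  proportionality guarantee matters more than utility.
- Equivalence classes are not re-optimized after the relaxed phase; a
  curve inserted late lands in the then-best class, not a globally
  optimal one.
- Republication of overlapping datasets is not protected (no
  m-invariance), and no reconstruction/perturbation of the released
  bounds is implemented.
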