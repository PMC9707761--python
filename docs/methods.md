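# Methods

## Matching model

An instance matches `n1` model vertices onto `n2 >= n1` observed
points. Costs are organized as dissimilarity tensors `Z^(d)`, one per
hyperedge degree `d`, each defined on a sparse *scope* of vertex
`d`-tuples (strictly increasing in branch order); the objective is the
sum of tensor costs at the assigned point tuples. Two contracts are
load-bearing:

* **Nonnegativity.** Every cost must be finite and `>= 0`. The
  branch-and-bound bound is the accumulated partial cost, which is a
  valid lower bound only under this contract; table entries are checked
  at construction and callable costs at every evaluation. Models with
  negative raw scores must be shifted by the caller.
* **No implicit zeros.** A vertex tuple outside a tensor's scope is an
  error, not a zero — silent zeros would mask model-construction bugs.

Indices are 0-based internally; file formats and printed assignments
are 1-based. Vertex index equals branch order (branch `b` owns vertices
`b*k .. b*k+k-1`), so "strictly increasing vertex tuple" and "charged
at the branch of its maximal vertex" are the same bookkeeping; display
names (e.g. `TL`, `V6R`) travel separately.

## Search

Depth-first branch-and-bound over branches of size `k`. Each branch
materializes the queue of feasible point `k`-permutations ordered by
the selection cost `H` (low-degree tensors, `d <= 2k`, precomputed /
memoized); expansion adds the aggregation cost `I` (lazy tensors,
`d > 2k`) for hyperedges that become evaluable at that branch. A
hyperedge is charged exactly once — at the branch containing its
maximal vertex — so the per-branch terms sum to the full objective
(asserted at 1e-9 relative tolerance in tests).

Pruning is against the pool's x-th best cost, so the returned pool is
provably the exact top-x set from a single search. Pruning is strict
(`accumulated > bound`): partial costs *equal* to the bound are kept,
because a zero-cost completion could tie the worst pool entry and win
its lexicographic tie-break. Ties everywhere are broken
lexicographically on point tuples, making pools deterministic. The
incumbent starts at +inf; an optional warm-start assignment seeds the
bound (and joins the pool if it is consistent with the seeds). A time
limit is checked cooperatively between node expansions; on expiry the
pool holds the best solutions found and `proved_optimal` is False. The
default per-sample cap in the experiment runner is four hours.

Seeds reserve their points globally: free vertices never consume a
point promised to a seeded vertex, so seeded searches explore only
seed-consistent subtrees. Queues are materialized per branch (at most
`n2!/(n2-k)!` entries; small for `k = 2`).

## Posture models

All models share branch order tail-first (`T, V6, [Q], V5, ..., H0`,
with Q between V6 and V5 at its anatomical position) and `k = 2` — one
lateral pair per branch. The first branch is steered by the
standardized tail-pair width (the tail width is nearly constant over
development, making it the most reliable anchor); unary (`d = 1`)
costs are absent from all models.

Feature families and their hyperedge degrees:

| degree | families | scope |
|---|---|---|
| 2 | lateral width; left/right side chords | each pair; consecutive pairs |
| 4 | width ratio (posterior/anterior), midpoint spacing, left-vs-right chord cosine, signed axial twist φ, unsigned axis angle τ | consecutive pair quads |
| 6 | midpoint bend angle Θ, best-fit plane intersection angle | consecutive pair triplets |
| n1 | posture-wide sums of every degree-4/6 family | the complete assignment |

Sides uses degree 2 only; Pairs adds degrees 4 and 6; Posture adds the
single degree-`n1` hyperedge. With `k = 2` the degree-6 and degree-`n1`
tensors are lazy: triplet terms accrue from the third branch on, and
the posture-wide term only at the final branch.

Angle conventions: the pair axis points left to right; features are
evaluated in branch (posterior-to-anterior) order. φ is the signed
dihedral between consecutive pair axes about the midpoint chord, in
(-180, 180], and flips sign under reflection — the one feature that
distinguishes a posture from its mirror image. Θ is the *interior*
angle at the middle midpoint (180° for a locally straight body),
consistent with bend angles opening as the embryo elongates and
straightens locally. The plane intersection angle uses
total-least-squares plane fits per pair quad and is folded into
[0, 90] because plane orientation is arbitrary. The side cosine
compares the left and right chords of the same segment: a single
scalar (comparing each side with its own next chord would need a third
pair and adds nothing the twist angles do not already measure). Angles
are stored in degrees; standardization makes the unit immaterial.

## Templates and standardization

Each feature at each body position is standardized against a
time-dependent template: `cost = weight * ((value - mean(t))/sd(t))^2`,
with per-family weights defaulting to 1 (exposed for configuration,
never learned). The squared z-score is smooth, nonnegative and
additive, which is all the solver's contract requires.

Templates are fitted from a labeled corpus: normalized time
`t = frame/(n_frames - 1)` per embryo, samples binned to the nearest
decile knot, per-bin sample mean and sd, piecewise-linear in `t`
between knots (the least-assumption interpolant), constant beyond the
sampled range. Bins with one sample borrow the corpus-wide sd (with a
warning); empty bins are interpolated from occupied ones. Spreads are
floored at 1e-6 of the feature family's corpus-wide sd (absolute 1e-6
for fully deterministic families) so that near-deterministic features
— e.g. lateral widths in a noiseless corpus — yield enormous but
finite penalties for mismatches instead of infinities. An optional
holdout excludes one embryo's samples entirely (leave-one-out
evaluation). Template files round-trip through a TSV at 12 significant
digits.

Body positions are keyed by pair names (`"T"`, `"T-V6"`,
`"V5-V6-T"`...), so templates transfer between stages wherever names
match. Extra detected points (`n2 > n1`) are simply never assigned; no
explicit outlier cost is charged. The pair count (pre-Q 10 vs post-Q
11) is an explicit caller input — the imaging protocol knows the
developmental stage, and inferring it from the point count would be
confounded by spurious detections.

## Synthetic embryos

The simulator provides the statistical structure the models assume,
with known ground truth:

* **Backbone**: a natural cubic spline through a correlated random
  walk, rescaled to arclength `L(t) = 60 + t*(170-60)` um (full-size
  default), with near-planar coiling of consistent turning sense about
  a per-draw coil axis plus out-of-plane jitter; self-approaching draws
  are rejected and resampled.
* **Pairs**: midpoints equally spaced in arclength; left/right nuclei
  at ± the per-position half-width (thicker mid-body, thin tail of
  constant 4 um width) along the local inward bend normal, rolled by a
  torsion term (0.015 rad/um), plus isotropic Gaussian jitter.
* **Repositioning**: every frame resamples the backbone independently —
  consecutive frames are entirely different postures, the regime that
  breaks coherent-transform matchers.

Orienting the left side toward the inside of the coil is the
simulator's stand-in for the embryo's consistent chirality. It
matters: on a perfectly bilaterally symmetric body, every model
feature is invariant under relabeling left and right globally, so the
mirror relabel of the truth would tie it and top-1 recovery would be
a coin flip. Real embryos are chiral; the simulator encodes that
chirality geometrically (systematically shorter inner-side chords),
which the degree-2 chord templates pick up. Bend normals are estimated
slightly inside the spline ends, where natural boundary conditions
would otherwise zero the second derivative and randomize the tip
pair's handedness.

Defaults are conventions chosen to be biologically plausible, not
measurements: 10 pairs (11 post-Q), body length 60–170 um across
development, half-widths 4–5.5 um tapering into a 2 um tail half-width.
A reduced 5-pair preset (`H0, H2, V2, V5, T`; 40–90 um) keeps
oracle-verified end-to-end tests fast while exercising every feature
family; distinctly different widths per position are what make the
zero-noise instance uniquely identifiable. What the generator does
*not* emulate: detection failures (missing/spurious points are off by
default), anisotropic localization error, intensity features, or any
real corpus's shape statistics — so passing tests demonstrate
correctness of the machinery and the qualitative model ordering, not
field accuracy on real embryos.

## Evaluation

Top-x accuracy demands the *exact* full assignment among the x
cheapest hypotheses. The cost ratio (correct cost / returned cost)
separates model failure (ratio > 1: the model prefers a wrong posture)
from search failure (impossible here when the search proves
optimality). Aggregates use medians for runtime and cost ratio.
Samples that hit the time limit still contribute their pool to
accuracy but are flagged unproven. Experiment reports exclude wall
times from the canonical JSON so fixed-seed runs are byte-identical.

Study sizes used by the tests and the acceptance script: 50 random
6-vertex instances for oracle equivalence and seeding, 100 assignments
for the decomposition identity, 20 degree-1 instances against an
independent linear-assignment solver, 20 noiseless and 50 noisy
(sd 0.5 um) reduced worms with templates fitted from a 6-embryo,
20-frame simulated corpus. The noise level is moderate by design —
roughly an eighth of the smallest lateral width — enough to degrade
the degree-2 Sides model while the hypergraphical models remain near
perfect, reproducing the qualitative ordering that motivates
hypergraphical modeling.

## Known limitations

* Exactness costs exponential worst-case time; the method targets
  small point-sets (tens of points). Larger problems need seeds or
  lower-degree models.
* The bound is the bare accumulated cost; no lookahead or relaxation
  bound is used, and the search is serial by design.
* Template estimation assumes the corpus spans the test frames' times;
  extrapolation beyond the sampled range is constant.
* Geometric degeneracies (coincident nuclei, collinear pair quads)
  raise errors rather than being priced; they do not occur under the
  generator's continuous noise model but real pipelines should guard
  their detections.
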