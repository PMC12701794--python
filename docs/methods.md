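# Methods

This note records the data model, the algorithms, the parameter choices
that matter, and what the synthetic fixtures do and do not establish.

## The tabular ARG model

A `D3ARG` holds four tables plus the genome extent `[0, L)` and style
defaults. Coordinates are 0-based, half-open real intervals, the
tree-sequence convention.

* **Nodes**: `id`, `time` (non-negative, arbitrary units — generations in
  typical use), `is_sample`, `label`, optional `pinned_x` (a normalized
  horizontal position fixed by the user), optional style.
* **Edges**: one record per `(parent, child)` pair, carrying an *ordered
  list of disjoint, non-touching intervals*. This differs from a tree
  sequence, which stores one row per contiguous interval; the converter
  merges rows sharing a pair and coalesces overlapping or abutting
  intervals, conserving total covered length per pair. Parent must be
  strictly older than child.
* **Mutations**: anchored by `(node, position)`; the owning edge is
  *resolved*, never stored, so mutation rows stay valid under edge
  merging. Resolution requires exactly one parent edge of the node to span
  the position. A mutation time, when present, must lie within the branch
  span.
* **Breakpoints**: the maximal regions within which the spanning-edge set
  is constant. Boundaries are exactly the distinct edge-interval endpoints
  plus `{0, L}`. Because intervals within an edge are always coalesced, an
  edge cannot both end and restart at a boundary, so adjacent regions
  always have different spanning sets and the table is recomputable from
  the edges (validation checks the stored copy against the recomputation).

Recombination nodes are identified structurally — any node with two or
more parent edges. The converter preserves input topology; it does not
merge the paired recombination nodes some tree-sequence encodings emit.
The alternative (collapsing pairs) would lose information, and preserving
the input is the safer contract.

`validate()` returns violations as data (table, row, rule, message) rather
than raising, so corrupted tables can be reported in full. The per-position
forest requirement (at most one parent edge spanning any position per
node) is checked pairwise on each node's parent-edge interval lists, which
is equivalent to checking every position.

## Serialization

The figure JSON (schema version "1") contains `genome_length`, the four
tables, style defaults, and optionally the layout
(`scale`/`seed`/`iterations`/`coords`) and the interaction map.
Serialization is canonical — sorted keys, rows sorted by id, compact
separators, full-precision floats — so serializing twice is byte-identical
and `from_json(to_json(x))` is the identity, including styles and pins.
This canonical byte-stability is what makes "re-render a saved figure and
get the same bytes" a checkable contract rather than a hope.

The portable TSV dump (one file per table, edges as one row per interval)
carries topology only, for interchange with tools outside the ecosystem;
floats are written with `%.17g` and parsed with round-trip precision.
Styling travels in the JSON dialect, not the TSV.

## Local trees and interaction maps

`edges_at_position(arg, p)` is a linear scan for intervals with
`left <= p < right`; positions exactly at a breakpoint belong to the
right-hand region. The scan is the reference semantics; no accelerated
index is used (profiling showed the scan adequate at fixture scale, and
any index would be required to match it exactly). The local tree keeps
unary nodes — the full-ARG drawing convention, where recombination nodes
appear as unary pass-throughs in each of their trees.

Hover behavior is precomputed as pure data (`InteractionMap`): region →
spanning edges, edge → covered regions (exact inverses), edge → mutations,
mutation → position. Since breakpoint boundaries include every interval
endpoint, each edge interval is a union of whole regions and each
(edge, region) incidence is found once by binary search. The rendered SVG
embeds these mappings as `data-*` attributes, and the HTML page's fixed
script only toggles CSS classes — region hover highlights the local tree's
edges *and their incident nodes* (the node highlight is a choice; edges
alone would also be defensible).

## Layout

**Vertical.** `y` is a function of node time and scale only, with the
oldest node at `y = 0` and the youngest at `y = 1`:

* `linear` — affine between the minimum and maximum time;
* `log` — affine in `log(1 + t)`, admitting `t = 0` samples;
* `rank` — distinct times get equally spaced positions; useful when times
  span orders of magnitude (the default).

Both linear and log use min–max normalization so the extremes always land
on 1 and 0; when the minimum time is 0 (samples at the present, the common
case) this reduces to `1 - t/t_max` and `1 - log1p(t)/log1p(t_max)`. If
all times coincide, every node sits at `y = 0.5`. Equal times always map
to equal y, and the simulation below never modifies y.

**Initial horizontal placement.** Samples are spread equally over `[0, 1]`
in id order. Internal nodes, processed young to old, start at the mean x
of their children in the leftmost local tree (position 0), falling back to
the mean over all graph children, then to 0.5. This is deterministic and
independent of table row order, and it is already a reasonable embedding
for the leftmost tree.

**Relaxation.** Per iteration, in fixed order (nodes sorted by id):

1. spring along every edge (per edge, not per interval): each endpoint's x
   is pulled toward the other's with stiffness `k_a = 0.06`;
2. 1-D repulsion between every node pair with `|Δy| < 0.08`:
   magnitude `k_r·Δx/(Δx² + ε)`, `k_r = 0.002`, `ε = 1e-4`. Restricting
   repulsion to near-equal heights is what prevents unbounded horizontal
   spread under the fixed-y constraint;
3. the step is scaled by a factor cooling geometrically from 1.0 to 0.001
   over the iteration budget (default 300, carried in the `Layout` and
   serialized so saved figures re-render identically);
4. x is clamped to `[0, 1]`; pinned nodes are reset to their pin.

Exact ties `Δx = 0` are broken by a tiny jitter derived by hashing the
ordered id pair with the seed, so runs are bit-reproducible. The repulsion
pair list depends only on y and is built once.

**Untangle guard.** The spring/repulsion equilibrium is not a minimum of
the crossing count, and on roughly a quarter of simulated fixtures the
relaxed state crosses one or two segments *more* than the tree-informed
initial placement. Since reducing crossings is the entire point of the
relaxation, `force_layout` ends by counting straight-segment crossings of
the initial and final configurations and returning whichever is lower
(ties prefer the relaxed state, which spaces nodes better). Exact counting
is quadratic in the number of edges, so the guard is skipped above 1000
edges (`ForceParams.guard_max_edges`); large drawings keep the relaxed
state unconditionally.

**Crossings.** `count_crossings` counts unordered pairs of routed segments
(2 per edge for orthogonal, 1 for line) meeting at a point interior to
both: proper sign-crossings count, collinear pairs count when their
overlap has positive length, contacts at an endpoint of either segment
never count (edges sharing a node are not "crossings"). Minimizing
crossings exactly is NP-hard and out of scope; the simulation plus manual
pinning is the offered mechanism.

**Subgraphs.** `subgraph(arg, focal, degree)` keeps the breadth-first
neighborhood of the focal node within `degree` undirected hops (a single
bound covers both rootward and leafward directions). Edges with both
endpoints kept stay intact; edges with exactly one kept endpoint become
stubs recording the kept node, the excluded node, the edge, and the
direction (up = excluded parent); edges with neither endpoint kept are
listed explicitly as excluded, so every input edge is accounted for.
Breakpoints are recomputed on the retained edges, and mutations resolving
to retained edges are kept.

## Rendering

Canvas defaults: 750 × 520 px, 40 px margins, a 25 px chromosome bar 15 px
below the graph (no dimensions are canonical; these fit a notebook cell).
Orthogonal edges rise at the *child's* x and shelve at the parent's y,
keeping the two children of a recombination node visually forked; with
more than two children the shelves overlap and the line stylization reads
better. Mutation glyphs sit at arc fraction
`(t_parent − t_mut)/(t_parent − t_child)` from the parent end (0.5 when
the mutation is undated); glyphs sharing an edge are separated by at least
0.02 of the arc in stable id order. Stubs are dashed segments of
normalized length 0.04. The bar maps genome coordinate `g` to pixel
`left + (g/L)·span`, and its rectangles tile the span exactly.

SVG is emitted by the package's own serializer with fixed attribute order
and fixed-precision coordinates, so identical inputs give identical bytes.
PNG export is intentionally not provided — any external SVG rasterizer
can produce one; the guaranteed formats are SVG, HTML and JSON.

## The fixture simulator

`simulate_arg` is a Hudson-style back-in-time coalescent with
recombination. Each of k live lineages carries ancestral-material segments
annotated with descendant-sample counts. Waiting times are exponential
with total rate `k(k−1)/2 + ρ·(total material length)` where ρ is the
per-length, per-lineage, per-time recombination rate. A coalescence picks
an unordered pair uniformly, creates a node, and emits edges for *all*
transferred material (full-ARG recording, including non-coalescing
passages); material ancestral to every sample is then retired. A
recombination picks a lineage in proportion to its material length and
splits it at a position uniform *within its material* (not the whole
genome), so every recorded event is visible in the output; splits landing
exactly on a material boundary are discarded as invisible. The process
runs until all material has coalesced, which guarantees a single root per
local tree. Edge rows are assembled through the per-interval converter, so
a recombination whose two halves later coalesce together merges back into
one (possibly single-interval) edge.

Random draws come from one NumPy PCG64 generator in fixed order — waiting
time, event-type uniform, then the event's own draws (pair indices for
coalescence; lineage uniform, position uniform for recombination) — so a
seed fully determines the ARG. `sprinkle_mutations` visits edges in id
order and draws, per interval, a Poisson count with mean
`rate · interval length · branch length`, then uniform positions and
times, so every mutation resolves to its generating edge and the total
count has a closed-form mean usable as a Monte-Carlo check.

Default study conditions used by the tests and the acceptance script:
small families at n = 5–7 samples, L = 1000, ρ ≈ 5–8·10⁻⁴ (a handful of
recombinations per ARG); the curated layout set uses n = 8, L = 2000,
ρ = 3·10⁻⁴, seeds 1–10, chosen so recombination-node counts center on
2–6 (the sampling noise of the process means individual seeds range from
0 to 7); the scaling run converts an msprime tree sequence with ≈10⁴
merged edges and relaxes it for 20 iterations — enough to exercise every
code path at scale while keeping the whole suite under a minute of
simulation time.

What the simulator does *not* emulate: demography, gene conversion,
selection, mutation models with back-mutation, or the error structure of
*inferred* ARGs (polytomies, unresolved node times, inference artifacts).
Tests passing on these fixtures establish the correctness of the data
structures, queries, layout contracts and serialization — not that the
visual output is informative for any particular empirical dataset.

## Known limitations

* The orthogonal stylization degrades visually for nodes with more than
  two children (overlapping shelves); use the line stylization there.
* Collinear overlapping segments count as a single crossing regardless of
  overlap length; crossing counts on degenerate layouts (many nodes at
  identical coordinates) are therefore coarse.
* The untangle guard above 1000 edges is skipped, so very large drawings
  may occasionally end slightly more crossed than their initial state.
* Interactive output is limited to hover highlighting driven by
  precomputed data; there is no in-page drag, zoom or pan — the drag
  gesture is modeled by `pin_x` followed by re-layout.
* Byte determinism is guaranteed for identical inputs on a given platform
  and dependency set; IEEE-754 double arithmetic is used throughout, and
  all iteration orders are fixed, but exotic platform float differences
  would surface as differing layouts rather than as errors.
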