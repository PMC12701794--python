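# argdraw

Reproducible figures of ancestral recombination graphs (ARGs).

An ARG is the directed acyclic graph of genetic ancestry for a set of
recombining sequences: at every genomic position the graph contains an
embedded *local tree*, and recombination makes neighbouring local trees
differ while still sharing most of their structure. `argdraw` is for
population geneticists who want to look at these graphs — whole, or zoomed
to a focal node — without the drawing collapsing into a tangle, and who
need a figure that can be regenerated byte-for-byte later.

The package provides:

* **A tabular ARG model (`D3ARG`)** — tables of nodes, edges, mutations and
  breakpoint regions, mirroring the succinct tree-sequence format but
  figure-oriented: one edge may carry several disjoint half-open intervals
  `[left, right)`, and every row has optional styling. Converters accept a
  `tskit.TreeSequence`, per-interval tables (rows sharing a
  `(parent, child)` pair are merged and adjacent intervals coalesced), a
  portable TSV dump, or a previously saved figure JSON.
* **Local-tree extraction** — the edges spanning a position `p` are exactly
  those with `left <= p < right`; they form the local tree (one parent per
  node, single root). Region ↔ edge and edge ↔ mutation incidences are
  precomputed into an `InteractionMap`, which is what drives all hover
  highlighting in the HTML export — interactivity as data, no graph logic
  in the page.
* **Time-constrained force layout** — the vertical coordinate is a pure
  function of node time (linear, log, or ranked scale; `y = 0` oldest) and
  is never touched by the simulation. Only the horizontal coordinate
  relaxes: edges act as springs pulling endpoint x together, nodes at
  near-equal heights repel, the step size cools geometrically, and a final
  guard keeps whichever of the initial and relaxed configurations has
  fewer straight-segment crossings. Nodes can be pinned at an exact x (the
  drag gesture, persisted in the tables). Everything is deterministic
  given `(arg, scale, seed, iterations)`.
* **Rendering** — orthogonal (riser-and-shelf) or straight-line edge
  stylization, a chromosome bar whose rectangles are the breakpoint
  regions, mutation glyphs placed by mutation age along their edge, dashed
  marking of edges outside a chosen focus position's local tree, and
  subgraph *stubs* for links to excluded parts of the graph. Output is
  SVG 1.1, self-contained HTML, and a canonical figure JSON whose
  round trip is exact — re-rendering a saved figure reproduces the SVG
  byte-for-byte.
* **A fixture simulator** — a small Hudson-style back-in-time
  coalescent-with-recombination generator (plus a Poisson mutation
  sprinkler), so every feature is testable without any external dataset.

## Worked example

```python
import argdraw as ad

arg = ad.toy_T1()                       # 2 samples, 1 recombination node
print(ad.validate(arg))                 # []
print(arg.recombination_node_ids())     # [2]
print([(b.left, b.right) for b in arg.breakpoints])
                                        # [(0.0, 40.0), (40.0, 100.0)]

lt = ad.local_tree(arg, 50.0)           # genealogy right of the breakpoint
print(lt.parent_of, sorted(lt.roots))   # {0: 2, 1: 3, 2: 4, 3: 4} [4]

lay = ad.force_layout(arg, scale="rank", seed=7, iterations=300)
print(ad.count_crossings(arg, lay, "line"))   # 0
print("(%.4f, %.4f)" % lay.coords[4])         # (0.4492, 0.0000)

res = ad.draw(arg, ad.DrawOptions(style="orthogonal", scale="rank", seed=7))
open("t1.svg", "w").write(res.outputs["svg"])
open("t1.html", "w").write(res.outputs["html"])
```

The two breakpoint regions say the genome splits at position 40 into two
local trees; node 2 is the recombination node joining them (it has parent
edges on both sides of the breakpoint). The layout places the root
(node 4, oldest, `y = 0`) near the middle of the canvas, and the relaxed
drawing has no crossing edges. Hovering a region of the chromosome bar in
`t1.html` highlights that region's local tree; hovering an edge highlights
the regions it covers.

The same pipeline from the shell:

```
argdraw simulate --samples 8 --length 10000 --recomb 1e-4 --seed 1 --out sim.json
argdraw draw --input sim.json --out sim.svg --style line --scale rank --seed 1
argdraw draw-node --input sim.json --out sub.svg --focal 11 --degree 2
```

Running the same command twice writes byte-identical files.

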