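# Methods

## Scope and model

`netannotate` condenses a network into labeled clusters. The pipeline is:
partition → per-cluster word cloud → label selection → shape/label
annotations → optional collapse into group nodes with meta-edges. The
package assumes node text attributes are natural-language phrases (pathway
descriptions, article titles, ontology term names); all cluster and
collapse semantics are direction-free, so directed input edges are stored
with their direction but treated as undirected by adjacency logic.
Parallel edges are kept in the edge multiset and deduplicated only in
adjacency queries, since networks of this kind often carry several edge
types between the same node pair.

## Clustering

Two partition sources are supported.

*Attribute grouping* places nodes with the same value of a chosen attribute
in one cluster; nodes missing the attribute (or with an empty value) stay
unclustered. Cluster ids from an explicit assignment are opaque — the text
`"1"` and the number `1` name different clusters — because coercing them
would silently merge clusters produced by external tools.

*MCL* is a dense implementation of the standard Markov Cluster iteration:
build the symmetric weighted adjacency matrix, add unit self-loops (this
guarantees aperiodicity), column-normalize, then alternate expansion
(matrix squaring) and inflation (entrywise power, default 2.0, then column
renormalization). Numerical policy: entries below 1e−6 are pruned to zero
each iteration; iteration stops when successive matrices differ by less
than 1e−8 in max norm, or after 100 iterations. Clusters are the unions of
column supports of the attractor rows (merged via union–find when attractor
rows overlap); a node attracted to no attractor becomes its own singleton
cluster so the partition invariant always holds. Parallel edges collapse
onto the strongest link when the matrix is built. Cluster ids are assigned
as consecutive integers by descending size, ties broken by smallest member
id, making the output deterministic. Because matrix powers preserve the
block structure of connected components, the result always refines the
components partition. The dense iteration is O(n³) per step and is intended
for the network sizes a human would annotate (up to a few thousand nodes),
not for streaming-scale graphs.

## Word clouds

Tokenization splits on whitespace and punctuation but keeps intra-word
hyphens and underscores (`TGF-beta`, `p53_target`), lower-cases, and drops
a packaged English stopword list (user-extensible) plus pure numbers.

Scoring blends two quantities with the normalization factor *k* ∈ [0, 1]
(default 0.5): the word's in-cluster frequency `f_c`, and the ratio of
`f_c` to its whole-network frequency `f_n` (network counts include
unclustered nodes — the comparison population is the entire network). The
behavior at the limits is fixed — *k* = 0 must rank words exactly by their
cluster counts, and large *k* must demote network-ubiquitous words — but
the blending algebra between the limits was an open design choice. The
choice made here: min–max rescale each of `f_c` and `f_c / f_n` to [0, 1]
over the words of the cloud, then form `(1 − k)·rescale(f_c) +
k·rescale(f_c/f_n)`. Rescaling makes the two terms dimensionally comparable
so *k* is a pure interpolation weight; a degenerate rescale range (all
words equal on a term) maps every word to 1, which keeps the k = 0 limit
exact even for single-word clouds. Scores map affinely onto font sizes in
[1, 64]; all-equal scores get the maximum font.

Adjacency groups link two words when they occupy adjacent token positions
in the text of at least 2 member nodes (a per-node presence count, not an
occurrence count); for clusters with fewer than 3 members the threshold
drops to 1 so tiny clusters are not starved of phrase structure. The
threshold of 2 is a design constant: requiring repetition filters
accidental juxtapositions while still catching real phrases like
"cell cycle". Groups are connected components of the link structure,
numbered by descending size then by smallest word.

Word order is the index of first appearance while scanning member nodes in
sorted id order with attributes in their selected order — an arbitrary but
deterministic convention that keeps labels readable and clouds independent
of set-iteration order.

## Label selection

*Biggest words*: sort by font size (ties toward the earlier-appearing
word), keep the top N, emit by first appearance. A brute-force
subset-enumeration oracle (maximize the sorted size profile over all size-N
subsets) is used in the tests to confirm the greedy selection is exact.

*Adjacent words* (default): after finding the N largest words, every word
sharing an adjacency group with any of them — including the top words
themselves, where the cap makes the bonus a no-op — gets `size + bonus`
(default bonus 8), capped at the maximum original size within the word's
own group; the cap is read as group-local because a global cap would almost
never bind. The list is re-ranked by boosted size and the top N are emitted
in first-appearance order, matching the sibling algorithm's emission order
(re-sorting determines *which* words win; first-appearance order keeps the
label phrase-like). With bonus 0 or all-singleton groups the algorithm
reduces exactly to biggest-words. The word budget N is clamped to [1, 10],
default 3.

## Annotations and geometry

A cluster's shape is the axis-aligned bounding box of its member positions
expanded by a 10-unit padding on each side; the ellipse variant is the
ellipse circumscribing the padded box (radii = half-extents × √2), so
member positions always lie inside the drawn shape. The label anchors
horizontally centered at the box top. With font scaling on, label font =
`base_font × (1 + log10(n))` for an n-member cluster — sublinear growth
chosen so labels of large clusters stand out without dwarfing the drawing.
Geometry is computed on demand from current positions, so moving nodes
never leaves stale annotations. A cluster without member coordinates blocks
geometry but not labeling, since labels are layout-free.

At most one annotation set is active per network, and collapsed clusters
must be expanded before switching sets — a collapsed group's members may
belong to different clusters in the other set, so switching while collapsed
would orphan them.

## Collapse and expand

Collapsing removes the member nodes and incident edges, adds one group node
(id `group:<cluster-id>`, named by the cluster label, positioned at the
member centroid) and one meta-edge per external neighbor, with a `count`
attribute equal to the number of underlying boundary edges. Meta-edges do
not aggregate edge weights — only connectivity and multiplicity are
summarized; aggregation policy is deliberately left to downstream users.

Each meta-edge privately carries the original edges it stands for, and each
group node its hidden member list. Expansion therefore restores the exact
pre-collapse state from the *current* meta-edges: a restored boundary edge
whose far endpoint is still hidden inside another collapsed group is
re-routed into a meta-edge to that group. This makes collapse/expand of
several clusters order-independent, and the final meta-edge set between two
collapsed clusters is always a single edge counting all their boundary
edges. These private bookkeeping attributes (underscore-prefixed) are
stripped when writing GraphML.

## Sessions and CLI

Sessions are versioned JSON (annotation sets, labels, collapsed flags,
options, collapse records, active-set marker); an unknown version or
truncated file fails outright without partial loading. Native session
compatibility with desktop network editors is not attempted. The CLI
(`netannotate annotate`, `netannotate generate`) is a thin layer over the
library; every stage failure surfaces with the stage name and a nonzero
exit.

## Synthetic fixtures

`make_themed_network` emulates the class of inputs the tool targets without
shipping any dataset: a planted-partition graph (within-cluster edge
probability `p_in` = 0.9, between-cluster `p_out` = 0.02, 4 clusters × 10
nodes by default — dense modules, sparse background, sized so whole-suite
runs stay fast while MCL recovery is non-trivial), node text of 8 words
drawn 80% from a disjoint 20-word per-cluster theme vocabulary and 20% from
a shared background whose draw weights are Zipf-like, so a few filler words
("pathway", "regulation", …) are frequent network-wide as in real pathway
descriptions; positions come from per-cluster Gaussians (SD 40 around
centers 300 units apart) so geometry and rendering are exercised. All
randomness flows from a single seed.

What the generator does **not** emulate: real enrichment statistics
(overlap-derived edge weights, q-values), polysemy and morphological
variants in text (no stemming is performed, so "pathway"/"pathways" count
separately), hub nodes and degree heterogeneity, and clusters of very
different sizes. Tests passing on these fixtures show the machinery is
exact and deterministic under its stated model; they do not certify label
quality on real corpora, which depends on attribute quality and the chosen
normalization factor.

## Known limitations

- Dense MCL limits practical network size (≈ thousands of nodes).
- No stemming/lemmatization; morphological variants dilute word scores.
- Overlapping or fuzzy clusters are out of scope; partitions are hard.
- Shape overlap between neighboring clusters is not resolved in renders.
- Meta-edges summarize counts only; no weight aggregation.
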