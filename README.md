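# netannotate

Large biological networks — enrichment maps whose nodes are pathways,
co-authorship graphs, protein–protein interactomes — are unreadable at full
resolution. `netannotate` summarizes them the way analysts do by hand:
partition the network into clusters, condense each cluster's textual node
attributes (pathway descriptions, publication titles, GO term names) into a
frequency-scored word cloud, pick a few words as a semantic label, draw a
bounding shape with the label over each cluster, and optionally *collapse*
every cluster into a single labeled group node joined by meta-edges, leaving
a compact thematic map of the original network.

## Method

**Clustering.** Either group nodes sharing a value of a chosen attribute
(so cluster assignments from any external tool can be imported), or run the
Markov Cluster algorithm (MCL): column-normalize the weighted adjacency
matrix (unit self-loops added), then alternate *expansion* (matrix squaring)
with *inflation* (entrywise power *r*, default *r* = 2, followed by column
renormalization) to convergence, and read clusters off the attractor rows.

**Word scoring.** For each word *w* in a cluster, with in-cluster frequency
*f<sub>c</sub>* and whole-network frequency *f<sub>n</sub>*, the score blends
two min–max-rescaled terms with the normalization factor *k* ∈ [0, 1]:

```
score(w) = (1 − k) · rescale(f_c)  +  k · rescale(f_c / f_n)
```

At *k* = 0 a word's weight is just how often it occurs in the cluster;
raising *k* up-weights the cluster-to-network frequency ratio, suppressing
words like "pathway" or "regulation" that are frequent everywhere. Scores
map affinely onto font sizes, and words that repeatedly occupy adjacent
token positions are linked into *adjacency groups* (connected components of
a repeated-bigram structure), which capture multi-word phrases.

**Labeling.** *Biggest words* keeps the N largest words and emits them in
first-appearance order. *Adjacent words* — the default — first finds the N
largest words, then adds a size bonus (default 8) to every word sharing an
adjacency group with them (capped at the largest original size within the
word's own group), re-ranks, keeps the top N, and emits in first-appearance
order. N is configurable from 1 to 10 words.

**Collapse.** A collapsed cluster is replaced by one group node, named by
the cluster label and placed at the member centroid; each external node
adjacent to ≥ 1 member gets exactly one meta-edge carrying the count of
underlying boundary edges. Expansion restores nodes, attributes, positions
and the edge multiset exactly, in any order.

## Worked example

Generate a synthetic 4-module network with planted word themes, then
annotate and collapse it:

```bash
netannotate generate --seed 4 --out fixture.graphml
# wrote 40 nodes / 180 edges to fixture.graphml (text attribute: 'description')

netannotate annotate fixture.graphml \
    --label-attr description --cluster-source mcl \
    --max-words 3 --normalization 0.5 --collapse-all \
    --report clusters.tsv --render annotated.svg --out collapsed.graphml
# 4 cluster(s) annotated
```

`clusters.tsv` then holds one row per cluster — its computed label, member
count and collapse state:

```
label	nodes	collapsed
theme1term10 theme1term02 theme1term11	10	true
theme2term05 theme2term16 theme2term07	10	true
theme3term06 theme3term10 theme3term19	10	true
theme4term15 theme4term18 theme4term14	10	true
```

MCL recovered the four planted modules (10 nodes each), and every 3-word
label is drawn from the corresponding module's planted theme vocabulary —
the background fillers ("pathway", "regulation", …) were suppressed by the
normalization factor of 0.5. `annotated.svg` shows the network with a
labeled ellipse per cluster; `collapsed.graphml` contains the 4 group nodes
and their meta-edges.

The same pipeline is available as a library:

```python
from netannotate import (AnnotationManager, CloudOptions, LabelOptions,
                         mcl_clusters, read_network)

net = read_network("fixture.graphml")
partition = mcl_clusters(net, inflation=2.0)
manager = AnnotationManager(net)
aset = manager.create_annotation_set(
    partition,
    CloudOptions(attributes=("description",), normalization=0.5),
    LabelOptions(algorithm="adjacent_words", max_words=3),
    name="themes")
for cluster in aset.clusters:
    print(cluster.id, len(cluster.members), cluster.label)
```

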