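# Methods

This note documents the models and procedures implemented in `mirnet`, the
choices made where the published workflow leaves details open, and what the
synthetic data used by the tests does and does not establish.

## Network construction

**Inputs.** Four file kinds: a Human Protein Atlas–style `normal_tissue`
table (gene, tissue, detection level, reliability), a miRTarBase-style
miRNA→target table, a STRING-style links file (`protein1 protein2
combined_score` on a 0–1000 scale) with a protein→symbol alias table, and a
GMT pathway collection. Real exports drift between database releases, so
every tabular reader accepts a column-name mapping; all readers accept
gzip-compressed files, and gene identity is the upper-cased symbol
throughout.

**Expression filter.** "Expressed in the tissue" is not formally defined by
the source workflow for HPA data. We use the standard HPA notion of a
detected gene: detection level in {Low, Medium, High} and annotation
reliability in {Approved, Enhanced, Supported}. Both lists are
configurable; which reliability classes the original analysis kept is
unknowable from the text, and this choice only shifts the expressed
universe, not the algorithm.

**Edge filter.** Edges are kept when the combined score is strictly greater
than 900 (the 0.9 cutoff on STRING's integer scale). Duplicate unordered
pairs are collapsed to their **maximum** score *before* thresholding, so one
high-confidence observation of a pair suffices; this matches STRING's
one-combined-score-per-pair semantics. Proteins mapping to the same gene
(splice variants) merge into one node; the resulting self-loops are dropped.
A protein id with several gene aliases resolves to the lexicographically
first (logged) for determinism.

**Network.** Candidate nodes are `targets ∩ expressed`; edges require both
endpoints to be candidates; candidates with no retained edge are excluded
from the graph but reported. An empty candidate intersection is an error,
while an all-isolated candidate set is a legitimate empty result — the two
conditions mean different things (no data vs. no connectivity) and carry
different CLI exit codes (2 vs. 3). Components are ordered by size, ties
broken by the lexicographically smallest member, so every downstream
artifact is reproducible byte-for-byte.

## Key-node selection

Centrality is the additive sum of normalized shortest-path betweenness
(factor `2/((N−1)(N−2))`, 0 when `N ≤ 2`) and degree centrality
(`degree/(N−1)`); both lie in [0, 1], which is what makes the additive
combination commensurable. The ranking is computed **once** on the intact
LCC and never updated during removal; an adaptive variant that re-ranks the
shrinking graph after every removal exists behind an off-by-default flag.

The disintegration curve `f(n)` is the largest-component cardinality after
deleting the top-`n` ranked nodes from the intact LCC. The derivative
condition of the selection rule is read as the forward difference
`f(n+1) − f(n) = 0` on the integer domain ("removing the next-ranked node no
longer shrinks the component"); `f` is extended with zeros beyond `n = N`,
where the graph is exhausted, which guarantees termination. The half-size
condition `f(n) < N/2` is evaluated in exact integer arithmetic
(`2·f(n) < N`), never floating point. Plateau points failing the half-size
condition are skipped and the scan continues.

A subtlety worth recording: on small motifs, betweenness-plus-degree does
not always rank an articulation "hub" first. For two triangles joined
through a degree-2 hub, the triangle nodes the hub attaches to carry more
combined centrality (1.033) than the hub itself (0.933), and the curve
follows the ranking, not the intuition. The unit tests assert the
brute-force-verified values.

## LCC significance

The permutation null draws `k` genes uniformly without replacement from the
tissue-expressed universe and scores each draw with exactly the network
construction above (edges within the draw, isolated genes dropped, LCC size;
0 for an edgeless draw). `k` defaults to the number of *expressed* targets
— sampling before the connectivity filter, so that connectivity itself is
part of the statistic being tested — and both `k` and the universe are
overridable. The per-replicate scorer is a union-find over the restricted
edge list; a test pins its equality to the full network builder on random
draws.

The p-value is the add-one estimator `(#{null ≥ obs} + 1)/(n_perm + 1)`,
kept as an exact rational. It can never be zero; with the default
`n_perm = 10 000` and no exceedance the reportable bound is `p < 0.0001`.

**Calibration.** With a discrete network statistic the add-one estimator is
valid but conservative: ties between the observed and null values can only
inflate p. On a toy universe with a handful of distinct LCC sizes, the
realized type-I error at α = 0.05 falls well short of 5%. The calibration
experiment therefore uses a dedicated synthetic universe — 250 genes,
random edges at density 0.012, draws of k = 75 — sized so a draw sits near
its percolation threshold and the null spreads over ~50 distinct values;
the analytic hit rate there is 4.6% against the exact 5% ceiling. This
choice was made from that analytic scan, not by re-rolling seeds.

## Overrepresentation and clustering

ORA p-values are exact upper-tail hypergeometric probabilities computed
with integer combinatorics and carried as rationals alongside floats;
Benjamini–Hochberg adjustment (statsmodels) is always reported. The
significance filter follows the original procedure — raw p < 0.05 — with
the adjusted filter available by flag. The background universe defaults to
the union of the GMT collection's members (self-contained, no web service);
key genes absent from it are excluded from the draw count and logged.
Pathways with fewer than `min_key_genes = 3` overlapping key genes are
discarded to focus on sets substantially represented by key targets.

The clustering method behind the published dendrogram is cited but not
described; we reconstruct it as: binary pathway × key-gene membership
matrix (rows by ascending p, columns by descending centrality), Jaccard
distance between rows, average-linkage agglomerative clustering, tree cut
at a configurable `n_clusters = 2` (the observed cluster count). Each
pathway's mean combined centrality over its *key* genes — the only genes
with centralities in the LCC table — is exported with the leaf order, which
is the quantity the figure's colour gradient encodes. The dendrogram is
data (Newick + TSV), not a rendering.

## Synthetic data

`make_toy_databases` writes fixed, hand-designed toy versions of all four
inputs (the seed shuffles row order only, so a seed reproduces files
byte-identically): 30 genes × 3 tissues with 18 heart-expressed; 25 target
rows with 12 distinct hsa-miR-375 targets; 40 link rows collapsing to 14
gene-level edges (including a splice-variant duplicate, a variant-pair
self-loop, reversed lower-score duplicates, and at-threshold rows); 12
GMT sets over a 31-gene universe. The 9 expressed targets form a 7-node,
8-edge connected network chosen — by exhaustive search over all connected
7-node/8-edge graphs — so that the curve `[7,5,3,2,1,1,1,0]` selects
exactly 4 key genes with no centrality tie at the selection boundary,
which in turn exercises the ≥3-key-gene filter (4 surviving sets) and a
non-degenerate 2-cluster dendrogram.

`make_planted_graph` builds two dense random clusters (default p = 0.9)
joined *only* through dedicated bridge nodes, each attached to 6 nodes per
cluster; with sparser attachment (2–3 per side) well-connected cluster
members outrank the bridges in combined centrality and the plant loses the
property it is supposed to have — that the bridges are the top-centrality
articulation set. With 6 attachments the bridges hold the top-b combined
centralities in ≥ 99/100 instances across cluster sizes 8–12 and 1–3
bridges, and key-node selection recovers the full bridge set essentially
always.

**What the toy data does not show.** Real HPA/miRTarBase/STRING exports are
orders of magnitude larger, with identifier noise, evidence heterogeneity,
and score distributions the toys do not model; the published gene counts
for miR-375 in heart (267 expressed targets, 82 connected, 53-gene LCC, 9
key genes, 94 enriched pathways) depend on specific database releases and
are not reproducible from synthetic data. Passing tests establish that the
algorithms are implemented correctly and deterministically, not that any
particular biological claim holds.

## Problem sizes and numerical choices

Tests and the acceptance script run at deliberately small scale: toy
pipeline networks of ~7 nodes, random property-test graphs of ≤ 50 nodes,
100 planted-graph trials, 400 calibration replicates at 199 permutations
(the add-one estimator makes `p ≤ 0.05` equivalent to ≤ 9 exceedances
there), and 10 000 permutations for the toy workflow's reported p. All
randomness flows through explicit integer seeds; no module reads global
RNG state. Floating-point output is formatted at 10 significant digits;
comparisons that define the algorithm (half-size rule, p-value ordering)
are exact integer or rational arithmetic.

## Known limitations

* Binary expressed/not-expressed calls discard expression magnitude.
* The static ranking can, on adversarial graphs, remove nodes that are no
  longer in the current largest component; the adaptive option exists but
  is not the documented default procedure.
* The alias map supports only protein→symbol resolution; no ortholog
  mapping or cross-species analysis.
* Jaccard-over-key-genes clustering is a documented reconstruction of an
  under-specified method; other set distances would order leaves
  differently.
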