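# Methods

## Model

`celltreewalk` annotates bulk-derived genomic regions with nodes of a
cell-type hierarchy by diffusing a random walk with restart over a combined
graph. The graph has one node per tree node (leaves = specific cell types,
internal nodes = broader groupings, root last) followed by one node per
cell. Its symmetric adjacency is assembled from four blocks: the binary tree
adjacency (1 per parent–child edge), the cell–cell similarity matrix, and
the label–cell block and its transpose. Internal tree nodes are connected to
cells only through the tree — their rows in the label–cell block are zero —
so information about broad groupings accumulates exclusively by diffusion
from their descendant leaves.

The walk terminates with probability `α` at each step and otherwise moves to
a neighbor with probability proportional to edge weight. Its termination
distribution has the closed form `F = α(I − (1 − α)W)⁻¹` with `W = D⁻¹A`;
`F` is row-stochastic by construction. Assumptions worth stating: the graph
must have no zero-degree node (`D` invertible; the solver raises naming the
offending nodes, and `drop_isolated_cells` is available when pruning is
preferred); edge weights are nonnegative; and the tree may have arbitrary
arity — nothing downstream relies on binary branching.

A region is scored through the cells in which it is accessible (half-open
interval overlap with at least one accessible peak). The influence rows of
those cells are summed over the tree-node columns, giving a raw flow vector;
regions accessible in no cell are reported as unscoreable rather than
scored. Flow vectors are standardized per tree node across regions into
label z-scores; `z > 2` marks a high-specificity annotation, `z > 1` a
lenient one.

## Solvers and numerics

- Direct sparse LU solve of `(I − (1 − α)W)` up to 5,000 graph nodes; the
  fixed-point iteration `F ← αI + (1 − α)WF` (tolerance 1e−10 on the
  max-abs change, 10,000 iteration cap) beyond that. Both satisfy the same
  contract, and a seeded Monte-Carlo walk simulator serves as an independent
  oracle in the tests.
- Influence entries in `[−1e−12, 0)` are clipped to zero; anything below
  that floor raises. Row sums must equal 1 within 1e−8.
- `α` defaults to 0.5; smaller values propagate information further along
  the graph at the cost of specificity.
- Zero-variance z-score columns get `z = 0` with a warning. The same
  treatment extends to *near-constant* columns — coefficient of variation
  below one tenth of the median column CV. The root's flow share varies an
  order of magnitude less than any other node's (every walk's tree flow
  passes the same bottleneck), so standardizing it manufactures large z
  values out of numerical noise; a root label would then survive ancestor
  pruning as the least specific node and mask all real annotations.

## Normalization choices

Two normalizations of the raw flow vector are available for z-scoring:

- `compositional` (pipeline default): divide by total tree flow, scoring
  *where* the flow goes. This removes per-cell-type differences in overall
  label connectivity (marker strength, degree) that otherwise shift whole
  score vectors up or down and leak into every column's z.
- `per_cell`: divide by the number of contributing cells (mean influence),
  scoring how much flow each contributing cell sends. Kept as an option;
  the `RegionLabelScores.normalized` field always carries this quantity.

The z-score null is likewise configurable: `across_regions` (default)
standardizes each node over the scored regions — appropriate when the region
pool is large and heterogeneous — while `permutation` compares each region
against random cell subsets of the same size (200 seeded draws). The
permutation null measures absolute specificity but tends to make ancestors
of a true label significant as well, which the across-region null avoids.

## Annotation and divergence

Discrete labels are produced by threshold (`z > z_threshold`, default 2) →
bottom-up parent collapse (a significant parent whose children are *all*
significant absorbs them, iterated to a fixed point; for multifurcating
nodes "all children" is the conservative generalization) → ancestor dedupe
(only the least specific of any ancestor-related pair survives, leaving an
antichain).

A gene is called cell type-divergent when some pair of its annotated regions
satisfies, simultaneously: (i) their label sets contain two distinct,
non-ancestral nodes; (ii) the Euclidean distance between their score vectors
is at least `score_distance_min`; (iii) the distance between their 2-D UMAP
coordinates is at least `embed_distance_min`. The embedding is seeded and
single-threaded, hence bit-reproducible, and neighborhood size shrinks
automatically when there are fewer regions than neighbors. The reported
`n_distinct_celltypes` is the size of the largest pairwise-compatible label
set (exhaustive search; label sets are tiny).

Distance rule choices. The score-vector distance uses the compositional
profile rather than the z vector: z columns are individually standardized,
so z distances are blind to tree proximity (two sibling types differ as
much as two unrelated ones), whereas compositional profiles of related
types genuinely correlate — which is what the rule is meant to measure. The
fixed defaults (40 in score space, 8 in embedding space) presume a
particular data scale; `suggest_divergence_params` recalibrates both to the
data at hand by exploiting the strong bimodality of pairwise distances
among annotated regions — a tight mode of same-cell-type pairs and a broad
mode of everything else — splitting at the geometric midpoint of a
deterministic two-means on log distances. The pipeline exposes this as
`divergence_calibration = calibrated`; `fixed` keeps the absolute defaults.

## Edge-weight tuning

The label-edge multiplier trades off how strongly marker information
anchors cells to labels versus cell–cell smoothing. The tuning objective is
cell homogeneity: assign each cell its top leaf label from the influence
matrix, then take log2 of mean within-label over between-label cell–cell
influence. The default grid is powers of ten from 1 to 10⁴ (`steps` sets
the resolution); ties break toward the smaller weight.

## Multiome validation

Cells are assigned to an eQTL when its eSNP is accessible in the cell and no
other eSNP of the same gene is, making assignments per gene disjoint; the
gene's background is cells assigned to none of its eQTLs. The expression
test is a two-tailed Wilcoxon rank-sum: exact by full enumeration of rank
assignments (mid-ranks for ties) when both groups have ≤ 8 observations,
otherwise the normal approximation with tie and continuity corrections.
Log2 fold change of means uses a pseudocount of 1. Benjamini–Hochberg
correction is applied across the whole batch of tests. Genes with fewer
than 100 total reads are filtered before testing. The enrichment ratio for
a cell type is the fraction of assigned cells of that type over the same
fraction among background cells; a zero background fraction reports
infinity alongside the raw fractions.

## Synthetic benchmark

The generator (`simulate_dataset`) emulates the data structure the method
assumes, with planted ground truth for recovery tests. Default study
conditions: 8 leaf cell types in a balanced binary tree, 40 cells per type;
150 shared peaks accessible at rate 0.5 everywhere; 30 specific peaks per
type accessible at 0.8 in-type against a 0.02 noise floor; 5 marker genes
per type at mean log2 fold change 2 (Poisson activity, base rate 0.5, plus
50 background genes); 20 cell type-specific eQTL genes with 2 eSNPs each,
half planted divergently in two non-sibling leaves, the rest in a single
leaf; and 20 non-specific eQTL genes whose eSNPs sit in shared peaks. The
non-specific pool mirrors real fine-mapped eQTL sets, where most scoreable
variants carry no cell-type signal; it also matters statistically, because
an across-region z null computed over exclusively type-specific regions
caps the attainable z near the threshold. Multiome expression is Poisson
with a 2-fold mean shift in cells where the gene's first eSNP is
accessible. All randomness flows from a single seed through independent
per-stage streams, so the planted truth is invariant to cell- and
gene-dimension changes.

Divergent truth uses non-sibling leaves deliberately: sibling types collapse
into their shared parent during annotation, so divergence between them is
undefined under the model's own semantics.

The correlated-siblings scenario (`nested_siblings_config`) has 16 leaves in
8 sibling pairs sharing 80% of markers and half of their specific peaks, and
plants half of the non-divergent specific genes *broadly* — in dedicated
peaks accessible across a four-leaf clade. Broad regions have no single
outstanding leaf, so a flat (star-tree) label space dilutes their signal
across four columns while the hierarchy captures them at the clade node;
this is the regime where hierarchical annotation demonstrably outperforms a
flat one.

What the generator does not emulate: read-level counts and fragment-length
structure (accessibility is Bernoulli per peak × cell), doublets, batch
effects, GC or mappability biases, linkage between eSNPs, and realistic
genomic peak spacing (peaks tile one synthetic chromosome). Passing the
recovery tests therefore demonstrates the machinery is correct and
well-calibrated under the stated generative assumptions, not performance on
real tissue.

## Problem sizes

The shipped tests and the acceptance script run the default scenario (335
graph nodes, 80 regions), the correlated-siblings scenario twice (671
nodes), 50 random graphs of 5–60 nodes for solver agreement, 10⁵
Monte-Carlo walks, and 20 seeded multiome simulations — sizes chosen so the
whole suite completes in a few minutes on one CPU while keeping every
statistical margin (binomial standard errors, recovery rates) comfortably
resolvable.

## Known limitations

- The across-region z null requires a reasonably diverse region pool; with
  few regions concentrated in few types, attainable z is bounded above by
  the pool composition.
- UMAP inter-cluster distances are unstable for small region counts; the
  calibrated divergence cutoffs compensate, but the embedding rule carries
  little independent information below a few hundred regions.
- The label-edge formula (nonnegative logFC-weighted sum of per-cell
  normalized gene activity) is a documented default, not a canonical
  definition; cosine cell similarity and the per-cell normalization variant
  are provided as alternatives.
- Edge-weight tuning optimizes cell-label coherence, not region-annotation
  accuracy; the two usually, but not provably, agree.
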