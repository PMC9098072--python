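# Methods

## The model

`immetnet` associates small molecules with immune processes through a
heterogeneous interaction graph.  The graph has three node types — immune
processes (Gene Ontology biological-process terms descending from "immune
system process", GO:0002376), proteins, and metabolites — and three
undirected edge types: protein–protein interactions (PPI, carrying an
integer confidence on the STRING-style 0–1000 scale), metabolite–protein
interactions (PMI), and metabolite–metabolite interactions (MMI, derived
from reaction participant lists by all-vs-all expansion of each
reactant–product combination).  All edges are undirected: the underlying
databases record associations, not causal direction.

The merged store (the *atlas*) is the statistical background for every
downstream quantity.  Inclusion filters applied at assembly:

* metabolites must be biological and not inorganic (this removes synthetic
  drugs and inorganic compounds);
* metabolite–protein links to proteins without any immune-process
  annotation are dropped;
* PPI edges below the confidence threshold (default 400, "medium") are
  dropped; duplicate rows keep the maximum score, self-loops are removed,
  endpoints are canonicalized lexicographically.

A query builds an *interaction network*: for a process query, all proteins
annotated to the queried process(es), every metabolite PMI-linked to them,
and all atlas edges among the included nodes; for a metabolite query, the
query metabolites plus their protein partners.  Proteins left with zero
edges stay in the network but are flagged as isolated.

## Inheritance

Metabolites inherit immune processes from proteins only.  At order *k*
(k ∈ {1, 2, 3}), a metabolite inherits the annotations of every protein
reachable by exactly one PMI edge followed by at most *k − 1* PPI edges;
the PMI hop counts as step one.  MMI edges never transmit annotations, so
a metabolite whose only interactions are with other metabolites inherits
nothing.  Each inherited pair records its supporting proteins and the
minimal qualifying depth.  By default inheritance is confined to the edges
of the built network; an explicit `scope="atlas"` traverses the full atlas
instead (used for gold-standard evaluation, where predictions must be
atlas-wide).  At order ≥ 2 any protein on the path contributes its
annotations, whether or not it is itself annotated to the queried process.
Because the reachable set grows with *k*, order-1 associations are always
a subset of order-2, which are a subset of order-3.

## Scores

**Harmonic closeness.**  For node *i* in a network of *n* nodes,
`raw(i) = Σ_{j≠i} 1/d(i,j)` over unweighted shortest paths, with
unreachable nodes contributing zero — well defined on disconnected graphs,
unlike classical closeness.  Reported values are normalized to network
size, `raw/(n−1) ∈ [0, 1]`.  Nodes with identical neighbor sets get equal
scores (graph automorphism), which is why co-attached metabolites share
one centrality value.  Shortest-path lengths come from networkx BFS.

**Precision.**  For metabolite *i* and process *j*, `N_ij` counts the
atlas neighbors of *i* (any edge type) that lie inside the process-*j*
network, `N_i` its atlas neighbors overall, and `V_j` the process-network
node count.  The default `ratio` mode reports `N_ij / N_i ∈ [0, 1]` — the
fraction of the metabolite's database interactions committed to the
process, which reaches exactly 1.0 for a fully committed metabolite.  The
`corrected` mode divides further by `V_j`; it is kept as an explicit
option because the size-corrected form cannot reach 1.0 for any network
with more than one node, while the narrative definition (and the published
example of a precision of 1.00) is a plain ratio.

**Overrepresentation.**  Each pair gets a Fisher's exact p-value from a
2×2 table.  For the metabolite-based test, *a* is the number of
protein-mediated associations of the metabolite to the process in the
network, *b* its associations to other processes in the network, *c* the
database count of the specific association minus *a*, and *d* the *total*
database association count of the metabolite minus *b*.  Note the *d* cell
subtracts the other-process network count from the total (not the
other-process) database count; under this construction a fully committed
metabolite with a large exclusive neighborhood is strongly significant,
whereas subtracting per-category counts would force a degenerate
`(a, b, 0, 0)` table with p = 1 for every committed metabolite.  The
process-based test uses annotation instances: *a* appearances of the
process among the network's proteins, *b* among all atlas proteins, *c*
and *d* the same for all other processes.  This is not a standard
enrichment 2×2 (the network column is contained in the database column);
it is implemented literally and validated through self-consistency
properties — with the network equal to the atlas the table is balanced
(*a* = *b*, *c* = *d*) and the observed cell sits at the hypergeometric
mode, so the two-sided p is exactly 1.  The one-sided p of a balanced
table is ≈ 0.5–0.7, which is why the whole-atlas sanity check is stated
for the two-sided convention only.

The test itself is computed in exact integer arithmetic (binomial-product
weights over all tables at fixed margins), so two-sided ties are exact and
no overflow is possible.  Default sidedness is one-sided (greater), the
natural direction for overrepresentation; two-sided is available by flag.

**Multiple testing.**  Benjamini–Hochberg step-up q-values, pooled per run
over all tested pairs (statsmodels implementation); significance at
q < 0.05 (configurable).  Rows are ranked by q ascending, ties broken by
precision, then centrality (both descending), then metabolite id.

**Biomarker candidates.**  Over the significant rows only, a pair is
flagged when its centrality *and* precision both strictly exceed the mean
plus two sample (n−1) standard deviations of the significant set.  The
multiplier is configurable; with fewer than two significant rows the SD is
undefined and nothing is flagged.

## Gold-standard evaluation

An external pair-count table (e.g. literature co-occurrence counts) is
filtered: pairs observed fewer than twice are removed to limit false
positives, and pairs whose metabolite belongs to an excluded superclass
(typically lipids, whose nomenclature defeats text mining) are removed
regardless of count.  Atlas-wide inheritance at each order is compared
against the filtered gold standard over a declared universe of candidate
pairs.  The universe is all (retained metabolite × immune process) pairs:
the evaluation needs a negative class to count true negatives, and the
atlas cross-product is the same background used by every other statistic;
it is recorded in the run summary.  Specificity, sensitivity, precision,
accuracy and F1 (= TP / (TP + (FP+FN)/2)) follow the usual confusion
formulas; ratios with a zero denominator are reported as missing rather
than zero.  Because predictions nest across orders, sensitivity is
non-decreasing and specificity non-increasing from order 1 to 3 against
any fixed gold standard.

## The synthetic-data generator

The generator emulates the five source schemas with planted structure so
every downstream stage is testable without database downloads.  One
integer seed drives a single PCG64 stream; identical seed + configuration
gives byte-identical files.  Defaults (12 processes, 140 proteins of which
75% carry immune annotations, 50 metabolites, mean 2 protein links per
metabolite, PPI density 0.05, 12 reactions) are sized so a full scoring
run takes well under a second while every planted signal is still
unambiguous.

Planted structure, with the analytic reasons it is recoverable:

* **Committed metabolites** (default 3) each get a dedicated process whose
  proteins they link to exclusively, so their ratio-precision is exactly
  1.0 and they are the only metabolite in their process network (rank 1).
  A small committed neighborhood (3 proteins) gives a Fisher p of
  `1/C(6,3) = 0.05`, deliberately not significant after FDR — committed
  plants must not crowd the significant set.
* **The outlier** is the first committed metabolite, with an enlarged
  exclusive neighborhood (40 proteins).  Its p, `1/C(80,40) ≈ 1e-23`,
  makes it the top-ranked association, and its raw centrality (40
  neighbors at distance 1 in a detached component) exceeds every enriched
  metabolite's by a margin several times the cluster spread.
* **Enriched metabolites** (default 10) share one dedicated process pool
  (14 proteins) and link to 12 of them plus 3–5 out-of-process proteins.
  Their p-values (`C(12+k,12)/C(24+k,12) ≈ 1e-4`) survive FDR easily, so
  they populate the significant set with clustered precision (0.71–0.80)
  and centrality — the nondegenerate baseline the mean + 2 SD biomarker
  rule needs.  With ten clustered rows plus one extreme row, the threshold
  sits below the extreme and above the cluster for any seed.
* **Isolated metabolites** have no protein links and can never inherit;
  one of them participates in a reaction, exercising the rule that MMI
  edges do not transmit annotations.
* **Excluded rows** alternate the two exclusion reasons (non-biological,
  inorganic) to exercise the inclusion filter.

The random PPI layer (Erdős–Rényi plus a hub star per background process,
with scores drawn from 150–999 so some edges fall below the default
threshold) spans only the general, non-planted immune proteins.  Keeping
the planted clusters as detached components is a deliberate narrowing of
the "ER over immune proteins" idea: coupling plants to the random
background would make planted centralities seed-dependent and the
biomarker-recovery guarantee probabilistic instead of exact.

What the generator does *not* emulate: real HMDB/STRING degree
distributions, annotation depth of the GO hierarchy (generated ontologies
are flat), correlated multi-process annotations, or literature-derived
gold standards.  Passing tests therefore demonstrate correctness of the
algorithms and statistics on known ground truth — not that the method's
published performance on the real databases is reproduced.  Published
database sizes and performance tables depend on frozen external database
versions and a literature crawl and are out of scope by design.

The packaged miniature T-cell atlas is fixed content checked into the
source (not generated), so it is byte-identical across platforms.  Its
topology mirrors the worked example of a positive-regulation-of-T-cell-
mediated-immunity network: eight metabolites, five of which share one
hub-protein neighbor set (equal centrality), one interacting only inside
the process (precision 1.00), three nucleotide-like metabolites on
peripheral proteins, and one annotated protein with no interactions
(flagged isolated).

## Numerical choices and degenerate inputs

* Fisher p-values: exact rationals converted to float at the end; an
  all-zero table returns p = 1 with a warning.
* Harmonic closeness of a singleton network is 0 (defined, not an error).
* Precision is undefined (error / missing) for a metabolite with no
  interactions; such metabolites cannot appear in an association table
  anyway.
* Duplicate PPI rows keep the maximum score before thresholding, so
  raising the threshold can only remove edges.
* Iteration is in lexicographic id order everywhere, so supporting-protein
  lists, rankings and exports are stable; repeated runs are byte-identical.
* Floating-point table outputs use 6 significant digits.

## Known limitations

* No directed or weighted propagation; PPI confidence is a hard filter,
  not a weight.
* GO annotations are taken as given; ancestor propagation up the hierarchy
  is not applied (annotations in the inputs are treated as already
  complete for the declared root's subtree).
* The process-based overrepresentation table is reported as defined but
  has no standard sampling interpretation; rank it, don't interpret its
  absolute p-values.
* Absolute p-values in general should be read with care: the background is
  the atlas itself, not the whole metabolome.
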