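# immetnet

Protein–metabolite interaction networks for immunometabolomics.

Immune cells reshape their metabolism when they activate, and metabolites
in turn steer immune function — but databases annotate *proteins* with
immune processes, not metabolites.  `immetnet` closes that gap: it builds
a merged atlas of immune processes (GO terms descending from "immune
system process", GO:0002376), proteins, and metabolites from flat
database-style tables (GO-, UniProt-, HMDB-, STRING- and Rhea-style
exports), lets metabolites **inherit** immune-process annotations through
their protein neighborhoods, and scores every metabolite–process
association so candidate biomarkers stand out.  It is aimed at
metabolomics and systems-immunology researchers who want to generate
hypotheses or guide study design from network context.

## The method in brief

For a query (a set of processes or of metabolites) a subnetwork is built
from the atlas, and metabolites inherit the processes of every protein
reachable by one metabolite–protein edge plus up to *k−1* protein–protein
edges (inheritance order *k* ∈ {1, 2, 3}; metabolite–metabolite edges
never transmit annotations).  Each inherited pair (i, j) is scored by:

* **centrality** — harmonic closeness of metabolite *i*,
  `Σ_{j≠i} 1/d(i,j) / (n−1)`, well defined on disconnected graphs;
* **precision** — `N_ij / N_i`, the fraction of the metabolite's database
  interactions inside the process-*j* network (optionally size-corrected
  by `1/V_j`);
* **p, q** — Fisher's exact overrepresentation p-value of the association
  in the network against the atlas background, with Benjamini–Hochberg
  FDR across the run; significant at q < 0.05;
* **biomarker flag** — significant pairs whose centrality *and* precision
  exceed the mean + 2 SD of the significant set.

Predicted associations can be evaluated against a literature-derived gold
standard (occurrence-filtered pair counts) with the usual confusion
metrics (specificity, sensitivity, precision, accuracy, F1) per
inheritance order.  See `docs/methods.md` for the full model, parameter
defaults and design choices.

## Worked example

The package ships a miniature atlas modeled on a T-cell-immunity process
network.  Write it and score the process of interest:

```sh
$ immetnet simulate --toy --out toy
wrote 6 file(s) to toy
$ immetnet score --manifest toy/manifest.json --process-ids GO:0002711 --out results
scored 13 association(s); 0 significant, 0 biomarker candidate(s)
$ head -7 results/association_table.tsv
metabolite_id	process_id	centrality	precision	p	q	significant	biomarker
M00002	GO:0002711	0.538462	0.75	0.119048	0.309524	False	False
M00003	GO:0002711	0.538462	0.75	0.119048	0.309524	False	False
M00004	GO:0002711	0.538462	0.75	0.119048	0.309524	False	False
M00001	GO:0002711	0.538462	0.6	0.0833333	0.309524	False	False
M00007	GO:0002711	0.5	0.6	0.0666667	0.309524	False	False
M00005	GO:0002711	0.538462	1	0.178571	0.386905	False	False
```

Reading the numbers: the process network holds 8 metabolites and 6
proteins.  Five metabolites (M00001–M00005) attach to the same three hub
proteins, so they share one centrality value (0.538462 = 7/13, the sum of
reciprocal hop distances over the 13 other nodes).  M00005 interacts with
*no* protein outside the process, so its precision is exactly 1 — the
most committed molecule in the network — while its promiscuous siblings
score 0.75 and below.  At this tiny scale nothing survives FDR (the atlas
is 9 metabolites), which is the correct reading: the toy demonstrates the
mechanics, not discovery.

```sh
$ immetnet query-process --manifest toy/manifest.json --ids GO:0002711 --format tsv --out net
network: 8 metabolites, 6 proteins, 25 edges
```

Networks export as GraphML (node attributes `kind`, `name`, `superclass`;
edge attributes `edge_type`, `confidence`) or as a TSV edge list.  A
synthetic atlas with planted, recoverable structure — committed
metabolites, an extreme biomarker outlier, isolated metabolites — comes
from `immetnet simulate --seed N --out DIR` (see
`immetnet.fixtures.FixtureConfig` for the knobs and
`planted_truth.json` for the planted answers); `immetnet validate`
compares predictions against a `metabolite_id / process_id /
occurrence_count` gold table across inheritance orders.

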