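# Methods

`ontoseek` packages the ranking, clustering, table-mining, co-expression
and crawl components of an ontology-driven biological search engine as a
library of independently testable operations. This note records the models
implemented, the tunable parameters and their defaults, what the synthetic
generators do and do not emulate, the numerical choices, and the design
decisions taken where the problem statement was genuinely open.

## Relevance model

A query is resolved against an ontology — a directed acyclic graph of
terms connected by `is-a`, `part-of` and `has-a` edges — before any
document is scored. Exact matches (every query word occurring among a
term's label/synonym tokens, case-insensitively) seed a breadth-first
expansion over the undirected DAG up to `max_hops` (default 2). Candidate
terms are ranked by hop distance, then by the best relation on a shortest
path (`is-a` before `part-of` before `has-a`), then by descending ontology
term frequency, then by term id; the relation priority is our convention
and exists purely to make ties deterministic.

Each (document X, term A) pair is scored

RL(X, A) = K1·PO(A) + K2·PP(X) + K3·PT(X) + K4·PR(X),
(K1, K2, K3, K4) = (0.2, 0.5, 0.4, 0.8).

All four components are kept on [0, 1] so the fixed coefficients are
scale-meaningful:

- **PO** — the fraction of terms in A's source ontology whose label or
  synonyms contain A's label as a case-insensitive substring. This is one
  defensible operationalization of "term frequency in the ontology"; it is
  bounded, cheap, and gives common umbrella terms higher weight than
  leaf-specific ones.
- **PP** — √tf(A, X) · idf² · |X|^(−1/2) with idf = 1 + ln(D/(df+1)), the
  classic practical TF-IDF form, divided by the maximum raw score of the
  term over the corpus (0 when the term is absent everywhere). The
  corpus-max normalization is ours; without it PP's scale would float with
  corpus size and swamp or starve the other components.
- **PT** — Σ_z w_z · tf(A, z)/max(1, |z|) over the five tag zones, divided
  by Σ_z w_z and capped at 1. Zone weights default to title 4, heading 3,
  anchor 2, table 1, body 1: monotone in the editorial prominence of the
  zone, otherwise a free choice.
- **PR** — PageRank with damping 0.85, uniform teleport, dangling mass
  redistributed uniformly, power iteration until the L1 change drops below
  1e-9 (flagged, not failed, at 200 iterations), normalized by the corpus
  maximum. Self-links are dropped when the link graph is built — a page
  cannot endorse itself — and parallel links collapse to one edge.

A document qualifies as a result only if it contains at least one word of
a matched term; otherwise the PR term alone would rank every document for
every query. Documents are scored against every matched term and keep
their best RL (max aggregation preserves the strongest evidence). For
multi-word term labels, PP and PT average the per-word scores. Retrieval
caps at the top 1000 documents; batch search deduplicates its input
(order-preserving) and rejects lists longer than 1000 genes outright —
silent truncation would hide caller errors.

Grouping of results into *exact* (an associated entity's name or synonym
contains the query substring) and *relevant* (entity merely co-occurs in
the document record) follows the retrieval display convention; exact
results list first. Results export to N-Triples with three predicates
(relevance score as a typed double, matched term, group), sorted for
byte-stable output.

## Document signatures and clustering

The descriptive word set is selected from all non-low-complexity words.
Low complexity means: pure DNA alphabet (ACGTN) of length ≥ 4, pure digit
runs of length ≥ 4, or single-character runs; such words are still indexed
for search but never enter a lexicon — a random sequence fragment is a
unique string, not a descriptor.

Per word, the threshold b(i) is the median of its positive relative
frequencies across documents, nudged one ulp downward so that a document
sitting exactly at the median sets its bit under the strict
"frequency > b(i)" rule (otherwise single-occurrence words could never
gain coverage). If the median thresholds fail to reach the coverage
target, b(i) relaxes to the 25th percentile and selection reruns. Word
quality is bit stability: 1 minus the mean within-source variance of the
bit, using the corpus's data-source labels as the bootstrap grouping
(stability "in similar documents" is circular before a lexicon exists, so
source grouping stands in). Selection is greedy max-coverage: repeatedly
take the word maximizing (newly covered documents × quality), ties
lexicographic, stopping when 95% of documents carry ≥ 1 set bit or at 512
words.

Signatures with three or fewer set bits are excluded from clustering;
within each data source, retained documents link when the normalized
Levenshtein distance between their bit strings is ≤ 0.10 (boundary
inclusive — "does not exceed 10%"), and clusters are the connected
components (single linkage). Excluded documents trail as singletons.
Edit distance is computed with edlib and normalized by the longer length;
Levenshtein rather than Hamming is retained deliberately even though
signature lengths are equal. Clusters and members order by best relevance
score when available, else by document id.

A consequence of the near-minimal-N stopping rule worth knowing: on small
corpora the greedy loop stops after a handful of words, so most documents
carry fewer than four set bits and are excluded from clustering. The rule
is kept because it is the stated selection objective; callers wanting
denser signatures can raise `coverage_target` or treat `max_N` as the
binding constraint.

## Table harvesting and promoter mapping

Every `<table>` element becomes a candidate (nested tables are flattened
depth-first, each cell counted once; ragged rows are padded). The first
row is treated as the header. A table is *relational* when it has ≥ 2
columns, ≥ 2 data rows, and some column's fraction of cells matching the
identifier vocabulary (gene names + synonyms, case-insensitive) reaches
`min_id_fraction` = 0.5, boundary inclusive; the densest column (leftmost
on ties) is the key. The original system used trained statistical column
classifiers; their training data is not available, so classification here
is deterministic by rule, and the 0.5 gate is configurable.

Non-key columns are harvested only if labeled in the header. A cell of
≥ 10 ACGTN characters is a DNA sequence; under a header containing
"promoter" it triggers the upstream scan, otherwise it is kept as a plain
`sequence` attribute; non-DNA labeled cells become named attributes. Rows
whose key cell resolves to no known gene are skipped and logged.

The upstream scan takes `upstream_bp` (default 10 000) bases 5′ of the
transcription start site on the gene's strand — reverse-complemented for
− genes, truncated at chromosome edges — and searches for the exact cell
sequence (no mismatches: fuzziness was never specified, and exactness
makes the coordinate round-trip verifiable). A hit yields a
`promoter_sequence` attribute with 0-based half-open coordinates on the +
reference strand (BED convention on disk); a miss keeps the sequence as an
uncoordinated attribute named by its column.

## Co-expression matrices

Per experiment, probe rows average arithmetically per gene; experiments
with fewer than 4 samples are skipped (the scaled Fisher transform needs
n − 3 > 0). Pearson correlations of every other gene with the query gene
feed z = atanh(r)·√(n−3), with r clamped to ±0.999999 so perfect
correlations stay finite. The √(n−3) standardization makes Z comparable
across experiments of different sample counts; the unscaled r grid is
retained alongside, and the highlight mask applies to r — strictly
r > 0.75 — not to Z. Constant-input correlations are recorded as 0 with a
degenerate flag rather than NaN. Ordering sorts genes by mean Z over
experiments and experiments by mean Z over genes, descending, ties by id,
NaN cells excluded from means; mean rather than sum keeps incomplete
matrices comparable. The word cloud tokenizes experiment descriptions,
drops a small shipped English stopword list and numerals, and keeps the
top 50 terms by count then alphabetically.

## Deep-web crawl

The crawler never touches the network: a form endpoint is a URL template
with one keyword slot plus a deterministic provider function (a
directory-backed provider ships for demos). Candidate keywords are page
tokens matching an ontology label or synonym. Expansion is breadth-first
with lexicographic order within a round; every keyword is probed exactly
once, every non-empty page is stored, and the crawl stops when the queue
empties (guaranteed on finite fixtures — the tried set only grows) or at
`max_rounds` = 100. The retrieved set therefore equals the reachable
closure of the seeds over the page-mention graph, which is what the
oracle tests assert. A helper implements the stricter initial form-validity
probe (non-empty page containing ≥ 1 ontology keyword).

## Synthetic fixtures

All inputs are generated by pure functions of a `FixtureSpec`; one master
seed fans out to independent per-generator streams, so identical specs
yield byte-identical files. Defaults are desk-scale (seconds, not
minutes): a 50-term layered DAG (is-a backbone to earlier layers plus
part-of/has-a cross edges — acyclic by construction); 100 HTML documents
over three sources with planted term placements per zone, Poisson(2)
hyperlinks, 20% relational gene/promoter tables and 10% decoy layout
tables; a 20-gene single-chromosome genome (1 kb genes, 2 kb intergenic,
alternating strands) with one 30 bp promoter recorded 50–500 bp upstream
of each TSS; and 20 expression experiments of 50 samples with a 5-gene
block correlated to the query gene at r_true = 0.9, 15 independent genes,
and 1–2 probes per gene with additive noise (σ = 0.1).

What the generators do *not* emulate: natural biomedical language (filler
text is drawn from a fixed vocabulary, so TF-IDF statistics are more
uniform than in real pages), realistic near-duplicate structure in the
corpus, heavy-tailed link topology, rowspan/colspan table layouts,
batch effects or missingness in expression data, and repeat-rich genomes
(planted promoters are unique at these sizes with overwhelming
probability). Passing tests therefore demonstrate correctness of the
algorithms and exact recovery of planted structure, not robustness to the
messiness of production web data.

## Numerical and degenerate-input conventions

- Tokens are maximal runs of letters/digits optionally joined by single
  internal periods (covers accession-style `hs.654481`), case-folded;
  tokenization is total and concatenation-invariant.
- Unparseable HTML degrades to a body-only document with a warning;
  empty ontology files load as empty graphs with a warning; cyclic
  ontologies are rejected naming an offending edge.
- PageRank non-convergence returns the last iterate with a flag rather
  than raising.
- Normalized Levenshtein requires non-empty inputs; empty gene lists and
  empty queries are usage errors; a query matching no ontology term is an
  empty result, not an error.
- All orderings (results, clusters, matrix rows/columns, RDF triples,
  crawl queue) specify explicit deterministic tie-breaks, so outputs are
  stable functions of the inputs.

## Known limitations

The PO definition is one reading of an underspecified quantity; learned
query-expansion weights are out of scope. Only trailing-`*`-free keyword
queries are supported (no wildcard grammar). The table parser does not
resolve rowspan/colspan beyond padding, and multi-gene synonym collisions
in key columns resolve to whichever gene model the vocabulary maps the
string to. The co-expression module computes, orders and highlights the
matrix but does not render heatmaps or clouds. The crawler handles
single-slot URL templates only.
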