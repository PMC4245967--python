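# Methods

## Scope and data model

pairsynt operates on *pairwise* comparisons of annotated complete
bacterial genomes.  A genome is an ordered list of replicons (file
order); each protein-coding gene carries 1-based inclusive coordinates, a
strand, functional annotations (GO terms partitioned by namespace, EC
numbers, cross-references, free-text product) and a genome-wide *rank* —
its 0-based position in the concatenation of replicons.  Rank order, not
base-pair position, is the coordinate system of the synteny algorithm.
One protein product per gene is assumed, which excludes eukaryotes;
pseudogenes and CDS without a protein product are skipped with a warning.
Genes wrapping the origin of a circular replicon keep their annotated
start and are placed last in rank order (a deterministic convention; the
alternative — splitting them — would break the one-gene-one-rank
invariant).

## Orthology

All-vs-all protein hits are consumed as 12-column tabular files.  Only
hits with e-value strictly below 0.01 are stored; multiple HSPs of a pair
collapse to the best one (lowest e-value, then highest bit score).  Query
coverage is reconstructed from the tabular columns as
100·(qend − qstart + 1)/protein_length.

Orthology is operational: a bidirectional best hit.  Best = lowest
e-value, then highest bit score, then lexicographically smallest subject
id.  The id tie-break carries no biological meaning; it exists solely so
that two runs of the pipeline agree.  E-value is the primary criterion;
bit-score-primary ranking would be a one-line change and is deliberately
not exposed as an option until someone needs it.  Stored pairs that are
not BDBH are plain homologs.  Within-genome paralogy is never computed —
duplications surface as one reference gene having several cross-genome
homologs.

## Synteny dynamic programming

Per replicon pair and per orientation (compared gene order as-is, and
reversed), gene strings are aligned with a local Gotoh algorithm:

* aligning a related pair scores +4 (ortholog) or +2 (homolog);
* aligning an unrelated pair is a mismatch, −4;
* a maximal run of k skipped genes on one genome costs −8 − 2(k − 1)
  (gap creation covers the first skipped gene; the alternative
  convention −8 − 2k is available as `gap_mode="open_plus_per_gene"`).
  Direct transitions between a gap in one genome and a gap in the other
  are disallowed; a mismatch column (−4) is always cheaper than such a
  double gap anyway.

Chains are terminally anchored: a local optimum can neither start nor end
on a mismatch or gap (a negative terminal column always lowers the
score), and a defensive trim asserts this.  Chains with score ≥ 2 and
≥ 1 anchor are kept; both thresholds, and all five scores, are
configurable.  "Minimum alignment size 1" is read as *anchor count*, the
only reading under which a single homologous pair is admissible together
with minimum score 2.

Successive sub-optimal chains are extracted Waterman–Eggert style: all
diagonal cells used by an accepted chain are masked (gaps may still cross
them) and the DP is re-run until nothing of score ≥ 2 remains.  Traceback
ties prefer: fresh start (trims zero-contribution prefixes), then
diagonal, then gap-in-compared, then gap-in-reference.  Scores are exact
integers under the default parameters.

**Reconciliation.**  Candidates from all replicon pairs and both
orientations are processed best-first (score, then forward before
reversed, then reference position).  A block's footprint on each genome
is the full rank interval between its first and last anchor — including
genes the chain skipped — so that accepted primary blocks are
interval-disjoint and the event chain below partitions the reference.  A
candidate whose anchor-pair set is contained in an already kept block is
a duplicate and dropped (single anchors are found identically in both
orientations, and leftover single anchors inside an inversion are
sub-chains of the reversed block); reversed chains with one anchor are
not emitted at all, singletons being forward by convention.  A candidate
overlapping a primary's footprint on either genome becomes an *offshoot*
— an alternative homologous copy (duplication/paralogy).  Blocks never
span replicon boundaries; the strand of individual genes is ignored, only
gene order matters.

**Events.**  Primary blocks sorted by reference start, interleaved with
the maximal uncovered reference stretches (`ref_specific`, possibly
gene-free for an empty replicon), form the backbone of the event chain.
Compared-genome stretches covered by no block at all become
`cmp_specific` events attached to their nearest flanking block on the
compared genome — left flank preferred, a stretch before the first block
attaches to (and precedes) that block, and a replicon with no blocks at
all goes to the end of the chain.  Every reference gene belongs to
exactly one non-offshoot event.

## Profiles, filters, core/dispensable

The presence profile labels each (reference gene, compared genome) cell
`ortholog` (a BDBH exists), `homolog_only` (only weaker homologs) or
`absent`; all supporting relations stack in the cell for offshoot
browsing.  Filters (location, name, annotation text, GO term, EC number,
cross-reference, motif text, presence/absence with an
ortholog/any-homolog predicate) combine in an AND/OR tree; AND over zero
children is the universe, OR over zero children is empty.  The
configuration format accepts arbitrary trees; the command line accepts a
flat list with one global operator, which sidesteps AND/OR precedence
entirely.  Motif filters match annotation text only — the pipeline stores
annotations, not sequence scans.  Core genes satisfy the presence
predicate in every genome of the chosen subset; dispensable is the
complement; the BDBH predicate is the default, `any_homolog` the
alternative.

## Annotation comparator

For one reference gene and the homologs passing the active filter
(max e-value, min % identity, min % query coverage, orthologs-only,
organism subset), annotations of four classes (three GO namespaces, EC)
are classified Shared / Missing / Unique.  Counting is per *organism*:
any admitted homolog within an organism suffices, and each annotation
reports the ratio of its organism count to the organisms compared.
Annotation identity is exact identifier equality — no GO-graph ancestor
expansion (a possible extension; it would only grow the shared sets).
Free-text products are excluded by default as too heterogeneous for
exact matching; a flag includes them with exact-string semantics.  GO
terms whose namespace the source does not state land in an
`unspecified` bucket that the comparator ignores.

## Binomial statistic

`binomial_pvalue(k, n, p)` returns both P(X = k) and P(X ≥ k) for
X ~ Bin(n, p), computed by scipy's log-space pmf/sf (no underflow at the
extreme values typical of enrichment claims; the test suite cross-checks
against an independent lgamma implementation to 1e-10 relative error).
The *point* probability is the default headline value: of the two
worked examples wired into the golden tests (k=24, n=24,
p=0.54 → 3.8e-7 and k=35, n=40, p=0.54 → 5.8e-6), the second is
reproduced only by the point probability — the upper tail gives 6.9e-6 —
so the point convention is adopted and both numbers are always printed.
`locus_overlap_test` maps a gene set and a collection of loci onto the
same statistic: n = |set|, k = |set ∩ ∪loci|, p = |∪loci| / genome size
in genes.  No multiple-testing correction is applied.

## Synthetic data generator

The generator emulates descent from a common ancestor: an ancestral gene
order with annotations drawn from small fixed pools, and descendants
derived by inversions, translocations, segmental duplications, island
gains and gene losses placed in disjoint windows with ≥ 4 untouched genes
between any two events.  Hit e-values are synthesized, not computed:
true-ortholog e-values (1e-50..1e-20) sit strictly below
paralog/secondary hits (1e-8..1e-3), making planted orthologs mutual best
hits by construction, and decoy hits land at or above 0.01 to exercise
the storage filter.  Protein sequences are arbitrary amino-acid strings
of the declared lengths.  A fixed seed reproduces byte-identical files.

Default study conditions: 2 genomes × 60 genes, one 20-gene inversion,
one 5-gene island, one 3-gene duplication, two single-gene losses.  The
inversion spans a third of the genome deliberately: bridging an inverted
segment of k genes costs ~4k (k mismatch columns), so a flanking
collinear run scoring more than 4k would absorb a smaller inversion as
mismatches.  With k ≥ (genome − k)/2 no flank can reach that score and
the reversed block is always recovered as such.  The same arithmetic
defines the **detectability regime** in which the truth table's expected
blocks are well defined at all: two adjacent runs merge into one reported
block exactly when the bridge (mismatches plus at most one gap run per
genome) costs less than the weaker flank, and the generator's expected
blocks are computed by an independent chainer that applies that criterion
to the planted correspondence — strictly collinear maximal runs with
in-run gaps ≤ 2, then bridge-cost merging.  Translocations default to 0
because at realistic genome sizes a short translocated segment leaves
flanks strong enough to bridge across its excision site, which makes the
expected outcome configuration-dependent; the translocation test uses a
10-gene configuration where the outcome is provable.

The planted-block fixture builder used by the recovery tests is stricter
still: blocks of 2–7 ortholog anchors separated by unrelated filler genes
sized to (min adjacent anchor count) + 1 — always ≥ 3 — which provably
exceeds any bridging gain; internal gaps of 1–2 skipped genes occur only
with ≥ 3 anchors on each side, so the DP provably bridges them; one block
is reversed and one is duplicated at a distant locus through weaker
homolog relations, which must surface as exactly one offshoot.

What the generator does *not* emulate: sequence-level evolution, gene
fusion/fission (unrepresentable under one-protein-per-gene), overlapping
or nested events, operon structure, and realistic e-value/identity
correlations.  Passing recovery tests therefore demonstrates the
correctness of the inference machinery inside the stated regime, not
performance on real genomes, where tangled rearrangements can make
"the" true block decomposition ill-defined.

## Layout

The SVG view is static and deterministic.  Symbols follow event order
(reference-start order with compared-specific insertions), one glyph per
event: rectangle for forward synteny, bowtie for reversed, a distinct
glyph for single-anchor homologies, half-size rectangles or lines for
genome-specific regions with or without genes.  Two proportional tracks
map concatenated bp coordinates affinely to x; each synteny symbol gets a
trapezoid joining its reference and compared spans and a triangular
marker at its proportional location.  Windowing clips the reference track
and drops symbols wholly outside the window.  Glyph kinds are CSS
classes; exact geometry is aesthetic and untested.

## Numerical and degenerate-input choices

* All synteny arithmetic is integer; no floating-point scores.
* Empty inputs are valid everywhere downstream of parsing: no relations →
  no blocks; no blocks → the whole reference is one specific region per
  replicon; an empty direction of a hit-table pair is allowed.
* Catalog TSV, relations TSV, blocks TSV and events JSON round-trip
  exactly and are byte-deterministic (sets serialized sorted).
* Problem sizes in the test suite and acceptance script — 200 random
  ≤ 8-gene instances for the enumeration oracle, 12 planted fixtures,
  60-gene simulated pairs — keep the full suite under a few seconds while
  exercising every code path; the DP is quadratic per replicon pair and
  handles desk-scale genomes (hundreds of genes) comfortably, but no
  attempt is made at chromosome-scale performance engineering.

## Known limitations

* BDBH is a deliberately simple orthology model: no tree reconciliation,
  no in-paralog clustering, no synteny-aware rescue of weak orthologs.
* Block reconciliation is greedy best-first; a globally optimal
  non-overlapping chain cover is not attempted.
* The comparator treats annotations as opaque identifiers; GO semantic
  similarity is out of scope.
* The interactive, multi-genome browsing experience this pipeline's data
  model supports is not part of the package — rendering is one static
  SVG per comparison.
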