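# pairsynt

Pairwise comparative genomics for bacteria: given annotated complete
genomes and all-vs-all protein comparison results, **pairsynt** infers
orthologs, detects conserved and inverted synteny blocks along the gene
order, segments each pairwise comparison into an alternating chain of
homologous and genome-specific regions, builds gene × genome presence
profiles with combinable filters and core/dispensable gene sets, compares
functional annotations between a gene and its homologs, and tests gene
sets for enrichment with the binomial law.  It is aimed at
microbiologists and annotators exploring pangenomes, horizontal transfer
hotspots and annotation transfer between related strains — at desk scale,
with plain files between stages.

No aligner is run and no database is needed: protein hits arrive as
12-column tabular files (the BLAST `outfmt 6` dialect), genomes as
GenBank/EMBL flat files or GFF3 + protein FASTA.  A synthetic-data
generator plants inversions, translocations, duplications, gene gains and
losses with a machine-readable truth table, so the entire pipeline is
testable without any external dataset.

## The model

**Orthology.**  Hits with e-value ≥ 0.01 are discarded (strict).  Two
genes *a* ∈ A, *b* ∈ B are *orthologs* iff they form a bidirectional best
hit (BDBH): *b* is *a*'s best subject and *a* is *b*'s (best = lowest
e-value, then highest bit score, then lexicographically smallest id for
determinism).  Every other stored cross-genome pair is a plain *homolog*.

**Synteny.**  For each replicon pair, the two gene orders are aligned by
local dynamic programming (Gotoh, affine gaps), twice: against the
compared order as-is (forward) and reversed (inversions).  Column scores:

| column                | score |
|-----------------------|------:|
| ortholog pair         |   +4  |
| homolog pair          |   +2  |
| mismatch (unrelated)  |   −4  |
| gap creation          |   −8  |
| gap extension         |   −2  |

A run of *k* skipped genes costs −8 − 2(k−1).  Chains must start and end
on a homologous pair and are kept when score ≥ 2 with ≥ 1 anchor;
sub-optimal chains are extracted by Waterman–Eggert masking.  The
highest-scoring block over a stretch of either genome is *primary*;
blocks re-using claimed genes (duplications, paralogy) become *offshoots*.
Primary blocks and the uncovered stretches between them form the event
chain — synteny blocks, reference-specific and compared-specific regions
— that the SVG layout renders as the classic symbolic + proportional
(trapezoid) display, with a bowtie glyph for reversed synteny.

**Enrichment.**  For *k* successes in *n* trials at success probability
*p*, both P(X = k) and P(X ≥ k) of X ~ Bin(n, p) are reported; the point
probability is the default headline value.

## Worked example

The bundled toy (`pairsynt.worked_toy`) is a deterministic 40-gene genome
pair with one 14-gene inversion, a 5-gene island, a 3-gene segmental
duplication and one gene loss:

```python
import tempfile
from pairsynt import (worked_toy, parse_hits, call_relations, compute_blocks,
                      segment_events, build_profile, core_dispensable,
                      binomial_pvalue)

toy = worked_toy(tempfile.mkdtemp())
a, b = toy.catalogs["G0"], toy.catalogs["G1"]
rels = call_relations(parse_hits(toy.hit_paths[("G0", "G1")], a, b),
                      parse_hits(toy.hit_paths[("G1", "G0")], b, a))
blocks = compute_blocks(a, b, rels)
events = segment_events(a, b, blocks)
core, disp = core_dispensable(build_profile(a, [("G1", rels)]), ["G1"])
```

which prints (`42 relations, 39 orthologs`):

```
primary  forward  anchors=13 score=40
primary  reversed anchors=14 score=56
primary  forward  anchors= 8 score=24
primary  forward  anchors= 4 score=16
offshoot forward  anchors= 3 score=6
event chain: synteny -> synteny -> synteny -> cmp_specific -> synteny
core=39 dispensable=1 (['G0_0031'])
```

The reversed 14-anchor block is the planted inversion (a bowtie in the
rendered SVG); the first block's score is 13 × 4 minus the bridged gap
where the duplication inserted its copies; the offshoot is that
duplication; the `cmp_specific` event is the gained island; the single
dispensable gene is the planted loss.  And the enrichment statistic:

```python
res = binomial_pvalue(24, 24, 0.54)
# P(X=24)=3.78e-07  P(X>=24)=3.78e-07
```

i.e. observing 24 pathogens among 24 synteny carriers when 54 % of the
reference pool is pathogenic has a binomial p-value of 3.8e-7.

The same pipeline is available from the shell:

```
pairsynt simulate --seed 7 --out sim/
pairsynt ingest --genome sim/G0.gbk --genome-id G0 --out G0.tsv
pairsynt ingest --genome sim/G1.gbk --genome-id G1 --out G1.tsv
pairsynt relations --catalog-a G0.tsv --catalog-b G1.tsv \
    --hits-ab sim/hits_G0_vs_G1.tsv --hits-ba sim/hits_G1_vs_G0.tsv --out rel.tsv
pairsynt synteny --ref G0.tsv --cmp G1.tsv --relations rel.tsv --out blocks.tsv
pairsynt events --ref G0.tsv --cmp G1.tsv --blocks blocks.tsv --out events.json
pairsynt render --events events.json --ref G0.tsv --cmp G1.tsv --out view.svg
pairsynt stats binomial --k 24 --n 24 --p 0.54
```

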