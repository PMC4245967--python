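"""Protein-hit parsing, the storage filter, and BDBH orthology.

All-vs-all protein comparison results arrive as 12-column tabular files
(the BLAST/DIAMOND ``outfmt 6`` dialect).  Hits with an e-value of 0.01 or
above are discarded outright — only hits below that threshold are stored.
Two genes of different genomes are called *orthologs* when they form a
bidirectional best hit (BDBH): each is the other's best-scoring subject.
Every other stored cross-genome hit pair is a plain *homolog* relation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .genome_io import GenomeCatalog, ValidationError

logger = logging.getLogger("pairsynt")

#: Storage threshold: hits must satisfy evalue < STORE_EVALUE (strict).
STORE_EVALUE = 0.01

ORTHOLOG = "ortholog"
HOMOLOG = "homolog"


@dataclass(frozen=True)
class HomologyHit:
    """Best HSP of one query/subject protein pair (one direction)."""

    query_gene_id: str
    subject_gene_id: str
    pct_identity: float
    aln_length: int
    evalue: float
    bitscore: float
    query_coverage: float  # 100 * aligned query residues / query protein length


@dataclass(frozen=True)
class HomologyRelation:
    """One unordered cross-genome gene pair with its best hits.

    ``gene_a`` belongs to the first genome of the pair (the query genome of
    ``hits_ab`` in :func:`call_relations`), ``gene_b`` to the second.
    """

    gene_a: str
    gene_b: str
    kind: str  # ORTHOLOG or HOMOLOG
    best_hit_a_to_b: Optional[HomologyHit]
    best_hit_b_to_a: Optional[HomologyHit]

    @property
    def relation_id(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"

    def other(self, gene_id: str) -> str:
        return self.gene_b if gene_id == self.gene_a else self.gene_a

    def best_evalue(self) -> float:
        evs = [h.evalue for h in (self.best_hit_a_to_b, self.best_hit_b_to_a) if h]
        return min(evs)

    def best_identity(self) -> float:
        return max(
            h.pct_identity for h in (self.best_hit_a_to_b, self.best_hit_b_to_a) if h
        )

    def coverage_of(self, gene_id: str) -> float:
        """Query coverage of the direction in which *gene_id* is the query."""
        if gene_id == self.gene_a and self.best_hit_a_to_b:
            return self.best_hit_a_to_b.query_coverage
        if gene_id == self.gene_b and self.best_hit_b_to_a:
            return self.best_hit_b_to_a.query_coverage
        return 0.0


# ---------------------------------------------------------------------------
# Hit-table parsing
# ---------------------------------------------------------------------------

def parse_hits(path, catalog_a: GenomeCatalog, catalog_b: GenomeCatalog,
               evalue_threshold: float = STORE_EVALUE) -> list:
    """Parse a 12-column tabular hit file for one genome pair.

    Applies the storage filter (``evalue < evalue_threshold``, strict),
    discards same-genome hits with a logged count, and collapses multiple
    HSPs of one query/subject pair to the single best one (lowest e-value,
    then highest bit score).  Gene ids must resolve in one of the two
    catalogs; the query's catalog supplies the protein length used for
    query coverage = 100 * (qend - qstart + 1) / protein_length.
    """
    best: dict = {}
    n_same = n_filtered = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 12:
            raise ValidationError(
                f"{path}:{lineno}: expected 12 tab-separated columns, got {len(f)}"
            )
        try:
            qid, sid = f[0], f[1]
            pident, alen = float(f[2]), int(f[3])
            qstart, qend = int(f[6]), int(f[7])
            evalue, bits = float(f[10]), float(f[11])
        except ValueError as exc:
            raise ValidationError(f"{path}:{lineno}: malformed line: {exc}") from exc

        qcat = catalog_a if qid in catalog_a else catalog_b if qid in catalog_b else None
        scat = catalog_a if sid in catalog_a else catalog_b if sid in catalog_b else None
        if qcat is None:
            raise ValidationError(f"{path}:{lineno}: unknown query gene id {qid!r}")
        if scat is None:
            raise ValidationError(f"{path}:{lineno}: unknown subject gene id {sid!r}")
        if qcat is scat:
            n_same += 1
            continue
        if evalue >= evalue_threshold:
            n_filtered += 1
            continue

        plen = qcat.gene(qid).protein_length
        cov = 100.0 * (qend - qstart + 1) / plen if plen else 0.0
        hit = HomologyHit(qid, sid, pident, alen, evalue, bits, cov)
        key = (qid, sid)
        prev = best.get(key)
        if prev is None or (hit.evalue, -hit.bitscore) < (prev.evalue, -prev.bitscore):
            best[key] = hit
    if n_same:
        logger.warning("%s: discarded %d same-genome hits", Path(path).name, n_same)
    if n_filtered:
        logger.info("%s: %d hits at or above e-value %g discarded",
                    Path(path).name, n_filtered, evalue_threshold)
    return list(best.values())


# ---------------------------------------------------------------------------
# BDBH ortholog calling
# ---------------------------------------------------------------------------

def _best_subject(hits: Iterable[HomologyHit]) -> dict:
    """Best subject per query: lowest e-value, then highest bit score,
    then lexicographically smallest subject id (determinism)."""
    best = {}
    for h in hits:
        prev = best.get(h.query_gene_id)
        if prev is None or (h.evalue, -h.bitscore, h.subject_gene_id) < (
            prev.evalue, -prev.bitscore, prev.subject_gene_id
        ):
            best[h.query_gene_id] = h
    return best


def call_relations(hits_ab: Iterable[HomologyHit],
                   hits_ba: Iterable[HomologyHit]) -> list:
    """Call ortholog (BDBH) and homolog relations for one genome pair.

    ``hits_ab`` are hits with genome-A queries, ``hits_ba`` the reverse
    direction; either may be empty.  Each unordered pair appears at most
    once.  A pair is an ortholog iff each gene is the other's best subject;
    every other stored hit pair yields a homolog relation.
    """
    hits_ab, hits_ba = list(hits_ab), list(hits_ba)
    ab_by_pair = {(h.query_gene_id, h.subject_gene_id): h for h in hits_ab}
    ba_by_pair = {(h.query_gene_id, h.subject_gene_id): h for h in hits_ba}
    best_ab = _best_subject(hits_ab)
    best_ba = _best_subject(hits_ba)

    pairs = {(a, b) for a, b in ab_by_pair} | {(a, b) for b, a in ba_by_pair}
    relations = []
    for a, b in sorted(pairs):
        best_a = best_ab.get(a)
        best_b = best_ba.get(b)
        is_bdbh = (
            best_a is not None and best_b is not None
            and best_a.subject_gene_id == b and best_b.subject_gene_id == a
        )
        relations.append(
            HomologyRelation(
                gene_a=a,
                gene_b=b,
                kind=ORTHOLOG if is_bdbh else HOMOLOG,
                best_hit_a_to_b=ab_by_pair.get((a, b)),
                best_hit_b_to_a=ba_by_pair.get((b, a)),
            )
        )
    return relations


# ---------------------------------------------------------------------------
# Relations TSV round trip
# ---------------------------------------------------------------------------

_REL_HEADER = (
    "gene_a", "gene_b", "kind", "evalue_ab", "evalue_ba", "pct_identity",
    "query_coverage_ab", "query_coverage_ba", "bitscore_ab", "bitscore_ba",
)


def write_relations(relations: Iterable[HomologyRelation], path) -> None:
    lines = ["#" + "\t".join(_REL_HEADER)]
    for r in sorted(relations, key=lambda r: (r.gene_a, r.gene_b)):
        ab, ba = r.best_hit_a_to_b, r.best_hit_b_to_a
        lines.append("\t".join([
            r.gene_a, r.gene_b, r.kind,
            f"{ab.evalue:.3e}" if ab else "",
            f"{ba.evalue:.3e}" if ba else "",
            f"{r.best_identity():.1f}",
            f"{ab.query_coverage:.1f}" if ab else "",
            f"{ba.query_coverage:.1f}" if ba else "",
            f"{ab.bitscore:.1f}" if ab else "",
            f"{ba.bitscore:.1f}" if ba else "",
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_relations(path) -> list:
    """Read a relations TSV written by :func:`write_relations`.

    Reconstructed hits carry only the fields the TSV stores; alignment
    length is not round-tripped (set to 0).
    """
    relations = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        if len(f) != len(_REL_HEADER):
            raise ValidationError(f"{path}:{lineno}: bad relations row")
        a, b, kind = f[0], f[1], f[2]
        ident = float(f[5])
        ab = (HomologyHit(a, b, ident, 0, float(f[3]), float(f[8]), float(f[6]))
              if f[3] else None)
        ba = (HomologyHit(b, a, ident, 0, float(f[4]), float(f[9]), float(f[7]))
              if f[4] else None)
        relations.append(HomologyRelation(a, b, kind, ab, ba))
    return relations


def relation_map(relations: Iterable[HomologyRelation]) -> dict:
    """Map unordered gene pair -> relation kind, for the synteny DP."""
    out = {}
    for r in relations:
        out[(r.gene_a, r.gene_b)] = r.kind
        out[(r.gene_b, r.gene_a)] = r.kind
    return out
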