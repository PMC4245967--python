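"""Reading annotated genomes into ordered gene catalogs.

A genome is modelled as an ordered list of replicons (chromosomes and
plasmids, in file order), each carrying an ordered list of protein-coding
genes.  The genome-wide gene *rank* — the 0-based position of a gene in the
concatenation of its genome's replicons — is the coordinate system every
downstream step (orthology, synteny dynamic programming, profiles) works in.

Coordinates are kept 1-based inclusive, as in GenBank/EMBL flat files.
One protein product per gene is assumed; this rules out eukaryotic genomes
with alternative transcripts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger("pairsynt")

#: GO namespaces recognised by the annotation comparator.  Terms whose
#: namespace cannot be determined from the source go to "unspecified".
GO_NAMESPACES = ("molecular_function", "biological_process", "cellular_component")
GO_UNSPECIFIED = "unspecified"

_CATALOG_COLUMNS = (
    "gene_id",
    "genome_id",
    "replicon_id",
    "start",
    "end",
    "strand",
    "rank",
    "protein_length",
    "product",
    "go_molecular_function",
    "go_biological_process",
    "go_cellular_component",
    "go_unspecified",
    "ec_numbers",
    "xrefs",
)


class PairsyntError(Exception):
    """Base class for all fatal errors raised by this package."""


class ValidationError(PairsyntError):
    """Bad user input: unparsable file, unknown identifier, bad parameter."""


@dataclass(frozen=True)
class GeneRecord:
    """One protein-coding gene.

    ``go_terms`` maps each GO namespace (plus ``unspecified``) to a frozen
    set of GO identifiers.  ``start``/``end`` are 1-based inclusive base
    pairs with ``start <= end``.
    """

    gene_id: str
    genome_id: str
    replicon_id: str
    start: int
    end: int
    strand: str
    rank: int
    protein_length: int
    product: str = ""
    go_terms: Mapping[str, frozenset] = field(default_factory=dict)
    ec_numbers: frozenset = frozenset()
    xrefs: frozenset = frozenset()

    def __post_init__(self):
        if self.start < 1 or self.start > self.end:
            raise ValidationError(
                f"gene {self.gene_id}: invalid span {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    def all_go_terms(self) -> frozenset:
        out = set()
        for terms in self.go_terms.values():
            out |= terms
        return frozenset(out)


@dataclass
class GenomeCatalog:
    """Ordered gene catalog of one genome.

    ``replicon_ids`` preserves file order; ``genes`` is the rank-ordered,
    genome-wide gene list.  ``replicon_lengths`` maps replicon id to its
    length in bp, from which cumulative offsets are derived for the
    concatenated proportional display.
    """

    genome_id: str
    replicon_ids: list
    replicon_lengths: dict
    genes: list  # rank order

    def __post_init__(self):
        self._by_id = {}
        for g in self.genes:
            if g.gene_id in self._by_id:
                raise ValidationError(
                    f"duplicate gene id {g.gene_id!r} in genome {self.genome_id}"
                )
            self._by_id[g.gene_id] = g
        for i, g in enumerate(self.genes):
            if g.rank != i:
                raise ValidationError(
                    f"genome {self.genome_id}: rank {g.rank} at position {i}"
                )

    # -- lookups -----------------------------------------------------------
    def __len__(self):
        return len(self.genes)

    def __contains__(self, gene_id):
        return gene_id in self._by_id

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise ValidationError(
                f"unknown gene id {gene_id!r} in genome {self.genome_id}"
            ) from None

    def genes_on(self, replicon_id: str) -> list:
        return [g for g in self.genes if g.replicon_id == replicon_id]

    @property
    def cumulative_offsets(self) -> dict:
        """bp offset of each replicon in the concatenated display."""
        off, total = {}, 0
        for rid in self.replicon_ids:
            off[rid] = total
            total += self.replicon_lengths[rid]
        return off

    @property
    def total_bp(self) -> int:
        return sum(self.replicon_lengths.values())


# ---------------------------------------------------------------------------
# Flat-file loading
# ---------------------------------------------------------------------------

def _go_sets():
    return {ns: set() for ns in GO_NAMESPACES + (GO_UNSPECIFIED,)}


def _freeze_go(go: dict) -> dict:
    return {ns: frozenset(v) for ns, v in go.items() if v}


def _gene_from_seqfeature(feat, genome_id, replicon_id, replicon_len):
    """Build the pre-rank fields of a GeneRecord from a Bio CDS feature.

    Returns ``None`` for pseudogenes and CDS without a protein product
    (both skipped with a logged warning).  Origin-wrapping genes on circular
    replicons are flagged so the caller can place them last in rank order.
    """
    q = feat.qualifiers
    if "pseudo" in q or "pseudogene" in q:
        return None
    gene_id = (q.get("locus_tag") or q.get("protein_id") or q.get("gene") or [None])[0]
    if gene_id is None:
        return None

    loc = feat.location
    start, end = int(loc.start) + 1, int(loc.end)
    wraps = False
    parts = getattr(loc, "parts", [loc])
    if len(parts) > 1 and int(parts[0].start) > int(parts[-1].end) - 1:
        # compound location running through the origin of a circular replicon
        wraps = True
        start = int(parts[0].start) + 1
        end = int(parts[-1].end)
        logger.info(
            "gene %s wraps the origin of %s; placed last in rank order",
            gene_id, replicon_id,
        )
    strand = "-" if loc.strand == -1 else "+"

    translation = q.get("translation", [None])[0]
    if translation:
        plen = len(translation)
    else:
        span = (end - start + 1) if not wraps else (replicon_len - start + 1 + end)
        if span % 3 == 0 and span >= 6:
            plen = span // 3 - 1  # minus stop codon
        else:
            return None

    go = _go_sets()
    for key, ns in (
        ("GO_function", "molecular_function"),
        ("GO_process", "biological_process"),
        ("GO_component", "cellular_component"),
    ):
        for val in q.get(key, []):
            for tok in val.replace(",", " ").split():
                if tok.startswith("GO:"):
                    go[ns].add(tok)
    xrefs = set()
    for val in q.get("db_xref", []):
        if val.startswith("GO:"):
            go[GO_UNSPECIFIED].add(val)
        else:
            xrefs.add(val)

    rec = dict(
        gene_id=gene_id,
        genome_id=genome_id,
        replicon_id=replicon_id,
        start=start,
        end=max(start, end) if wraps else end,
        strand=strand,
        rank=-1,
        protein_length=plen,
        product=q.get("product", [""])[0],
        go_terms=_freeze_go(go),
        ec_numbers=frozenset(q.get("EC_number", [])),
        xrefs=frozenset(xrefs),
    )
    return rec, wraps


def _assemble(genome_id, replicon_order, replicon_lengths, staged):
    """Sort per replicon, assign genome-wide ranks, build the catalog."""
    genes, rank = [], 0
    for rid in replicon_order:
        entries = staged.get(rid, [])
        # origin-wrapping genes (wraps=True) sort after everything else
        entries.sort(key=lambda e: (e[1], e[0]["start"], e[0]["end"], e[0]["gene_id"]))
        for rec, _ in entries:
            genes.append(GeneRecord(**{**rec, "rank": rank}))
            rank += 1
    return GenomeCatalog(genome_id, list(replicon_order), dict(replicon_lengths), genes)


def load_genome(path, format="genbank", protein_fasta=None, genome_id=None):
    """Read an annotated genome into a :class:`GenomeCatalog`.

    Parameters
    ----------
    path : path to a GenBank / EMBL flat file, or to a GFF3 file.
    format : one of ``genbank``, ``embl``, ``gff3``.
    protein_fasta : required for ``gff3``; FASTA of protein products keyed
        by CDS ID (used for protein lengths).
    genome_id : defaults to the stem of *path*.

    One GeneRecord is produced per CDS feature; non-CDS features are
    ignored, pseudogenes and CDS without a protein product are skipped with
    a warning.  Replicons keep file order and ranks are assigned over the
    concatenation of replicons, chromosomes and plasmids consecutively.
    """
    path = Path(path)
    gid = genome_id or path.stem
    if format == "gff3":
        return _load_gff3(path, protein_fasta, gid)
    if format not in ("genbank", "embl"):
        raise ValidationError(f"unknown genome format {format!r}")

    try:
        records = list(SeqIO.parse(str(path), format))
    except Exception as exc:  # Biopython raises assorted ValueErrors
        raise ValidationError(f"cannot parse {path} as {format}: {exc}") from exc
    if not records:
        raise ValidationError(f"no records found in {path} ({format})")

    replicon_order, replicon_lengths, staged = [], {}, {}
    seen = {}
    n_skipped = 0
    for rec in records:
        rid = rec.id
        replicon_order.append(rid)
        replicon_lengths[rid] = len(rec.seq)
        staged[rid] = []
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            built = _gene_from_seqfeature(feat, gid, rid, len(rec.seq))
            if built is None:
                n_skipped += 1
                continue
            g, wraps = built
            if g["gene_id"] in seen:
                raise ValidationError(
                    f"duplicate locus tag {g['gene_id']!r}: on {seen[g['gene_id']]} "
                    f"and on {rid} at {g['start']}..{g['end']}"
                )
            seen[g["gene_id"]] = rid
            staged[rid].append((g, wraps))
    if n_skipped:
        logger.warning("%s: skipped %d CDS without a protein product", path.name, n_skipped)
    return _assemble(gid, replicon_order, replicon_lengths, staged)


def _load_gff3(path, protein_fasta, gid):
    import gffutils

    if protein_fasta is None:
        raise ValidationError("gff3 input requires a protein FASTA (protein_fasta=)")
    proteins = {r.id: str(r.seq) for r in SeqIO.parse(str(protein_fasta), "fasta")}

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique", force=True
        )
    except Exception as exc:
        raise ValidationError(f"cannot parse {path} as GFF3: {exc}") from exc

    # replicon order: ##sequence-region directives, falling back to feature order
    replicon_order, replicon_lengths = [], {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) >= 4:
                replicon_order.append(parts[1])
                replicon_lengths[parts[1]] = int(parts[3])

    staged, seen, n_skipped = {}, {}, 0
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        rid = feat.seqid
        if rid not in replicon_order:
            replicon_order.append(rid)
        gene_id = (feat.attributes.get("locus_tag") or feat.attributes.get("ID") or [None])[0]
        if gene_id is None:
            n_skipped += 1
            continue
        if "pseudo" in feat.attributes or "pseudogene" in feat.attributes:
            n_skipped += 1
            continue
        if gene_id not in proteins:
            n_skipped += 1
            logger.warning("CDS %s has no protein in %s; skipped", gene_id, protein_fasta)
            continue
        if gene_id in seen:
            raise ValidationError(
                f"duplicate CDS id {gene_id!r}: on {seen[gene_id]} and on {rid}"
            )
        seen[gene_id] = rid
        go = _go_sets()
        for term in feat.attributes.get("Ontology_term", []):
            if term.startswith("GO:"):
                go[GO_UNSPECIFIED].add(term)
        rec = dict(
            gene_id=gene_id,
            genome_id=gid,
            replicon_id=rid,
            start=feat.start,
            end=feat.end,
            strand="-" if feat.strand == "-" else "+",
            rank=-1,
            protein_length=len(proteins[gene_id].rstrip("*")),
            product=(feat.attributes.get("product") or [""])[0],
            go_terms=_freeze_go(go),
            ec_numbers=frozenset(feat.attributes.get("ec_number", [])),
            xrefs=frozenset(feat.attributes.get("Dbxref", [])),
        )
        staged.setdefault(rid, []).append((rec, False))
    if n_skipped:
        logger.warning("%s: skipped %d CDS", path, n_skipped)
    for rid in replicon_order:
        replicon_lengths.setdefault(
            rid, max((r["end"] for r, _ in staged.get(rid, [])), default=0)
        )
    return _assemble(gid, replicon_order, replicon_lengths, staged)


# ---------------------------------------------------------------------------
# Gene-table TSV round trip
# ---------------------------------------------------------------------------

def _join(values: Iterable[str]) -> str:
    return ";".join(sorted(values))


def write_catalog(catalog: GenomeCatalog, path) -> None:
    """Write a catalog as a tab-separated gene table.

    Header lines are '#'-prefixed: one ``#genome`` line, one ``#replicon``
    line per replicon (file order, with length in bp), then the column
    header.  Deterministic: identical catalogs produce identical bytes.
    """
    lines = [f"#genome\t{catalog.genome_id}"]
    for rid in catalog.replicon_ids:
        lines.append(f"#replicon\t{rid}\t{catalog.replicon_lengths[rid]}")
    lines.append("#" + "\t".join(_CATALOG_COLUMNS))
    for g in catalog.genes:
        go = g.go_terms
        row = (
            g.gene_id,
            g.genome_id,
            g.replicon_id,
            str(g.start),
            str(g.end),
            g.strand,
            str(g.rank),
            str(g.protein_length),
            g.product.replace("\t", " ").replace("\n", " "),
            _join(go.get("molecular_function", ())),
            _join(go.get("biological_process", ())),
            _join(go.get("cellular_component", ())),
            _join(go.get(GO_UNSPECIFIED, ())),
            _join(g.ec_numbers),
            _join(g.xrefs),
        )
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_catalog(path) -> GenomeCatalog:
    """Read a gene table written by :func:`write_catalog`."""
    genome_id, replicon_ids, replicon_lengths = None, [], {}
    genes, header_seen = [], False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if line.startswith("#genome\t"):
            genome_id = line.split("\t")[1]
        elif line.startswith("#replicon\t"):
            _, rid, length = line.split("\t")
            replicon_ids.append(rid)
            replicon_lengths[rid] = int(length)
        elif line.startswith("#"):
            cols = tuple(line[1:].split("\t"))
            if cols != _CATALOG_COLUMNS:
                missing = set(_CATALOG_COLUMNS) - set(cols)
                extra = set(cols) - set(_CATALOG_COLUMNS)
                raise ValidationError(
                    f"{path}: gene-table schema mismatch "
                    f"(missing columns: {sorted(missing)}, unexpected: {sorted(extra)})"
                )
            header_seen = True
        elif line.strip():
            f = line.split("\t")
            if len(f) != len(_CATALOG_COLUMNS):
                raise ValidationError(
                    f"{path}:{lineno}: expected {len(_CATALOG_COLUMNS)} columns, got {len(f)}"
                )
            go = {}
            for ns, raw in zip(GO_NAMESPACES + (GO_UNSPECIFIED,), f[9:13]):
                if raw:
                    go[ns] = frozenset(raw.split(";"))
            genes.append(
                GeneRecord(
                    gene_id=f[0], genome_id=f[1], replicon_id=f[2],
                    start=int(f[3]), end=int(f[4]), strand=f[5], rank=int(f[6]),
                    protein_length=int(f[7]), product=f[8], go_terms=go,
                    ec_numbers=frozenset(f[13].split(";")) if f[13] else frozenset(),
                    xrefs=frozenset(f[14].split(";")) if f[14] else frozenset(),
                )
            )
    if genome_id is None or not header_seen:
        raise ValidationError(f"{path}: not a pairsynt gene table (missing headers)")
    return GenomeCatalog(genome_id, replicon_ids, replicon_lengths, genes)
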