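"""Gene × genome presence profiles, filter algebra, core/dispensable sets.

The orthologues-table abstraction: rows are compared organisms, columns are
reference genes, and each cell says whether the reference gene has a BDBH
ortholog there (``ortholog``), only weaker homologs (``homolog_only``), or
nothing stored at all (``absent``).  Gene filters — location, name,
annotation text, GO term, EC number, cross-reference, motif text,
presence/absence — combine freely under AND (intersection) and OR (union)
into a combinator tree evaluated against a profile, and core/dispensable
gene sets fall out of the presence predicate applied across a genome
subset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .genome_io import GenomeCatalog, ValidationError
from .homology import ORTHOLOG, HOMOLOG

ABSENT = "absent"
HOMOLOG_ONLY = "homolog_only"

_CELL_CODE = {ORTHOLOG: "O", HOMOLOG_ONLY: "H", ABSENT: "-"}


@dataclass
class PresenceProfile:
    """Presence/absence labels of every reference gene in every compared genome."""

    ref_genome_id: str
    gene_ids: list        # reference genes, rank order
    genome_ids: list      # compared genomes, input order
    labels: dict          # (gene_id, genome_id) -> ortholog | homolog_only | absent
    support: dict         # (gene_id, genome_id) -> list of relation ids

    def label(self, gene_id, genome_id) -> str:
        return self.labels.get((gene_id, genome_id), ABSENT)

    def supporting(self, gene_id, genome_id) -> list:
        return self.support.get((gene_id, genome_id), [])


def build_profile(ref: GenomeCatalog, relation_sets) -> PresenceProfile:
    """Build the profile of *ref* against several compared genomes.

    *relation_sets* is an ordered mapping (or list of pairs)
    ``genome_id -> relations`` where each relation list comes from
    :func:`pairsynt.homology.call_relations` with *ref* as genome A.
    A cell is ``ortholog`` iff a BDBH relation exists, ``homolog_only`` iff
    only non-BDBH relations exist; multiple overlapping homologies stack in
    the cell as supporting relations (offshoot browsing).
    """
    items = list(relation_sets.items()) if isinstance(relation_sets, dict) \
        else list(relation_sets)
    gene_ids = [g.gene_id for g in ref.genes]
    labels, support = {}, {}
    for genome_id, relations in items:
        for r in relations:
            if r.gene_a not in ref:
                raise ValidationError(
                    f"relation {r.relation_id} references gene {r.gene_a!r} "
                    f"absent from reference {ref.genome_id}"
                )
            key = (r.gene_a, genome_id)
            support.setdefault(key, []).append(r.relation_id)
            if r.kind == ORTHOLOG:
                labels[key] = ORTHOLOG
            elif labels.get(key) != ORTHOLOG:
                labels[key] = HOMOLOG_ONLY
    return PresenceProfile(
        ref_genome_id=ref.genome_id,
        gene_ids=gene_ids,
        genome_ids=[g for g, _ in items],
        labels=labels,
        support={k: sorted(v) for k, v in support.items()},
    )


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFilter:
    """One leaf filter.

    kinds and parameters:
      location       — replicon (optional), start/end bp window (optional)
      name_or_id     — case-insensitive substring of the gene id
      annotation_text— case-insensitive substring of the product
      go_term        — exact GO identifier (any namespace)
      ec_number      — exact EC string
      xref           — exact cross-reference
      domain_motif   — substring of product or xrefs (annotation text only;
                       no sequence scanning)
      presence       — genomes (all must satisfy), predicate
                       ortholog | any_homolog
      absence        — genomes (all must lack any stored homolog)
    """

    kind: str
    text: Optional[str] = None
    replicon: Optional[str] = None
    start: Optional[int] = None
    end: Optional[int] = None
    genomes: tuple = ()
    predicate: str = ORTHOLOG  # or "any_homolog"


@dataclass(frozen=True)
class FilterNode:
    """AND/OR combinator over filters and sub-trees."""

    op: str  # "AND" | "OR"
    children: tuple

    def __post_init__(self):
        if self.op not in ("AND", "OR"):
            raise ValidationError(f"unknown combinator {self.op!r}")


def _satisfies(label, predicate):
    if predicate == ORTHOLOG:
        return label == ORTHOLOG
    if predicate == "any_homolog":
        return label in (ORTHOLOG, HOMOLOG_ONLY)
    raise ValidationError(f"unknown presence predicate {predicate!r}")


def _eval_leaf(f: GeneFilter, profile: PresenceProfile, catalog: GenomeCatalog):
    universe = profile.gene_ids
    if f.kind in ("presence", "absence"):
        for gid in f.genomes:
            if gid not in profile.genome_ids:
                raise ValidationError(f"genome {gid!r} not in profile")
        if not f.genomes:
            raise ValidationError(f"{f.kind} filter needs at least one genome")
        if f.kind == "presence":
            return {g for g in universe
                    if all(_satisfies(profile.label(g, gid), f.predicate)
                           for gid in f.genomes)}
        return {g for g in universe
                if all(profile.label(g, gid) == ABSENT for gid in f.genomes)}

    out = set()
    for g in universe:
        rec = catalog.gene(g)
        if f.kind == "location":
            ok = (f.replicon is None or rec.replicon_id == f.replicon)
            if f.start is not None:
                ok = ok and rec.end >= f.start
            if f.end is not None:
                ok = ok and rec.start <= f.end
        elif f.kind == "name_or_id":
            ok = f.text.lower() in rec.gene_id.lower()
        elif f.kind == "annotation_text":
            ok = f.text.lower() in rec.product.lower()
        elif f.kind == "go_term":
            if not f.text.startswith("GO:"):
                raise ValidationError(f"not a GO identifier: {f.text!r}")
            ok = f.text in rec.all_go_terms()
        elif f.kind == "ec_number":
            if not f.text or not f.text[0].isdigit():
                raise ValidationError(f"not an EC number: {f.text!r}")
            ok = f.text in rec.ec_numbers
        elif f.kind == "xref":
            ok = f.text in rec.xrefs
        elif f.kind == "domain_motif":
            hay = rec.product.lower() + " " + " ".join(rec.xrefs).lower()
            ok = f.text.lower() in hay
        else:
            raise ValidationError(f"unknown filter kind {f.kind!r}")
        if ok:
            out.add(g)
    return out


def apply_filter(profile: PresenceProfile, catalog: GenomeCatalog, node) -> list:
    """Evaluate a filter tree; returns matching reference genes in rank order.

    An AND over zero children is the identity of intersection and returns
    every reference gene; an OR over zero children returns none.
    """
    result = _eval_node(node, profile, catalog)
    return [g for g in profile.gene_ids if g in result]


def _eval_node(node, profile, catalog):
    if isinstance(node, GeneFilter):
        return _eval_leaf(node, profile, catalog)
    if isinstance(node, FilterNode):
        sets = [_eval_node(c, profile, catalog) for c in node.children]
        if node.op == "AND":
            out = set(profile.gene_ids)
            for s in sets:
                out &= s
            return out
        out = set()
        for s in sets:
            out |= s
        return out
    raise ValidationError(f"not a filter: {node!r}")


def filter_from_json(obj) -> object:
    """Build a filter tree from its JSON form.

    ``{"op": "AND"|"OR", "filters": [...]}`` for combinators, otherwise a
    leaf object with ``kind`` plus that kind's parameters.
    """
    if isinstance(obj, str):
        obj = json.loads(obj)
    if "op" in obj:
        return FilterNode(obj["op"], tuple(filter_from_json(c)
                                           for c in obj.get("filters", [])))
    kind = obj.get("kind")
    if kind is None:
        raise ValidationError(f"filter object lacks 'kind': {obj!r}")
    return GeneFilter(
        kind=kind,
        text=obj.get("text"),
        replicon=obj.get("replicon"),
        start=obj.get("start"),
        end=obj.get("end"),
        genomes=tuple(obj.get("genomes", ())),
        predicate=obj.get("predicate", ORTHOLOG),
    )


# ---------------------------------------------------------------------------
# Core / dispensable
# ---------------------------------------------------------------------------

def core_dispensable(profile: PresenceProfile, genome_subset: Sequence,
                     predicate: str = ORTHOLOG):
    """Split the reference gene set into core and dispensable.

    Core genes satisfy *predicate* (``ortholog`` or ``any_homolog``) in
    every genome of *genome_subset*; the dispensable set is the complement.
    The two lists partition the reference genes, both in rank order.
    """
    if not genome_subset:
        raise ValidationError("genome_subset must be non-empty")
    for gid in genome_subset:
        if gid not in profile.genome_ids:
            raise ValidationError(f"genome {gid!r} not in profile")
    core, disp = [], []
    for g in profile.gene_ids:
        if all(_satisfies(profile.label(g, gid), predicate) for gid in genome_subset):
            core.append(g)
        else:
            disp.append(g)
    return core, disp


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def write_profile(profile: PresenceProfile, path, sep="\t") -> None:
    """Profile matrix: genes as columns, genomes as rows, cells O/H/-.

    ``sep=","`` gives the whole-table comma-separated export.
    """
    lines = [sep.join(["genome"] + profile.gene_ids)]
    for gid in profile.genome_ids:
        lines.append(sep.join(
            [gid] + [_CELL_CODE[profile.label(g, gid)] for g in profile.gene_ids]
        ))
    Path(path).write_text("\n".join(lines) + "\n")


def write_gene_list(gene_ids: Iterable, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_ids))
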