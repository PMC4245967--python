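"""Shared / Missing / Unique classification of functional annotations.

For a reference gene and the set of its admitted homologs (those passing the
active e-value / identity / query-coverage / orthologs-only filter), every
annotation of four classes — GO molecular function, GO biological process,
GO cellular component, EC number — is classified as:

* **shared**  — on the reference gene and on a homolog in ≥ 1 organism,
* **unique**  — on the reference gene but on no admitted homolog,
* **missing** — absent from the reference gene but on a homolog in ≥ 1
  organism.

Counts are per *organism* (any admitted homolog within an organism
suffices), and each annotation carries the ratio of its organism count to
the total number of organisms compared.  Free-text products are excluded by
default (too heterogeneous for exact matching) but can be opted in.
GO terms whose namespace the source did not state ("unspecified") are
ignored by the comparator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

from .genome_io import GeneRecord, ValidationError, GO_NAMESPACES
from .homology import ORTHOLOG, HomologyRelation

ANNOTATION_CLASSES = GO_NAMESPACES + ("ec_number",)


@dataclass(frozen=True)
class ComparatorFilter:
    """Thresholds a homolog must pass to be admitted.

    Unset thresholds admit everything; ``orthologs_only`` keeps BDBH pairs
    only; ``organisms`` restricts the compared-organism subset.
    """

    max_evalue: Optional[float] = None
    min_pct_identity: Optional[float] = None
    min_query_coverage_pct: Optional[float] = None
    orthologs_only: bool = False
    organisms: Optional[tuple] = None

    def admits(self, relation: HomologyRelation, ref_gene_id: str) -> bool:
        if self.orthologs_only and relation.kind != ORTHOLOG:
            return False
        if self.max_evalue is not None and relation.best_evalue() > self.max_evalue:
            return False
        if (self.min_pct_identity is not None
                and relation.best_identity() < self.min_pct_identity):
            return False
        if (self.min_query_coverage_pct is not None
                and relation.coverage_of(ref_gene_id) < self.min_query_coverage_pct):
            return False
        return True


@dataclass
class AnnotationComparison:
    """Classification result for one reference gene.

    ``shared``/``missing``/``unique`` map annotation class ->
    {annotation -> sorted list of organisms whose admitted homolog carries
    it} (empty list for unique).  ``n_organisms`` is the number of
    organisms compared, the denominator of the reported ratios.
    """

    ref_gene_id: str
    n_organisms: int
    shared: dict
    missing: dict
    unique: dict

    def ratio(self, category: str, cls: str, annotation: str) -> float:
        orgs = getattr(self, category)[cls][annotation]
        return len(orgs) / self.n_organisms if self.n_organisms else 0.0

    def to_json(self) -> str:
        payload = {"ref_gene_id": self.ref_gene_id,
                   "n_organisms": self.n_organisms}
        for cat in ("shared", "missing", "unique"):
            payload[cat] = {
                cls: {ann: {"organisms": orgs,
                            "ratio": self.ratio(cat, cls, ann)}
                      for ann, orgs in sorted(anns.items())}
                for cls, anns in getattr(self, cat).items()
            }
        return json.dumps(payload, indent=1)


def _class_annotations(gene: GeneRecord, include_product: bool) -> dict:
    out = {ns: set(gene.go_terms.get(ns, ())) for ns in GO_NAMESPACES}
    out["ec_number"] = set(gene.ec_numbers)
    if include_product and gene.product:
        out["product"] = {gene.product}
    return out


def compare_annotations(ref_gene_id: str, relations: Iterable[HomologyRelation],
                        catalogs: Mapping[str, object], ref_genome_id: str,
                        comp_filter: ComparatorFilter = None,
                        include_product: bool = False) -> AnnotationComparison:
    """Classify the annotations of *ref_gene_id* against its homologs.

    *relations* are all relations of the reference genome (the reference
    gene is ``gene_a``); *catalogs* maps genome id -> GenomeCatalog and
    must include the reference genome and every compared one.  Organisms
    with no admitted homolog contribute to no category.
    """
    comp_filter = comp_filter or ComparatorFilter()
    ref_cat = catalogs.get(ref_genome_id)
    if ref_cat is None or ref_gene_id not in ref_cat:
        raise ValidationError(f"unknown reference gene {ref_gene_id!r}")
    ref_gene = ref_cat.gene(ref_gene_id)

    organisms = [gid for gid in catalogs if gid != ref_genome_id]
    if comp_filter.organisms is not None:
        organisms = [g for g in organisms if g in comp_filter.organisms]

    classes = list(ANNOTATION_CLASSES) + (["product"] if include_product else [])
    ref_ann = _class_annotations(ref_gene, include_product)

    # organism -> class -> union of annotations over its admitted homologs
    hom_ann = {org: {cls: set() for cls in classes} for org in organisms}
    for rel in relations:
        if rel.gene_a != ref_gene_id:
            continue
        for org in organisms:
            if rel.gene_b in catalogs[org]:
                if comp_filter.admits(rel, ref_gene_id):
                    ann = _class_annotations(catalogs[org].gene(rel.gene_b),
                                             include_product)
                    for cls in classes:
                        hom_ann[org][cls] |= ann.get(cls, set())
                break

    shared = {cls: {} for cls in classes}
    missing = {cls: {} for cls in classes}
    unique = {cls: {} for cls in classes}
    for cls in classes:
        for ann in sorted(ref_ann.get(cls, ())):
            orgs = sorted(o for o in organisms if ann in hom_ann[o][cls])
            (shared if orgs else unique)[cls][ann] = orgs
        seen = set()
        for org in organisms:
            seen |= hom_ann[org][cls]
        for ann in sorted(seen - ref_ann.get(cls, set())):
            missing[cls][ann] = sorted(o for o in organisms
                                       if ann in hom_ann[o][cls])
    return AnnotationComparison(ref_gene_id, len(organisms), shared, missing, unique)


def diff_detail(ref_gene: GeneRecord, hom_gene: GeneRecord,
                relation: HomologyRelation, include_product: bool = False) -> dict:
    """Field-by-field similarity report of one reference/homolog pair.

    Per annotation class: ``common``, ``ref_only`` and ``homolog_only``
    sorted lists, plus the alignment summary of the relation.
    """
    ra = _class_annotations(ref_gene, include_product)
    ha = _class_annotations(hom_gene, include_product)
    report = {"classes": {}, "alignment": {}}
    for cls in list(ANNOTATION_CLASSES) + (["product"] if include_product else []):
        r, h = ra.get(cls, set()), ha.get(cls, set())
        report["classes"][cls] = {
            "common": sorted(r & h),
            "ref_only": sorted(r - h),
            "homolog_only": sorted(h - r),
        }
    ab, ba = relation.best_hit_a_to_b, relation.best_hit_b_to_a
    report["alignment"] = {
        "kind": relation.kind,
        "evalue": relation.best_evalue(),
        "pct_identity": relation.best_identity(),
        "query_coverage": relation.coverage_of(ref_gene.gene_id),
        "bitscore": max(h.bitscore for h in (ab, ba) if h),
    }
    return report


def comparison_to_tsv(cmp: AnnotationComparison, path) -> None:
    """Flat TSV export: category, class, annotation, count, ratio, organisms."""
    lines = ["#category\tclass\tannotation\tn_organisms\tratio\torganisms"]
    for cat in ("shared", "missing", "unique"):
        table = getattr(cmp, cat)
        for cls in table:
            for ann, orgs in sorted(table[cls].items()):
                lines.append("\t".join([
                    cat, cls, ann, str(len(orgs)),
                    f"{cmp.ratio(cat, cls, ann):.3f}", ";".join(orgs),
                ]))
    Path(path).write_text("\n".join(lines) + "\n")
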