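"""Synthetic genome pairs with planted evolutionary events and ground truth.

An ancestral gene order is generated, and each descendant genome derives
from it by applying configured events — inversions, translocations,
segmental duplications, gene gains (island insertions) and gene losses.
The generator emits GenBank files that parse under :mod:`pairsynt.genome_io`,
all-vs-all tabular hit files with the planted orthologs as mutual best
hits, and a machine-readable truth table (ortholog pairs, expected synteny
blocks with orientation and anchors, genome-specific gene sets, annotation
assignments).  Identical seeds reproduce byte-identical output.

Hit e-values and bit scores are synthesized rather than computed from
sequences: the pipeline consumes hit tables, so sequence realism buys
nothing.  Protein sequences are arbitrary valid amino-acid strings of the
declared lengths, and annotations are drawn from small fixed pools so the
emitted files stay tiny and readable.

Detectability regime
--------------------
Expected blocks are only well defined when planted events cannot interact
under the scoring scheme.  The generator keeps events apart (≥ 4 untouched
genes) and sizes inversions at ≥ a third of the genome so that bridging an
inverted segment of k genes (k mismatch columns, −4k) never beats keeping
the flanking blocks separate.  Within that regime the expected blocks are
computed by an independent chainer over the planted gene correspondence:
maximal strictly collinear runs (small in-run gaps ≤ 2 allowed), followed
by bridge-cost merging of adjacent same-direction runs exactly when the
bridge is cheaper than the weaker flank.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import dataclass, field
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio import SeqIO

from .genome_io import ValidationError, load_genome
from .homology import ORTHOLOG, HOMOLOG
from .synteny import SyntenyScoringParams, FORWARD, REVERSED

_AA = "ACDEFGHIKLMNPQRSTVWY"

_PRODUCTS = (
    "DNA polymerase III subunit alpha", "ABC transporter permease",
    "50S ribosomal protein L2", "two-component sensor histidine kinase",
    "phosphotransferase system EIIB component", "cell wall hydrolase",
    "MFS family transporter", "transcriptional regulator, LacI family",
    "glucuronyl hydrolase", "aminotransferase class I",
    "tRNA modification GTPase", "peptide chain release factor",
)
_GO_MF = ("GO:0003677", "GO:0005524", "GO:0016301", "GO:0016787",
          "GO:0022857", "GO:0003735")
_GO_BP = ("GO:0006260", "GO:0006412", "GO:0055085", "GO:0008643",
          "GO:0006508", "GO:0016310")
_GO_CC = ("GO:0005737", "GO:0005886", "GO:0005840", "GO:0009279")
_EC = ("2.7.7.7", "2.7.13.3", "3.2.1.-", "3.5.1.104", "2.6.1.1", "3.6.5.-")


@dataclass(frozen=True)
class SimulationConfig:
    """Event counts and rates of one simulation; the seed fixes everything.

    Defaults give a 2-genome, 60-gene comparison with one 20-gene
    inversion, one 5-gene island gain, one 3-gene segmental duplication and
    two single-gene losses — one well-separated instance of each default
    event type, inside the detectability regime.  True-ortholog hit
    e-values (1e-50..1e-20) sit strictly below paralog/secondary hits
    (1e-8..1e-3), so planted orthologs are mutual best hits by
    construction; decoy hits land at or above the storage threshold and
    must be filtered out on parsing.
    """

    seed: int = 0
    n_genomes: int = 2
    genes_per_genome: int = 60
    replicons_per_genome: int = 1
    n_inversions: int = 1
    inversion_size: int = 20
    n_translocations: int = 0
    translocation_size: int = 4
    n_duplications: int = 1
    duplication_size: int = 3
    n_gains: int = 1
    gain_size: int = 5
    n_losses: int = 2
    loss_size: int = 1
    ortholog_evalue_range: tuple = (1e-50, 1e-20)
    paralog_evalue_range: tuple = (1e-8, 1e-3)
    n_decoy_hits: int = 3
    annotation_share: float = 0.85
    event_separation: int = 4

    def __post_init__(self):
        counts = (self.n_genomes, self.genes_per_genome, self.n_inversions,
                  self.n_translocations, self.n_duplications, self.n_gains,
                  self.n_losses)
        if min(counts) < 0 or self.n_genomes < 1 or self.genes_per_genome < 1:
            raise ValidationError("all counts must be >= 0 (and sizes >= 1)")
        if self.n_losses * self.loss_size >= self.genes_per_genome:
            raise ValidationError("more losses than genes")
        for lo, hi in (self.ortholog_evalue_range, self.paralog_evalue_range):
            if not (0 < lo <= hi < 0.01):
                raise ValidationError("planted hit e-value ranges must lie in (0, 0.01)")


@dataclass
class SimulationResult:
    outdir: Path
    genome_paths: dict      # genome_id -> GenBank path
    hit_paths: dict         # (query_genome, subject_genome) -> path
    truth: dict
    catalogs: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Ancestor and descendants
# ---------------------------------------------------------------------------

def _make_ancestor(rng, n):
    genes = []
    for i in range(n):
        ann = {
            "molecular_function": {rng.choice(_GO_MF)},
            "biological_process": set(rng.sample(_GO_BP, rng.randint(0, 2))),
            "cellular_component": set(rng.sample(_GO_CC, rng.randint(0, 1))),
            "ec": {rng.choice(_EC)} if rng.random() < 0.3 else set(),
        }
        genes.append({
            "aid": i,
            "plen": rng.randint(80, 300),
            "product": rng.choice(_PRODUCTS),
            "ann": ann,
            "xref": f"UniProtKB:P{10000 + i}",
        })
    return genes


def _pick_windows(rng, n, sizes, sep):
    """Disjoint windows with >= sep untouched genes between any two and
    clear of the genome ends.  Windows are laid out in random order with
    the residual slack split randomly between them; returns the start of
    each requested window in input order."""
    k = len(sizes)
    if k == 0:
        return []
    widths = [max(s, 1) for s in sizes]
    slack = n - 2 * sep - sum(widths) - sep * (k - 1)
    if slack < 0:
        raise ValidationError("cannot place events: configuration too crowded")
    order = list(range(k))
    rng.shuffle(order)
    cuts = sorted(rng.randint(0, slack) for _ in range(k))
    extra = [cuts[0]] + [b - a for a, b in zip(cuts, cuts[1:])]
    starts, pos = {}, sep
    for idx, ex in zip(order, extra):
        pos += ex
        starts[idx] = pos
        pos += widths[idx] + sep
    return [starts[i] for i in range(k)]


def _derive(rng, cfg, n):
    """Event plan + derived gene-item list for one descendant.

    Items are ("anc", i), ("dup", i) or ("gain", tag).  Returns
    (items, plan) where plan records the planted windows in ancestor
    coordinates.
    """
    sizes = ([cfg.inversion_size] * cfg.n_inversions
             + [cfg.translocation_size] * cfg.n_translocations
             + [cfg.duplication_size] * cfg.n_duplications
             + [0] * cfg.n_duplications          # duplication insertion points
             + [0] * cfg.n_translocations        # translocation insertion points
             + [0] * cfg.n_gains                 # gain insertion points
             + [cfg.loss_size] * cfg.n_losses)
    starts = _pick_windows(rng, n, sizes, cfg.event_separation)

    p = 0
    inversions = [(starts[p + k], cfg.inversion_size) for k in range(cfg.n_inversions)]
    p += cfg.n_inversions
    transloc_src = [(starts[p + k], cfg.translocation_size)
                    for k in range(cfg.n_translocations)]
    p += cfg.n_translocations
    dup_src = [(starts[p + k], cfg.duplication_size) for k in range(cfg.n_duplications)]
    p += cfg.n_duplications
    dup_ins = starts[p:p + cfg.n_duplications]
    p += cfg.n_duplications
    tr_ins = starts[p:p + cfg.n_translocations]
    p += cfg.n_translocations
    gain_ins = starts[p:p + cfg.n_gains]
    p += cfg.n_gains
    losses = [(starts[p + k], cfg.loss_size) for k in range(cfg.n_losses)]

    lost = {i for s, w in losses for i in range(s, s + w)}
    tr_moved = {i for s, w in transloc_src for i in range(s, s + w)}
    inv_at = {s: w for s, w in inversions}
    dup_at = {}
    for (s, w), at in zip(dup_src, dup_ins):
        dup_at.setdefault(at, []).extend(range(s, s + w))
    tr_at = {}
    for (s, w), at in zip(transloc_src, tr_ins):
        tr_at.setdefault(at, []).extend(range(s, s + w))

    items, gain_tag = [], 0
    pos = 0
    while pos < n:
        for src in dup_at.get(pos, ()):
            items.append(("dup", src))
        for src in tr_at.get(pos, ()):
            items.append(("anc", src))
        if pos in {g for g in gain_ins}:
            for _ in range(cfg.gain_size):
                items.append(("gain", gain_tag))
                gain_tag += 1
        if pos in inv_at:
            w = inv_at[pos]
            for q in range(pos + w - 1, pos - 1, -1):
                if q not in lost and q not in tr_moved:
                    items.append(("anc", q))
            pos += w
            continue
        if pos not in lost and pos not in tr_moved:
            items.append(("anc", pos))
        pos += 1

    plan = {
        "inversions": inversions, "translocations": list(zip(transloc_src, tr_ins)),
        "duplications": list(zip(dup_src, dup_ins)), "gains": gain_ins,
        "losses": losses, "lost": sorted(lost),
    }
    return items, plan


# ---------------------------------------------------------------------------
# Expected blocks: the detectability-regime chainer
# ---------------------------------------------------------------------------

def _bridge_cost(a, b, params):
    """Cheapest cost of crossing a unmatched reference genes and b unmatched
    compared genes between two anchors (mismatch pairs plus one gap run per
    genome; splitting gap runs is never cheaper)."""
    best = None
    for m in range(min(a, b) + 1):
        c = params.mismatch_score * m + params.gap_cost(a - m) + params.gap_cost(b - m)
        best = c if best is None else max(best, c)
    return best if best is not None else 0


def expected_blocks(ref_order, cmp_order, ortholog_pairs,
                    params: SyntenyScoringParams = None):
    """Expected primary blocks from a planted gene correspondence.

    *ref_order*/*cmp_order* are gene-id lists in rank order;
    *ortholog_pairs* maps ref gene id -> cmp gene id.  Returns a list of
    ``{"orientation", "anchors"}`` dicts in reference order.  Valid only
    inside the generator's detectability regime (see module docstring).
    """
    params = params or SyntenyScoringParams()
    cmp_rank = {g: r for r, g in enumerate(cmp_order)}
    matched = [(r, g, cmp_rank[ortholog_pairs[g]])
               for r, g in enumerate(ref_order) if g in ortholog_pairs]

    runs = []
    for r, g, c in matched:
        if runs:
            pr, pg, pc = runs[-1]["trip"][-1]
            a, step = r - pr - 1, c - pc
            d = runs[-1]["dir"]
            fits = (
                a <= 2
                and ((d in (0, 1) and 0 < step <= 3 and step - 1 <= 2)
                     or (d in (0, -1) and 0 > step >= -3 and -step - 1 <= 2))
            )
            if fits:
                runs[-1]["trip"].append((r, g, c))
                if runs[-1]["dir"] == 0 and abs(step) >= 1:
                    runs[-1]["dir"] = 1 if step > 0 else -1
                continue
        runs.append({"trip": [(r, g, c)], "dir": 0})

    def score(run):
        s = params.ortholog_score * len(run["trip"])
        t = run["trip"]
        for (r1, _, c1), (r2, _, c2) in zip(t, t[1:]):
            s += _bridge_cost(r2 - r1 - 1, abs(c2 - c1) - 1, params)
        return s

    # merge adjacent same-direction runs when the bridge beats the weaker
    # flank and no other run's anchors lie between them on either genome
    changed = True
    while changed:
        changed = False
        for k in range(len(runs) - 1):
            r1, r2 = runs[k], runs[k + 1]
            d1, d2 = r1["dir"], r2["dir"]
            if not (d1 == d2 or d1 == 0 or d2 == 0):
                continue
            d = d1 or d2 or 1
            lr, fr = r1["trip"][-1], r2["trip"][0]
            a = fr[0] - lr[0] - 1
            step = fr[2] - lr[2]
            if d == 1 and step <= 0 or d == -1 and step >= 0:
                continue
            b = abs(step) - 1
            lo, hi = min(lr[2], fr[2]), max(lr[2], fr[2])
            between = any(lo < c < hi for rr in runs if rr not in (r1, r2)
                          for (_, _, c) in rr["trip"])
            if between or a < 0:
                continue
            if _bridge_cost(a, b, params) > -min(score(r1), score(r2)):
                merged = {"trip": r1["trip"] + r2["trip"], "dir": d}
                runs[k:k + 2] = [merged]
                changed = True
                break

    out = []
    for run in runs:
        if score(run) < params.min_score or len(run["trip"]) < params.min_anchor_count:
            continue
        out.append({
            "orientation": REVERSED if run["dir"] == -1 else FORWARD,
            "anchors": [[g, ortholog_pairs[g], ORTHOLOG] for _, g, _ in run["trip"]],
        })
    return out


# ---------------------------------------------------------------------------
# Emission
# ---------------------------------------------------------------------------

def _annotate_descendant(rng, anc_gene, share):
    ann = {}
    for cls, pool in (("molecular_function", _GO_MF), ("biological_process", _GO_BP),
                      ("cellular_component", _GO_CC), ("ec", _EC)):
        kept = {t for t in anc_gene["ann"][cls] if rng.random() < share}
        if rng.random() < 0.15:
            kept.add(rng.choice(pool))
        ann[cls] = kept
    return ann


def _genbank_record(rng, genome_id, replicon_id, genes):
    """genes: list of dicts with gene_id, plen, product, ann, xref, strand."""
    pos, feats = 100, []
    for g in genes:
        span = 3 * (g["plen"] + 1)
        start, end = pos, pos + span - 1
        g["start"], g["end"] = start, end
        quals = {
            "locus_tag": [g["gene_id"]],
            "product": [g["product"]],
            "translation": ["".join(rng.choice(_AA) for _ in range(g["plen"]))],
            "codon_start": ["1"],
            "transl_table": ["11"],
            "db_xref": [g["xref"]],
        }
        for key, cls in (("GO_function", "molecular_function"),
                         ("GO_process", "biological_process"),
                         ("GO_component", "cellular_component")):
            if g["ann"][cls]:
                quals[key] = sorted(g["ann"][cls])
        if g["ann"]["ec"]:
            quals["EC_number"] = sorted(g["ann"]["ec"])
        feats.append(SeqFeature(
            SimpleLocation(start - 1, end, strand=1 if g["strand"] == "+" else -1),
            type="CDS", qualifiers=quals,
        ))
        pos = end + 1 + rng.randint(40, 120)
    total = pos + 100
    seq = Seq("".join(rng.choice("ACGT") for _ in range(total)))
    rec = SeqRecord(seq, id=replicon_id, name=replicon_id[:16],
                    description=f"{genome_id} {replicon_id}, synthetic")
    rec.annotations.update({
        "molecule_type": "DNA", "topology": "linear",
        "data_file_division": "BCT", "date": "01-JAN-1980",
        "accessions": [replicon_id], "organism": f"Synthetica {genome_id}",
        "source": f"Synthetica {genome_id} (synthetic genome)",
    })
    rec.features = feats
    return rec


def _fmt_hit(q, s, rng, ev_range):
    lo, hi = ev_range
    ev = 10 ** rng.uniform(math.log10(lo), math.log10(hi))
    ident = round(rng.uniform(55.0, 99.0), 1)
    alen = min(q["plen"], s["plen"])
    bits = round(1.8 * alen + rng.uniform(0, 25), 1)
    return "\t".join(map(str, (
        q["gene_id"], s["gene_id"], ident, alen, int(alen * (100 - ident) / 100), 0,
        1, q["plen"], 1, s["plen"], f"{ev:.2e}", bits,
    )))


def simulate(config: SimulationConfig, outdir) -> SimulationResult:
    """Run one simulation and write genomes, hit tables and truth.json."""
    rng = random.Random(config.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    n = config.genes_per_genome
    ancestor = _make_ancestor(rng, n)

    genome_ids = [f"G{k}" for k in range(config.n_genomes)]
    per_genome = {}   # gid -> list of gene dicts in final order
    plans = {}
    for k, gid in enumerate(genome_ids):
        if k == 0:
            items, plan = [("anc", i) for i in range(n)], {
                "inversions": [], "translocations": [], "duplications": [],
                "gains": [], "losses": [], "lost": []}
        else:
            items, plan = _derive(rng, config, n)
        plans[gid] = plan
        genes = []
        for pos, (kind, ref) in enumerate(items):
            gene_id = f"{gid}_{pos:04d}"
            if kind == "gain":
                genes.append({
                    "gene_id": gene_id, "origin": None, "dup_of": None,
                    "plen": rng.randint(80, 300),
                    "product": rng.choice(_PRODUCTS),
                    "ann": {"molecular_function": {rng.choice(_GO_MF)},
                            "biological_process": set(rng.sample(_GO_BP, 1)),
                            "cellular_component": set(), "ec": set()},
                    "xref": f"UniProtKB:Q{50000 + config.seed % 1000}{pos:03d}",
                    "strand": rng.choice("++-"),
                })
                continue
            anc = ancestor[ref]
            genes.append({
                "gene_id": gene_id,
                "origin": ref if kind == "anc" else None,
                "dup_of": ref if kind == "dup" else None,
                "plen": anc["plen"],
                "product": anc["product"],
                "ann": anc["ann"] if k == 0 else
                       _annotate_descendant(rng, anc, config.annotation_share),
                "xref": anc["xref"] if kind == "anc" else f"UniProtKB:D{10000 + ref}",
                "strand": rng.choice("++-"),
            })
        per_genome[gid] = genes

    # genome files (replicon split: last fifth of the genes go to a plasmid)
    genome_paths = {}
    for gid in genome_ids:
        genes = per_genome[gid]
        if config.replicons_per_genome >= 2 and len(genes) >= 10:
            cut = len(genes) - len(genes) // 5
            parts = [(f"{gid}_chr", genes[:cut]), (f"{gid}_pls", genes[cut:])]
        else:
            parts = [(f"{gid}_chr", genes)]
        records = [_genbank_record(rng, gid, rid, gs) for rid, gs in parts]
        path = outdir / f"{gid}.gbk"
        with path.open("w") as fh:
            SeqIO.write(records, fh, "genbank")
        genome_paths[gid] = path

    # hit tables, one per ordered genome pair
    by_origin = {gid: {} for gid in genome_ids}
    for gid in genome_ids:
        for g in per_genome[gid]:
            if g["origin"] is not None:
                by_origin[gid][g["origin"]] = g
    hit_paths = {}
    for qa in genome_ids:
        for sa in genome_ids:
            if qa == sa:
                continue
            lines = []
            for g in per_genome[qa]:
                tgt = None
                if g["origin"] is not None:
                    tgt = by_origin[sa].get(g["origin"])
                    if tgt is not None:
                        lines.append(_fmt_hit(g, tgt, rng, config.ortholog_evalue_range))
                    # secondary hits against duplicate copies in the subject
                    for s in per_genome[sa]:
                        if s["dup_of"] == g["origin"]:
                            lines.append(_fmt_hit(g, s, rng, config.paralog_evalue_range))
                if g["dup_of"] is not None:
                    tgt = by_origin[sa].get(g["dup_of"])
                    if tgt is not None:
                        lines.append(_fmt_hit(g, tgt, rng, config.paralog_evalue_range))
            for _ in range(config.n_decoy_hits):
                q = rng.choice(per_genome[qa])
                s = rng.choice(per_genome[sa])
                lines.append(_fmt_hit(q, s, rng, (0.02, 5.0)))
            path = outdir / f"hits_{qa}_vs_{sa}.tsv"
            path.write_text("\n".join(lines) + "\n")
            hit_paths[(qa, sa)] = path

    # truth table
    ref = genome_ids[0]
    truth = {"genomes": genome_ids, "reference": ref, "seed": config.seed,
             "ortholog_pairs": {}, "blocks": {}, "specific": {},
             "annotations": {}, "plans": {
                 gid: {k: v for k, v in plans[gid].items()} for gid in genome_ids}}
    ref_order = [g["gene_id"] for g in per_genome[ref]]
    for gid in genome_ids:
        truth["annotations"][gid] = {
            g["gene_id"]: {
                "go": {cls: sorted(g["ann"][cls]) for cls in
                       ("molecular_function", "biological_process", "cellular_component")},
                "ec": sorted(g["ann"]["ec"]),
                "product": g["product"],
            } for g in per_genome[gid]
        }
        if gid == ref:
            continue
        pairs = {}
        for g in per_genome[ref]:
            if g["origin"] is not None and g["origin"] in by_origin[gid]:
                pairs[g["gene_id"]] = by_origin[gid][g["origin"]]["gene_id"]
        truth["ortholog_pairs"][gid] = sorted(pairs.items())
        cmp_order = [g["gene_id"] for g in per_genome[gid]]
        blocks = expected_blocks(ref_order, cmp_order, pairs)
        # one expected offshoot per planted duplication: copies are emitted
        # contiguously, so group them by adjacency in the compared genome
        run, prev_rank = [], None
        for rank, g in enumerate(per_genome[gid]):
            if g["dup_of"] is not None and g["dup_of"] in by_origin[ref]:
                anchor = [by_origin[ref][g["dup_of"]]["gene_id"], g["gene_id"], HOMOLOG]
                if prev_rank is not None and rank != prev_rank + 1:
                    blocks.append({"orientation": FORWARD, "anchors": run,
                                   "is_offshoot": True})
                    run = []
                run.append(anchor)
                prev_rank = rank
        if run:
            blocks.append({"orientation": FORWARD, "anchors": run,
                           "is_offshoot": True})
        for b in blocks:
            b.setdefault("is_offshoot", False)
        truth["blocks"][gid] = blocks
        truth["specific"][gid] = {
            "gained": [g["gene_id"] for g in per_genome[gid] if g["origin"] is None
                       and g["dup_of"] is None],
            "duplicated_copies": [g["gene_id"] for g in per_genome[gid]
                                  if g["dup_of"] is not None],
            "ref_lost": [g["gene_id"] for g in per_genome[ref]
                         if g["gene_id"] not in pairs],
        }

    (outdir / "truth.json").write_text(json.dumps(truth, indent=1) + "\n")
    catalogs = {gid: load_genome(genome_paths[gid], "genbank", genome_id=gid)
                for gid in genome_ids}
    return SimulationResult(outdir, genome_paths, hit_paths, truth, catalogs)


def worked_toy(outdir) -> SimulationResult:
    """The documentation toy: 2 genomes, 40 genes, one 14-gene inversion,
    one 5-gene island, one 3-gene duplication, one loss.  Deterministic."""
    cfg = SimulationConfig(
        seed=92201, n_genomes=2, genes_per_genome=40,
        n_inversions=1, inversion_size=14,
        n_gains=1, gain_size=5,
        n_duplications=1, duplication_size=3,
        n_losses=1, loss_size=1,
        event_separation=3,
    )
    return simulate(cfg, outdir)


# ---------------------------------------------------------------------------
# Planted-block instances (in-memory, exact recovery fixtures)
# ---------------------------------------------------------------------------

def planted_block_instance(seed: int, n_blocks: int = 4,
                           include_reversed: bool = True,
                           include_duplication: bool = True,
                           include_gaps: bool = True):
    """Genome pair built block-by-block with exact expected anchors.

    The pair is a concatenation of planted synteny blocks separated by
    unrelated filler genes.  Separator lengths are sized to
    (min adjacent anchor count) + 1 so that, under default scoring, the
    dynamic programme provably cannot merge adjacent blocks; internal gaps
    (≤ 2 skipped genes) only occur with ≥ 3 ortholog anchors on each side
    so they are provably bridged.  Returns
    ``(ref_catalog, cmp_catalog, relations, expected)`` where *expected*
    is a list of ``{"orientation", "anchors", "is_offshoot"}``.
    """
    from .genome_io import GeneRecord, GenomeCatalog
    from .homology import HomologyHit, HomologyRelation

    rng = random.Random(seed)
    specs = []
    for b in range(n_blocks):
        reversed_ = include_reversed and b == 1 and n_blocks >= 2
        gapped = include_gaps and b == (2 if n_blocks > 2 else 0) and not reversed_
        n_anchors = rng.randint(6, 7) if gapped else rng.randint(2, 5)
        gap = 0 if not gapped else rng.randint(1, 2)
        gap_side = rng.choice(("ref", "cmp")) if gapped else None
        specs.append({"n": n_anchors, "reversed": reversed_, "gap": gap,
                      "gap_side": gap_side})

    ref_items, cmp_items = [], []   # ("anchor", block, idx) | ("filler",) | ("dup", block, idx)
    relations_plan = []             # (ref_pos_key, cmp_pos_key, kind)

    def sep_len(left_spec, right_spec):
        s = min(4 * left_spec["n"], 4 * right_spec["n"])
        return s // 4 + 1

    for b, spec in enumerate(specs):
        if b > 0:
            g = max(3, sep_len(specs[b - 1], spec))
            ref_items.extend([("filler",)] * g)
            cmp_items.extend([("filler",)] * g)
        ref_local, cmp_local = [], []
        for a in range(spec["n"]):
            ref_local.append(("anchor", b, a))
            cmp_local.append(("anchor", b, a))
            if spec["gap"] and a == spec["n"] // 2 - 1:
                side = ref_local if spec["gap_side"] == "ref" else cmp_local
                side.extend([("filler",)] * spec["gap"])
        if spec["reversed"]:
            cmp_local = cmp_local[::-1]
        ref_items.extend(ref_local)
        cmp_items.extend(cmp_local)

    dup_block = None
    if include_duplication:
        dup_block = next((b for b, s in enumerate(specs)
                          if not s["reversed"] and not s["gap"] and s["n"] >= 3), None)
    if dup_block is not None:
        g = max(3, specs[dup_block]["n"] // 2 + 1)
        cmp_items.extend([("filler",)] * g)
        for a in range(specs[dup_block]["n"]):
            cmp_items.append(("dup", dup_block, a))

    def build_catalog(genome_id, items):
        genes, pos = [], 100
        for rank, it in enumerate(items):
            gid = f"{genome_id}_{rank:04d}"
            genes.append(GeneRecord(
                gene_id=gid, genome_id=genome_id, replicon_id=f"{genome_id}_chr",
                start=pos, end=pos + 899, strand="+", rank=rank,
                protein_length=250, product="planted", go_terms={},
            ))
            pos += 1000
        total = pos + 100
        return GenomeCatalog(genome_id, [f"{genome_id}_chr"],
                             {f"{genome_id}_chr": total}, genes)

    ref_cat = build_catalog("R", ref_items)
    cmp_cat = build_catalog("C", cmp_items)

    anchor_ref = {}   # (block, idx) -> gene id
    for rank, it in enumerate(ref_items):
        if it[0] == "anchor":
            anchor_ref[(it[1], it[2])] = ref_cat.genes[rank].gene_id
    anchor_cmp, dup_cmp = {}, {}
    for rank, it in enumerate(cmp_items):
        if it[0] == "anchor":
            anchor_cmp[(it[1], it[2])] = cmp_cat.genes[rank].gene_id
        elif it[0] == "dup":
            dup_cmp[(it[1], it[2])] = cmp_cat.genes[rank].gene_id

    def rel(a, b, kind, ev):
        hit_ab = HomologyHit(a, b, 90.0, 250, ev, 450.0, 100.0)
        hit_ba = HomologyHit(b, a, 90.0, 250, ev, 450.0, 100.0)
        return HomologyRelation(a, b, kind, hit_ab, hit_ba)

    relations, expected = [], []
    for b, spec in enumerate(specs):
        anchors = []
        for a in range(spec["n"]):
            r, c = anchor_ref[(b, a)], anchor_cmp[(b, a)]
            relations.append(rel(r, c, ORTHOLOG, 1e-40))
            anchors.append((r, c, ORTHOLOG))
        expected.append({
            "orientation": REVERSED if spec["reversed"] else FORWARD,
            "anchors": anchors, "is_offshoot": False,
        })
    if dup_block is not None:
        anchors = []
        for a in range(specs[dup_block]["n"]):
            r, c = anchor_ref[(dup_block, a)], dup_cmp[(dup_block, a)]
            relations.append(rel(r, c, HOMOLOG, 1e-5))
            anchors.append((r, c, HOMOLOG))
        expected.append({"orientation": FORWARD, "anchors": anchors,
                         "is_offshoot": True})
    return ref_cat, cmp_cat, relations, expected
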