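"""Collinear synteny blocks by dynamic programming, and event segmentation.

A pairwise comparison aligns the *gene orders* of a reference and a compared
genome, replicon pair by replicon pair.  Aligning a gene pair scores
+4 when the pair is a BDBH ortholog, +2 for a plain homolog, and −4 when the
two genes have no stored relation (a mismatch column).  Skipping a run of
k genes on one genome costs gap_open + (k−1)·gap_extend (the opening charge
covers the first skipped gene).  Chains are local, must start and end on a
homologous pair, and are kept when score ≥ 2 with at least 1 anchor.

Each replicon pair is aligned twice — once against the compared gene order
as-is (forward) and once against it reversed — so inversions surface as
*reversed* blocks (the "bowtie" of the genomic organization display).
Successive sub-optimal chains are extracted Waterman–Eggert style: cells
paired by an accepted chain are masked and the DP is re-run until nothing
of score ≥ min_score remains.

After both orientations are collected, blocks are reconciled: the
highest-scoring block over a stretch of either genome is *primary*; a block
re-using reference or compared genes already claimed by a primary is
demoted to an *offshoot* (paralogy / segmental duplication); a chain whose
anchor pairs are all contained in an already kept block is a duplicate and
dropped.  Primaries partition the reference into the alternating chain of
annotation events: synteny blocks and genome-specific regions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from .genome_io import GenomeCatalog, ValidationError
from .homology import ORTHOLOG, HOMOLOG, relation_map, HomologyRelation

logger = logging.getLogger("pairsynt")

MISMATCH = "mismatch"
FORWARD = "forward"
REVERSED = "reversed"

NEG = float("-inf")


@dataclass(frozen=True)
class SyntenyScoringParams:
    """Scores and thresholds of the gene-order alignment.

    Defaults: ortholog +4, homolog +2, mismatch −4, gap creation −8,
    gap extension −2, minimum alignment size 1 anchor, minimum score 2.
    ``gap_mode`` selects how the creation charge combines with extension:
    ``open_includes_first`` (default) prices a k-gene gap at
    gap_open + (k−1)·gap_extend; ``open_plus_per_gene`` at
    gap_open + k·gap_extend.
    """

    ortholog_score: int = 4
    homolog_score: int = 2
    mismatch_score: int = -4
    gap_open: int = -8
    gap_extend: int = -2
    min_anchor_count: int = 1
    min_score: int = 2
    gap_mode: str = "open_includes_first"

    def __post_init__(self):
        if not (self.ortholog_score >= self.homolog_score > 0):
            raise ValidationError("require ortholog_score >= homolog_score > 0")
        if max(self.mismatch_score, self.gap_open, self.gap_extend) >= 0:
            raise ValidationError("mismatch and gap costs must be negative")
        if self.min_anchor_count < 1:
            raise ValidationError("min_anchor_count must be >= 1")
        if self.gap_mode not in ("open_includes_first", "open_plus_per_gene"):
            raise ValidationError(f"unknown gap_mode {self.gap_mode!r}")

    def gap_cost(self, k: int) -> int:
        """Cost of a maximal run of k >= 1 skipped genes on one genome."""
        if k < 1:
            return 0
        if self.gap_mode == "open_includes_first":
            return self.gap_open + (k - 1) * self.gap_extend
        return self.gap_open + k * self.gap_extend

    @property
    def _open(self) -> int:
        # charge applied when the first gene of a gap run is skipped
        if self.gap_mode == "open_includes_first":
            return self.gap_open
        return self.gap_open + self.gap_extend


@dataclass(frozen=True)
class SyntenyBlock:
    """One scored collinear chain of homologous gene pairs.

    ``anchors`` is ordered by reference rank; compared ranks increase for
    forward blocks and decrease for reversed ones.  The rank ranges cover
    the full interval between the first and last anchor on each genome,
    including genes the chain skipped — these intervals define block
    ownership for overlap resolution and event segmentation.
    """

    ref_genome_id: str
    cmp_genome_id: str
    orientation: str
    anchors: tuple  # of (ref_gene_id, cmp_gene_id, kind)
    score: int
    ref_replicon: str
    ref_start: int
    ref_end: int
    cmp_replicon: str
    cmp_start: int
    cmp_end: int
    ref_rank_lo: int
    ref_rank_hi: int
    cmp_rank_lo: int
    cmp_rank_hi: int
    is_offshoot: bool = False

    @property
    def anchor_pairs(self) -> frozenset:
        return frozenset((a, b) for a, b, _ in self.anchors)

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass
class AnnotationEvent:
    """One element of the per-comparison event chain.

    ``synteny`` and ``ref_specific`` events live on the reference genome and
    are ordered by reference start; a ``cmp_specific`` event lives on the
    compared genome and records the ordinal of the event it attaches to.
    """

    kind: str  # synteny | ref_specific | cmp_specific
    ordinal: int
    replicon_id: str
    start: int
    end: int
    gene_ids: tuple
    block: Optional[SyntenyBlock] = None
    attached_ordinal: Optional[int] = None


# ---------------------------------------------------------------------------
# Chain scoring (explicit chains)
# ---------------------------------------------------------------------------

_ANCHOR_TOKENS = (ORTHOLOG, HOMOLOG)
_GAP_TOKENS = ("gap_ref", "gap_cmp")


def chain_score(chain: Iterable, params: SyntenyScoringParams = None) -> int:
    """Score an explicitly described collinear chain.

    *chain* is a sequence of column tokens, in order: the strings
    ``"ortholog"``, ``"homolog"``, ``"mismatch"``, or tuples
    ``("gap_ref", k)`` / ``("gap_cmp", k)`` for a maximal run of k skipped
    genes on the reference / compared genome.  The chain must be terminally
    anchored (first and last tokens are anchors).
    """
    params = params or SyntenyScoringParams()
    tokens = list(chain)
    if not tokens:
        raise ValidationError("empty chain")
    for t in (tokens[0], tokens[-1]):
        if t not in _ANCHOR_TOKENS:
            raise ValidationError(f"chain must start and end on an anchor, got {t!r}")
    score = 0
    for t in tokens:
        if t == ORTHOLOG:
            score += params.ortholog_score
        elif t == HOMOLOG:
            score += params.homolog_score
        elif t == MISMATCH:
            score += params.mismatch_score
        elif isinstance(t, tuple) and len(t) == 2 and t[0] in _GAP_TOKENS:
            k = t[1]
            if not isinstance(k, int) or k < 1:
                raise ValidationError(f"gap run length must be an integer >= 1: {t!r}")
            score += params.gap_cost(k)
        else:
            raise ValidationError(f"unknown chain token {t!r}")
    return score


# ---------------------------------------------------------------------------
# Gene-string local alignment (Gotoh with affine gaps + masking)
# ---------------------------------------------------------------------------

def _gotoh_best(R, C, relmap, params, masked):
    """Best local chain between gene-id lists R and C.

    Returns ``(score, columns)`` where columns is the ordered list of
    ``(i, j, kind)`` diagonal columns (0-based indices into R and C,
    kind in {ortholog, homolog, mismatch}), or ``None`` when no chain with
    positive score exists.  ``masked`` holds (i, j) diagonal cells already
    claimed by accepted chains (Waterman–Eggert masking); gaps may still
    cross masked cells.
    """
    n, m = len(R), len(C)
    s_orth, s_hom, s_mis = params.ortholog_score, params.homolog_score, params.mismatch_score
    g_open, g_ext = params._open, params.gap_extend

    # matrices are (n+1) x (m+1); row 0 / col 0 are boundaries
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best_score, best_cell = 0, None

    for i in range(1, n + 1):
        ri = R[i - 1]
        Mi, Ei, Fi = M[i], E[i], F[i]
        Mp, Ep, Fp = M[i - 1], E[i - 1], F[i - 1]
        for j in range(1, m + 1):
            kind = relmap.get((ri, C[j - 1]))
            s = s_orth if kind == ORTHOLOG else s_hom if kind == HOMOLOG else s_mis
            Ei[j] = max(Mi[j - 1] + g_open, Ei[j - 1] + g_ext)
            Fi[j] = max(Mp[j] + g_open, Fp[j] + g_ext)
            if (i, j) in masked:
                Mi[j] = NEG
            else:
                Mi[j] = s + max(0, Mp[j - 1], Ep[j - 1], Fp[j - 1])
                if Mi[j] > best_score:
                    best_score, best_cell = Mi[j], (i, j)

    if best_cell is None:
        return None

    # traceback; tie preference: fresh start > diagonal > gap-in-compared (E)
    # > gap-in-reference (F)
    cols = []
    i, j = best_cell
    state = "M"
    while True:
        if state == "M":
            ri, cj = R[i - 1], C[j - 1]
            kind = relmap.get((ri, cj)) or MISMATCH
            cols.append((i - 1, j - 1, kind))
            s = s_orth if kind == ORTHOLOG else s_hom if kind == HOMOLOG else s_mis
            prev = M[i][j] - s
            if prev == 0:
                break
            if M[i - 1][j - 1] == prev:
                state = "M"
            elif E[i - 1][j - 1] == prev:
                state = "E"
            else:
                state = "F"
            i, j = i - 1, j - 1
        elif state == "E":
            if M[i][j - 1] + g_open == E[i][j]:
                state = "M"
            j -= 1
        else:  # F
            if M[i - 1][j] + g_open == F[i][j]:
                state = "M"
            i -= 1
    cols.reverse()
    # local optima never begin or end on a negative column
    assert cols[0][2] != MISMATCH and cols[-1][2] != MISMATCH
    return best_score, cols


def _extract_chains(R, C, relmap, params):
    """All chains of one replicon pair and orientation, best first."""
    masked = set()
    out = []
    for _ in range(len(R) * len(C) + 1):
        hit = _gotoh_best(R, C, relmap, params, masked)
        if hit is None or hit[0] < params.min_score:
            break
        score, cols = hit
        masked.update((i + 1, j + 1) for i, j, _ in cols)
        anchors = [(i, j, k) for i, j, k in cols if k != MISMATCH]
        if len(anchors) >= params.min_anchor_count:
            out.append((score, anchors))
    return out


# ---------------------------------------------------------------------------
# Block computation
# ---------------------------------------------------------------------------

def _mk_block(ref_genes, cmp_genes, orientation, score, anchors_ij,
              ref_gid, cmp_gid, ref_rep, cmp_rep):
    a_ref = [ref_genes[i] for i, _, _ in anchors_ij]
    a_cmp = [cmp_genes[j] for _, j, _ in anchors_ij]
    anchors = tuple(
        (r.gene_id, c.gene_id, k) for (_, _, k), r, c in zip(anchors_ij, a_ref, a_cmp)
    )
    return SyntenyBlock(
        ref_genome_id=ref_gid,
        cmp_genome_id=cmp_gid,
        orientation=orientation,
        anchors=anchors,
        score=score,
        ref_replicon=ref_rep,
        ref_start=min(g.start for g in a_ref),
        ref_end=max(g.end for g in a_ref),
        cmp_replicon=cmp_rep,
        cmp_start=min(g.start for g in a_cmp),
        cmp_end=max(g.end for g in a_cmp),
        ref_rank_lo=min(g.rank for g in a_ref),
        ref_rank_hi=max(g.rank for g in a_ref),
        cmp_rank_lo=min(g.rank for g in a_cmp),
        cmp_rank_hi=max(g.rank for g in a_cmp),
    )


def _spans_overlap(lo1, hi1, lo2, hi2):
    return lo1 <= hi2 and lo2 <= hi1


def compute_blocks(ref: GenomeCatalog, cmp: GenomeCatalog, relations,
                   params: SyntenyScoringParams = None) -> list:
    """Compute all synteny blocks (primary and offshoot) of a genome pair.

    *relations* is the relation list from :func:`pairsynt.homology.
    call_relations` (or a pre-built pair->kind mapping).  Blocks never span
    replicon boundaries; strand of individual genes is ignored — only gene
    order matters.
    """
    params = params or SyntenyScoringParams()
    relmap = relations if isinstance(relations, dict) else relation_map(relations)

    candidates = []
    for ref_rep in ref.replicon_ids:
        ref_genes = ref.genes_on(ref_rep)
        if not ref_genes:
            continue
        rset = {g.gene_id for g in ref_genes}
        for cmp_rep in cmp.replicon_ids:
            cmp_genes = cmp.genes_on(cmp_rep)
            if not cmp_genes:
                continue
            if not any((a, c.gene_id) in relmap for c in cmp_genes for a in rset):
                continue
            R = [g.gene_id for g in ref_genes]
            for orientation in (FORWARD, REVERSED):
                cg = cmp_genes if orientation == FORWARD else cmp_genes[::-1]
                C = [g.gene_id for g in cg]
                for score, anchors_ij in _extract_chains(R, C, relmap, params):
                    if orientation == REVERSED and len(anchors_ij) == 1:
                        continue  # identical single anchor is found forward
                    candidates.append(
                        _mk_block(ref_genes, cg, orientation, score, anchors_ij,
                                  ref.genome_id, cmp.genome_id, ref_rep, cmp_rep)
                    )

    # reconcile orientations / replicon pairs: primaries claim disjoint
    # stretches of both genomes, overlaps demote to offshoots, anchor-subset
    # duplicates are dropped
    order = sorted(
        candidates,
        key=lambda b: (-b.score, b.orientation != FORWARD, b.ref_replicon,
                       b.ref_rank_lo, b.cmp_replicon, b.cmp_rank_lo),
    )
    kept, primaries = [], []
    for b in order:
        pairs = b.anchor_pairs
        if any(pairs <= k.anchor_pairs for k in kept):
            continue
        clash = any(
            (p.ref_replicon == b.ref_replicon
             and _spans_overlap(p.ref_rank_lo, p.ref_rank_hi, b.ref_rank_lo, b.ref_rank_hi))
            or (p.cmp_replicon == b.cmp_replicon
                and _spans_overlap(p.cmp_rank_lo, p.cmp_rank_hi, b.cmp_rank_lo, b.cmp_rank_hi))
            for p in primaries
        )
        b = replace(b, is_offshoot=clash)
        kept.append(b)
        if not clash:
            primaries.append(b)

    rep_order = {rid: k for k, rid in enumerate(ref.replicon_ids)}
    kept.sort(key=lambda b: (b.is_offshoot, rep_order[b.ref_replicon],
                             b.ref_rank_lo, b.cmp_replicon, b.cmp_rank_lo))
    return kept


# ---------------------------------------------------------------------------
# Event segmentation
# ---------------------------------------------------------------------------

def segment_events(ref: GenomeCatalog, cmp: GenomeCatalog, blocks) -> list:
    """Segment one comparison into its ordered chain of annotation events.

    Primary blocks become ``synteny`` events ordered by reference start;
    maximal uncovered reference stretches become ``ref_specific`` events;
    compared-genome stretches covered by no block at all become
    ``cmp_specific`` events attached to their nearest flanking block on the
    compared genome (left flank preferred; a stretch before the first block
    attaches to, and is placed before, that block; a replicon with no
    blocks attaches to the end of the chain).
    """
    primaries = [b for b in blocks if not b.is_offshoot]
    for a in primaries:
        for b in primaries:
            if a is b or a.ref_replicon != b.ref_replicon:
                continue
            if _spans_overlap(a.ref_rank_lo, a.ref_rank_hi, b.ref_rank_lo, b.ref_rank_hi):
                raise RuntimeError("overlapping primary blocks; upstream reconciliation failed")

    events = []  # (sort key, AnnotationEvent without ordinal)
    block_event = {}
    for rep_idx, rid in enumerate(ref.replicon_ids):
        genes = ref.genes_on(rid)
        reps = sorted((b for b in primaries if b.ref_replicon == rid),
                      key=lambda b: b.ref_rank_lo)
        if not genes:
            ev = AnnotationEvent("ref_specific", -1, rid, 1,
                                 max(1, ref.replicon_lengths[rid]), ())
            events.append(ev)
            continue
        covered = {}
        for b in reps:
            for r in range(b.ref_rank_lo, b.ref_rank_hi + 1):
                covered[r] = b
        i = 0
        while i < len(genes):
            g = genes[i]
            b = covered.get(g.rank)
            if b is not None:
                span = [x for x in genes if b.ref_rank_lo <= x.rank <= b.ref_rank_hi]
                ev = AnnotationEvent("synteny", -1, rid, b.ref_start, b.ref_end,
                                     tuple(x.gene_id for x in span), block=b)
                events.append(ev)
                block_event[id(b)] = ev
                i += len(span)
            else:
                run = [g]
                i += 1
                while i < len(genes) and genes[i].rank not in covered:
                    run.append(genes[i])
                    i += 1
                ev = AnnotationEvent("ref_specific", -1, rid, run[0].start,
                                     run[-1].end, tuple(x.gene_id for x in run))
                events.append(ev)

    # compared-genome specific stretches (uncovered by any block, offshoots
    # included)
    attach_after, attach_before, tail = {}, {}, []
    for rid in cmp.replicon_ids:
        genes = cmp.genes_on(rid)
        if not genes:
            continue
        covered = set()
        for b in blocks:
            if b.cmp_replicon == rid:
                covered.update(range(b.cmp_rank_lo, b.cmp_rank_hi + 1))
        on_rep = sorted((b for b in primaries if b.cmp_replicon == rid),
                        key=lambda b: b.cmp_rank_lo)
        i = 0
        while i < len(genes):
            if genes[i].rank in covered:
                i += 1
                continue
            run = [genes[i]]
            i += 1
            while i < len(genes) and genes[i].rank not in covered:
                run.append(genes[i])
                i += 1
            ev = AnnotationEvent("cmp_specific", -1, rid, run[0].start,
                                 run[-1].end, tuple(x.gene_id for x in run))
            left = [b for b in on_rep if b.cmp_rank_hi < run[0].rank]
            right = [b for b in on_rep if b.cmp_rank_lo > run[-1].rank]
            if left:
                attach_after.setdefault(id(left[-1]), []).append(ev)
            elif right:
                attach_before.setdefault(id(right[0]), []).append(ev)
            else:
                tail.append(ev)

    chain = []
    for ev in events:
        if ev.kind == "synteny":
            chain.extend(attach_before.get(id(ev.block), []))
            chain.append(ev)
            chain.extend(attach_after.get(id(ev.block), []))
        else:
            chain.append(ev)
    n_before_tail = len(chain)
    chain.extend(tail)

    for ordinal, ev in enumerate(chain):
        ev.ordinal = ordinal
    # resolve attachments to ordinals
    target = {}
    for bid, evs in list(attach_after.items()) + list(attach_before.items()):
        for ev in evs:
            target[id(ev)] = bid
    by_bid = {bid: ev.ordinal for bid, ev in
              ((id(e.block), e) for e in chain if e.kind == "synteny")}
    last_ordinal = chain[n_before_tail - 1].ordinal if n_before_tail else None
    for ev in chain:
        if ev.kind == "cmp_specific":
            bid = target.get(id(ev))
            ev.attached_ordinal = by_bid.get(bid, last_ordinal)
    return chain


# ---------------------------------------------------------------------------
# Serialization: blocks TSV (v1) and events JSON (v1)
# ---------------------------------------------------------------------------

_BLOCK_HEADER = (
    "ref_genome", "cmp_genome", "orientation", "score", "n_anchors",
    "ref_replicon", "ref_start", "ref_end", "cmp_replicon", "cmp_start",
    "cmp_end", "is_offshoot", "anchors",
)


def write_blocks(blocks: Iterable[SyntenyBlock], path) -> None:
    lines = ["#pairsynt-blocks\tv1", "#" + "\t".join(_BLOCK_HEADER)]
    for b in blocks:
        anchors = ";".join(f"{r}:{c}:{k}" for r, c, k in b.anchors)
        lines.append("\t".join(map(str, (
            b.ref_genome_id, b.cmp_genome_id, b.orientation, b.score,
            b.n_anchors, b.ref_replicon, b.ref_start, b.ref_end,
            b.cmp_replicon, b.cmp_start, b.cmp_end, int(b.is_offshoot), anchors,
        ))))
    Path(path).write_text("\n".join(lines) + "\n")


def read_blocks(path, ref: GenomeCatalog, cmp: GenomeCatalog) -> list:
    """Read a blocks TSV; rank ranges are rebuilt from the catalogs."""
    blocks = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("#") or not line.strip():
            continue
        f = line.split("\t")
        if len(f) != len(_BLOCK_HEADER):
            raise ValidationError(f"{path}: bad blocks row: {line[:60]}")
        anchors = tuple(tuple(tok.split(":")) for tok in f[12].split(";") if tok)
        a_ref = [ref.gene(r) for r, _, _ in anchors]
        a_cmp = [cmp.gene(c) for _, c, _ in anchors]
        blocks.append(SyntenyBlock(
            ref_genome_id=f[0], cmp_genome_id=f[1], orientation=f[2],
            anchors=anchors, score=int(f[3]), ref_replicon=f[5],
            ref_start=int(f[6]), ref_end=int(f[7]), cmp_replicon=f[8],
            cmp_start=int(f[9]), cmp_end=int(f[10]),
            ref_rank_lo=min(g.rank for g in a_ref),
            ref_rank_hi=max(g.rank for g in a_ref),
            cmp_rank_lo=min(g.rank for g in a_cmp),
            cmp_rank_hi=max(g.rank for g in a_cmp),
            is_offshoot=bool(int(f[11])),
        ))
    return blocks


def write_events(events: Iterable[AnnotationEvent], path) -> None:
    out = {"schema": "pairsynt-events/1", "events": []}
    for ev in events:
        d = {
            "kind": ev.kind,
            "ordinal": ev.ordinal,
            "replicon_id": ev.replicon_id,
            "start": ev.start,
            "end": ev.end,
            "gene_ids": list(ev.gene_ids),
        }
        if ev.kind == "synteny":
            b = ev.block
            d["block"] = {
                "orientation": b.orientation,
                "score": b.score,
                "is_offshoot": b.is_offshoot,
                "cmp_replicon": b.cmp_replicon,
                "cmp_start": b.cmp_start,
                "cmp_end": b.cmp_end,
                "anchors": [list(a) for a in b.anchors],
            }
        if ev.kind == "cmp_specific":
            d["attached_ordinal"] = ev.attached_ordinal
        out["events"].append(d)
    Path(path).write_text(json.dumps(out, indent=1) + "\n")


def read_events(path) -> list:
    raw = json.loads(Path(path).read_text())
    if raw.get("schema") != "pairsynt-events/1":
        raise ValidationError(f"{path}: not a pairsynt events file")
    events = []
    for d in raw["events"]:
        block = None
        if "block" in d:
            b = d["block"]
            block = SyntenyBlock(
                ref_genome_id="", cmp_genome_id="", orientation=b["orientation"],
                anchors=tuple(tuple(a) for a in b["anchors"]), score=b["score"],
                ref_replicon=d["replicon_id"], ref_start=d["start"],
                ref_end=d["end"], cmp_replicon=b["cmp_replicon"],
                cmp_start=b["cmp_start"], cmp_end=b["cmp_end"],
                ref_rank_lo=0, ref_rank_hi=0, cmp_rank_lo=0, cmp_rank_hi=0,
                is_offshoot=b["is_offshoot"],
            )
        events.append(AnnotationEvent(
            kind=d["kind"], ordinal=d["ordinal"], replicon_id=d["replicon_id"],
            start=d["start"], end=d["end"], gene_ids=tuple(d["gene_ids"]),
            block=block, attached_ordinal=d.get("attached_ordinal"),
        ))
    return events
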