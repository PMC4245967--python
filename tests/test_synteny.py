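import random

import pytest

from pairsynt import (SyntenyScoringParams, chain_score, compute_blocks,
                      segment_events, write_blocks, read_blocks, write_events,
                      read_events, ValidationError, ORTHOLOG, HOMOLOG,
                      planted_block_instance)

from conftest import make_catalog, pair_relations, make_relation


# ---------------------------------------------------------------------------
# chain_score
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("chain,expected", [
    (["ortholog", "ortholog", "ortholog"], 12),
    (["ortholog", ("gap_cmp", 2), "ortholog"], -2),   # 4 + (-8 + -2) + 4
    (["homolog"], 2),
    (["ortholog", "mismatch", "ortholog"], 4),
    (["ortholog", ("gap_ref", 1), "homolog"], -2),    # 4 - 8 + 2
    (["ortholog", ("gap_ref", 3), ("gap_cmp", 2), "ortholog"], -14),
])
def test_chain_score_arithmetic(chain, expected):
    assert chain_score(chain) == expected


def test_single_homolog_meets_default_thresholds():
    p = SyntenyScoringParams()
    assert chain_score(["homolog"]) == 2 >= p.min_score
    assert p.min_anchor_count == 1


def test_alternative_gap_mode():
    p = SyntenyScoringParams(gap_mode="open_plus_per_gene")
    assert chain_score(["ortholog", ("gap_cmp", 2), "ortholog"], p) == 4 - 12 + 4


@pytest.mark.parametrize("bad", [
    [],
    [("gap_ref", 1), "ortholog"],
    ["ortholog", "mismatch"],
    ["ortholog", ("gap_ref", 0), "ortholog"],
    ["ortholog", "sideways", "ortholog"],
])
def test_chain_score_rejects_unanchored_or_malformed(bad):
    with pytest.raises(ValidationError):
        chain_score(bad)


def test_scoring_params_validation():
    with pytest.raises(ValidationError):
        SyntenyScoringParams(homolog_score=0)
    with pytest.raises(ValidationError):
        SyntenyScoringParams(gap_open=1)
    with pytest.raises(ValidationError):
        SyntenyScoringParams(min_anchor_count=0)


# ---------------------------------------------------------------------------
# compute_blocks
# ---------------------------------------------------------------------------

def test_identity_pair_single_forward_block():
    ref = make_catalog("R", 10)
    cmp = make_catalog("C", 10)
    rels = pair_relations(ref, cmp, {i: i for i in range(10)})
    blocks = compute_blocks(ref, cmp, rels)
    assert len(blocks) == 1
    b = blocks[0]
    assert b.orientation == "forward" and b.n_anchors == 10 and b.score == 40
    assert not b.is_offshoot


def test_inversion_yields_bowtie_between_forward_blocks():
    # compared genome = reference order with genes 4..7 (0-based 3..6) reversed
    ref = make_catalog("R", 10)
    cmp = make_catalog("C", 10)
    mapping = {i: i for i in range(10)}
    for k, i in enumerate(range(3, 7)):
        mapping[i] = 6 - k
    rels = pair_relations(ref, cmp, mapping)
    blocks = compute_blocks(ref, cmp, rels)
    prim = [b for b in blocks if not b.is_offshoot]
    assert [(b.orientation, b.n_anchors) for b in prim] == [
        ("forward", 3), ("reversed", 4), ("forward", 3)]
    assert all(not b.is_offshoot for b in prim)


def test_duplicated_segment_yields_one_offshoot():
    # ref genes 2..4 present twice in cmp: once as orthologs in context,
    # once as a weaker homolog copy far away
    ref = make_catalog("R", 12)
    cmp = make_catalog("C", 16)
    rels = pair_relations(ref, cmp, {i: i for i in range(12)})
    rels += [make_relation(ref.genes[i].gene_id, cmp.genes[13 + k].gene_id,
                           HOMOLOG, evalue=1e-5)
             for k, i in enumerate(range(2, 5))]
    blocks = compute_blocks(ref, cmp, rels)
    prim = [b for b in blocks if not b.is_offshoot]
    offs = [b for b in blocks if b.is_offshoot]
    assert len(prim) == 1 and prim[0].n_anchors == 12
    assert len(offs) == 1 and offs[0].n_anchors == 3
    assert {a[2] for a in offs[0].anchors} == {HOMOLOG}
    assert {a[0] for a in offs[0].anchors} <= {a[0] for a in prim[0].anchors}


def test_blocks_never_span_replicons():
    ref = make_catalog("R", 10, replicon_sizes=[5, 5])
    cmp = make_catalog("C", 10)
    rels = pair_relations(ref, cmp, {i: i for i in range(10)})
    blocks = compute_blocks(ref, cmp, rels)
    prim = [b for b in blocks if not b.is_offshoot]
    assert len(prim) == 2
    assert {b.ref_replicon for b in prim} == {"R_r0", "R_r1"}


def test_no_relations_no_blocks():
    ref = make_catalog("R", 5)
    cmp = make_catalog("C", 5)
    assert compute_blocks(ref, cmp, []) == []


def test_min_score_monotonicity():
    ref_cat, cmp_cat, rels, _ = planted_block_instance(3)
    prev = None
    for ms in (2, 6, 10, 16, 24, 9999):
        n = len(compute_blocks(ref_cat, cmp_cat, rels,
                               SyntenyScoringParams(min_score=ms)))
        if prev is not None:
            assert n <= prev
        prev = n
    assert prev == 0  # absurd threshold removes everything


def test_orientation_symmetry_reversing_compared_genome(rng):
    # reversing the compared gene order swaps forward/reversed labels but
    # preserves the multiset of block scores
    for seed in range(6):
        ref_cat, cmp_cat, rels, _ = planted_block_instance(seed)
        fwd = compute_blocks(ref_cat, cmp_cat, rels)
        flipped = make_catalog("C", len(cmp_cat))
        old_order = [g.gene_id for g in cmp_cat.genes]
        renamed = {old: flipped.genes[len(old_order) - 1 - r].gene_id
                   for r, old in enumerate(old_order)}
        rels2 = [make_relation(r.gene_a, renamed[r.gene_b], r.kind,
                               r.best_hit_a_to_b.evalue) for r in rels]
        rev = compute_blocks(ref_cat, flipped, rels2)
        assert sorted(b.score for b in fwd) == sorted(b.score for b in rev)
        fl = {"forward": "reversed", "reversed": "forward"}
        assert sorted((b.score, fl[b.orientation]) for b in fwd if b.n_anchors > 1) \
            == sorted((b.score, b.orientation) for b in rev if b.n_anchors > 1)


def test_ref_cmp_swap_preserves_primary_scores():
    for seed in (0, 1, 5):
        ref_cat, cmp_cat, rels, _ = planted_block_instance(seed)
        ab = compute_blocks(ref_cat, cmp_cat, rels)
        swapped = [make_relation(r.gene_b, r.gene_a, r.kind,
                                 r.best_hit_a_to_b.evalue) for r in rels]
        ba = compute_blocks(cmp_cat, ref_cat, swapped)
        assert sorted(b.score for b in ab if not b.is_offshoot) == \
               sorted(b.score for b in ba if not b.is_offshoot)


def test_compute_blocks_deterministic():
    ref_cat, cmp_cat, rels, _ = planted_block_instance(11)
    b1 = compute_blocks(ref_cat, cmp_cat, rels)
    b2 = compute_blocks(ref_cat, cmp_cat, list(reversed(rels)))
    assert [(b.anchors, b.score, b.orientation, b.is_offshoot) for b in b1] == \
           [(b.anchors, b.score, b.orientation, b.is_offshoot) for b in b2]


# ---------------------------------------------------------------------------
# planted-block recovery (fixture truth)
# ---------------------------------------------------------------------------

def _canon(blocks):
    out = set()
    for b in blocks:
        if isinstance(b, dict):
            out.add((b["orientation"], tuple((r, c) for r, c, _ in b["anchors"]),
                     b["is_offshoot"]))
        else:
            out.add((b.orientation, tuple((r, c) for r, c, _ in b.anchors),
                     b.is_offshoot))
    return out


@pytest.mark.parametrize("seed", range(8))
def test_planted_blocks_recovered_exactly(seed):
    ref_cat, cmp_cat, rels, expected = planted_block_instance(seed)
    blocks = compute_blocks(ref_cat, cmp_cat, rels)
    assert _canon(blocks) == _canon(expected)


# ---------------------------------------------------------------------------
# segment_events
# ---------------------------------------------------------------------------

def test_full_genome_block_single_event():
    ref = make_catalog("R", 6)
    cmp = make_catalog("C", 6)
    blocks = compute_blocks(ref, cmp, pair_relations(ref, cmp,
                                                     {i: i for i in range(6)}))
    events = segment_events(ref, cmp, blocks)
    assert [e.kind for e in events] == ["synteny"]
    assert events[0].ordinal == 0


def test_reference_island_becomes_ref_specific_event():
    # 5-gene island (ranks 3..7) present only in the reference; flanks are
    # kept below the bridging cost so the island is not absorbed as a gap
    ref = make_catalog("R", 11)
    cmp = make_catalog("C", 6)
    mapping = {i: i for i in range(3)}
    mapping.update({i + 8: i + 3 for i in range(3)})
    blocks = compute_blocks(ref, cmp, pair_relations(ref, cmp, mapping))
    events = segment_events(ref, cmp, blocks)
    assert [(e.kind, len(e.gene_ids)) for e in events] == [
        ("synteny", 3), ("ref_specific", 5), ("synteny", 3)]


def test_homolog_free_plasmid_single_cmp_specific_event():
    ref = make_catalog("R", 6)
    cmp = make_catalog("C", 10, replicon_sizes=[6, 4])
    blocks = compute_blocks(ref, cmp, pair_relations(ref, cmp,
                                                     {i: i for i in range(6)}))
    events = segment_events(ref, cmp, blocks)
    assert [e.kind for e in events] == ["synteny", "cmp_specific"]
    assert len(events[1].gene_ids) == 4
    assert events[1].attached_ordinal == 0


def test_event_partition_of_reference_genes(toy):
    from pairsynt import parse_hits, call_relations
    a, b = toy.catalogs["G0"], toy.catalogs["G1"]
    rels = call_relations(parse_hits(toy.hit_paths[("G0", "G1")], a, b),
                          parse_hits(toy.hit_paths[("G1", "G0")], b, a))
    events = segment_events(a, b, compute_blocks(a, b, rels))
    ref_events = [e for e in events if e.kind in ("synteny", "ref_specific")]
    seen = [g for e in ref_events for g in e.gene_ids]
    assert sorted(seen) == sorted(g.gene_id for g in a.genes)
    assert len(seen) == len(set(seen))
    # ordered by reference start
    starts = [e.start for e in ref_events]
    assert starts == sorted(starts)


def test_events_ordinals_consecutive(toy):
    from pairsynt import parse_hits, call_relations
    a, b = toy.catalogs["G0"], toy.catalogs["G1"]
    rels = call_relations(parse_hits(toy.hit_paths[("G0", "G1")], a, b),
                          parse_hits(toy.hit_paths[("G1", "G0")], b, a))
    events = segment_events(a, b, compute_blocks(a, b, rels))
    assert [e.ordinal for e in events] == list(range(len(events)))


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def test_blocks_tsv_roundtrip(tmp_path):
    ref_cat, cmp_cat, rels, _ = planted_block_instance(4)
    blocks = compute_blocks(ref_cat, cmp_cat, rels)
    path = tmp_path / "blocks.tsv"
    write_blocks(blocks, path)
    back = read_blocks(path, ref_cat, cmp_cat)
    assert [(b.anchors, b.score, b.orientation, b.is_offshoot,
             b.ref_rank_lo, b.cmp_rank_hi) for b in back] == \
           [(b.anchors, b.score, b.orientation, b.is_offshoot,
             b.ref_rank_lo, b.cmp_rank_hi) for b in blocks]


def test_events_json_roundtrip(tmp_path):
    ref_cat, cmp_cat, rels, _ = planted_block_instance(4)
    events = segment_events(ref_cat, cmp_cat,
                            compute_blocks(ref_cat, cmp_cat, rels))
    path = tmp_path / "events.json"
    write_events(events, path)
    back = read_events(path)
    assert [(e.kind, e.ordinal, e.gene_ids) for e in back] == \
           [(e.kind, e.ordinal, e.gene_ids) for e in events]
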