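import random

import pytest

from pairsynt import (build_profile, apply_filter, core_dispensable,
                      filter_from_json, write_profile, GeneFilter, FilterNode,
                      ValidationError, ORTHOLOG, HOMOLOG, ABSENT, HOMOLOG_ONLY)

from conftest import make_catalog, make_relation


def _random_profile(rng, n_genes=12, genomes=("B", "C", "D")):
    """Random label matrix realized through actual relations."""
    ref = make_catalog("A", n_genes)
    sets, labels = [], {}
    for gid in genomes:
        cmp = make_catalog(gid, n_genes)
        rels = []
        for i, g in enumerate(ref.genes):
            lab = rng.choice((ORTHOLOG, HOMOLOG_ONLY, ABSENT))
            labels[(g.gene_id, gid)] = lab
            if lab == ORTHOLOG:
                rels.append(make_relation(g.gene_id, cmp.genes[i].gene_id, ORTHOLOG))
            elif lab == HOMOLOG_ONLY:
                rels.append(make_relation(g.gene_id, cmp.genes[i].gene_id, HOMOLOG))
        sets.append((gid, rels))
    return ref, sets, labels


def test_bdbh_cell_is_ortholog():
    ref = make_catalog("A", 1)
    cmp = make_catalog("B", 1)
    prof = build_profile(ref, [("B", [make_relation("A_0000", "B_0000", ORTHOLOG)])])
    assert prof.label("A_0000", "B") == ORTHOLOG


def test_stacked_homologs_are_offshoots_in_one_cell():
    ref = make_catalog("A", 1)
    rels = [make_relation("A_0000", "B_0001", HOMOLOG),
            make_relation("A_0000", "B_0005", HOMOLOG)]
    prof = build_profile(ref, [("B", rels)])
    assert prof.label("A_0000", "B") == HOMOLOG_ONLY
    assert len(prof.supporting("A_0000", "B")) == 2


def test_planted_losses_are_absent_cells(toy):
    from pairsynt import parse_hits, call_relations
    a, b = toy.catalogs["G0"], toy.catalogs["G1"]
    rels = call_relations(parse_hits(toy.hit_paths[("G0", "G1")], a, b),
                          parse_hits(toy.hit_paths[("G1", "G0")], b, a))
    prof = build_profile(a, [("G1", rels)])
    absent = {g for g in prof.gene_ids if prof.label(g, "G1") == ABSENT}
    assert absent == set(toy.truth["specific"]["G1"]["ref_lost"])


def test_profile_rows_stable_under_input_permutation(rng):
    ref, sets, _ = _random_profile(rng)
    p1 = build_profile(ref, sets)
    p2 = build_profile(ref, list(reversed(sets)))
    for g in p1.gene_ids:
        for gid in p1.genome_ids:
            assert p1.label(g, gid) == p2.label(g, gid)


def test_unknown_reference_gene_fatal():
    ref = make_catalog("A", 1)
    with pytest.raises(ValidationError):
        build_profile(ref, [("B", [make_relation("NOPE", "B_0000", ORTHOLOG)])])


# ---------------------------------------------------------------------------
# filter algebra
# ---------------------------------------------------------------------------

def test_presence_and_absence_toy():
    rng = random.Random(0)
    ref = make_catalog("A", 4)
    b = [make_relation("A_0000", "B_0000", ORTHOLOG),
         make_relation("A_0001", "B_0001", ORTHOLOG)]
    d = [make_relation("A_0001", "D_0001", ORTHOLOG)]
    prof = build_profile(ref, [("B", b), ("D", d)])
    node = FilterNode("AND", (GeneFilter("presence", genomes=("B",)),
                              GeneFilter("absence", genomes=("D",))))
    assert apply_filter(prof, ref, node) == ["A_0000"]


def test_or_of_disjoint_filters_is_union_without_duplicates():
    ref = make_catalog("A", 4)
    prof = build_profile(ref, [("B", [])])
    f1 = GeneFilter("name_or_id", text="A_0000")
    f2 = GeneFilter("name_or_id", text="A_0002")
    out = apply_filter(prof, ref, FilterNode("OR", (f1, f2)))
    assert out == ["A_0000", "A_0002"]


def test_empty_and_returns_universe():
    ref = make_catalog("A", 3)
    prof = build_profile(ref, [("B", [])])
    assert apply_filter(prof, ref, FilterNode("AND", ())) == prof.gene_ids
    assert apply_filter(prof, ref, FilterNode("OR", ())) == []


def test_combinators_distribute_over_set_operations(rng):
    ref, sets, _ = _random_profile(rng)
    prof = build_profile(ref, sets)
    leaves = [GeneFilter("presence", genomes=("B",)),
              GeneFilter("presence", genomes=("C",), predicate="any_homolog"),
              GeneFilter("absence", genomes=("D",)),
              GeneFilter("name_or_id", text="0"),
              ]
    for f, g in [(leaves[0], leaves[1]), (leaves[2], leaves[3])]:
        fa = set(apply_filter(prof, ref, f))
        ga = set(apply_filter(prof, ref, g))
        assert set(apply_filter(prof, ref, FilterNode("AND", (f, g)))) == fa & ga
        assert set(apply_filter(prof, ref, FilterNode("OR", (f, g)))) == fa | ga


def test_annotation_filters_match_catalog_fields():
    from pairsynt import GeneRecord, GenomeCatalog
    genes = [
        GeneRecord("g0", "A", "chr", 100, 999, "+", 0, 100, product="DNA kinase",
                   go_terms={"molecular_function": frozenset({"GO:0016301"})},
                   ec_numbers=frozenset({"2.7.1.1"})),
        GeneRecord("g1", "A", "chr", 1100, 1999, "+", 1, 100,
                   product="membrane pump", xrefs=frozenset({"PF:PF00001"})),
    ]
    ref = GenomeCatalog("A", ["chr"], {"chr": 3000}, genes)
    prof = build_profile(ref, [("B", [])])
    assert apply_filter(prof, ref, GeneFilter("go_term", text="GO:0016301")) == ["g0"]
    assert apply_filter(prof, ref, GeneFilter("ec_number", text="2.7.1.1")) == ["g0"]
    assert apply_filter(prof, ref, GeneFilter("annotation_text", text="pump")) == ["g1"]
    assert apply_filter(prof, ref, GeneFilter("xref", text="PF:PF00001")) == ["g1"]
    assert apply_filter(prof, ref, GeneFilter("domain_motif", text="pf00001")) == ["g1"]
    assert apply_filter(prof, ref, GeneFilter("location", start=1000, end=2500)) == ["g1"]
    with pytest.raises(ValidationError):
        apply_filter(prof, ref, GeneFilter("go_term", text="0016301"))
    with pytest.raises(ValidationError):
        apply_filter(prof, ref, GeneFilter("ec_number", text="EC?"))


def test_filter_tree_from_json():
    node = filter_from_json({
        "op": "OR",
        "filters": [{"kind": "go_term", "text": "GO:1"},
                    {"op": "AND",
                     "filters": [{"kind": "presence", "genomes": ["B"],
                                  "predicate": "any_homolog"}]}],
    })
    assert isinstance(node, FilterNode) and node.op == "OR"
    assert isinstance(node.children[1], FilterNode)
    assert node.children[1].children[0].predicate == "any_homolog"


# ---------------------------------------------------------------------------
# core / dispensable
# ---------------------------------------------------------------------------

def test_single_genome_all_orthologs_core_is_everything():
    ref = make_catalog("A", 3)
    rels = [make_relation(g.gene_id, f"B_{i:04d}", ORTHOLOG)
            for i, g in enumerate(ref.genes)]
    prof = build_profile(ref, [("B", rels)])
    core, disp = core_dispensable(prof, ["B"])
    assert core == prof.gene_ids and disp == []


def test_core_dispensable_partition_property(rng):
    for _ in range(10):
        ref, sets, _ = _random_profile(rng)
        prof = build_profile(ref, sets)
        subset = rng.sample(prof.genome_ids, rng.randint(1, 3))
        for pred in (ORTHOLOG, "any_homolog"):
            core, disp = core_dispensable(prof, subset, pred)
            assert sorted(core + disp) == sorted(prof.gene_ids)
            assert not (set(core) & set(disp))


def test_any_homolog_core_contains_ortholog_core(rng):
    ref, sets, _ = _random_profile(rng)
    prof = build_profile(ref, sets)
    strict, _ = core_dispensable(prof, prof.genome_ids, ORTHOLOG)
    loose, _ = core_dispensable(prof, prof.genome_ids, "any_homolog")
    assert set(strict) <= set(loose)


def test_toy_island_is_dispensable(toy):
    from pairsynt import parse_hits, call_relations
    a, b = toy.catalogs["G0"], toy.catalogs["G1"]
    rels = call_relations(parse_hits(toy.hit_paths[("G0", "G1")], a, b),
                          parse_hits(toy.hit_paths[("G1", "G0")], b, a))
    prof = build_profile(a, [("G1", rels)])
    _, disp = core_dispensable(prof, ["G1"])
    assert set(toy.truth["specific"]["G1"]["ref_lost"]) == set(disp)


def test_profile_export_matrix(tmp_path, rng):
    ref, sets, labels = _random_profile(rng, n_genes=5, genomes=("B",))
    prof = build_profile(ref, sets)
    path = tmp_path / "prof.tsv"
    write_profile(prof, path)
    lines = path.read_text().splitlines()
    assert lines[0].split("\t")[1:] == prof.gene_ids
    row = dict(zip(lines[0].split("\t")[1:], lines[1].split("\t")[1:]))
    code = {ORTHOLOG: "O", HOMOLOG_ONLY: "H", ABSENT: "-"}
    for g in prof.gene_ids:
        assert row[g] == code[labels[(g, "B")]]
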