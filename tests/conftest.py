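import random

import pytest

from pairsynt import (GeneRecord, GenomeCatalog, HomologyHit, HomologyRelation,
                      worked_toy)


def make_catalog(genome_id, n, replicon_sizes=None, start0=100, spacing=1000):
    """A synthetic single- or multi-replicon catalog of n evenly spaced genes."""
    sizes = replicon_sizes or [n]
    assert sum(sizes) == n
    genes, rank = [], 0
    replicon_ids, lengths = [], {}
    for r, size in enumerate(sizes):
        rid = f"{genome_id}_r{r}"
        replicon_ids.append(rid)
        pos = start0
        for _ in range(size):
            genes.append(GeneRecord(
                gene_id=f"{genome_id}_{rank:04d}", genome_id=genome_id,
                replicon_id=rid, start=pos, end=pos + 899, strand="+",
                rank=rank, protein_length=250,
            ))
            rank += 1
            pos += spacing
        lengths[rid] = pos + 200
    return GenomeCatalog(genome_id, replicon_ids, lengths, genes)


def make_relation(a, b, kind, evalue=1e-40, identity=90.0, coverage=100.0):
    hab = HomologyHit(a, b, identity, 250, evalue, 450.0, coverage)
    hba = HomologyHit(b, a, identity, 250, evalue, 450.0, coverage)
    return HomologyRelation(a, b, kind, hab, hba)


def pair_relations(ref, cmp, mapping, kind="ortholog", evalue=1e-40):
    """Relations for an index mapping {ref rank: cmp rank}."""
    return [
        make_relation(ref.genes[i].gene_id, cmp.genes[j].gene_id, kind, evalue)
        for i, j in mapping.items()
    ]


@pytest.fixture(scope="session")
def toy(tmp_path_factory):
    """The deterministic documentation toy with its truth table."""
    return worked_toy(tmp_path_factory.mktemp("toy"))


@pytest.fixture()
def rng():
    return random.Random(42)
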