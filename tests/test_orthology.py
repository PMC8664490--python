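"""Synteny caller: chaining hand-traces, the four pairing rules, families."""

import pytest

from aperates.orthology import (
    GeneRecord,
    HomologyHit,
    OrthologPair,
    SyntenyBlock,
    assemble_families,
    detect_collinear_blocks,
    make_global_identity,
    read_blast_tab,
    read_gene_table,
    resolve_ortholog_pairs,
    write_blast_tab,
    write_gene_table,
)
from aperates.simulate import generate_toy_genomes


def make_genome(species, ids):
    return [
        GeneRecord(
            gene_id=g, species=species, chromosome=f"{species}_c1",
            start=1 + i * 1000, end=500 + i * 1000, rank=i,
        )
        for i, g in enumerate(ids)
    ]


def one_to_one_hits(ids_a, ids_b, bitscore=100.0):
    return [HomologyHit(a, b, bitscore) for a, b in zip(ids_a, ids_b)]


def exact_identity(a, b):
    return 100.0 if a.protein_sequence == b.protein_sequence else 50.0


class TestDetectCollinearBlocks:
    def test_identical_order_gives_one_block(self):
        A = make_genome("human", ["a1", "a2", "a3", "a4", "a5"])
        B = make_genome("chimp", ["b1", "b2", "b3", "b4", "b5"])
        hits = one_to_one_hits([g.gene_id for g in A], [g.gene_id for g in B])
        blocks = detect_collinear_blocks(A, B, hits)
        assert len(blocks) == 1
        assert blocks[0].size == 5 and blocks[0].orientation == "+"

    def test_reversed_middle_segment_forms_its_own_block(self):
        # middle three genes reversed in B: the reversed segment is its
        # own 3-gene block and the flanking singletons chain nowhere.
        A = make_genome("human", ["a1", "a2", "a3", "a4", "a5"])
        B = make_genome("chimp", ["b1", "b4", "b3", "b2", "b5"])
        hits = [HomologyHit(f"a{i}", f"b{i}", 100.0) for i in range(1, 6)]
        blocks = detect_collinear_blocks(A, B, hits)
        assert len(blocks) == 1
        assert blocks[0].orientation == "-"
        assert [p[0].gene_id for p in blocks[0].pairs] == ["a2", "a3", "a4"]

    def test_planted_inversions_recovered_exactly(self):
        toy = generate_toy_genomes(100, n_inversions=2, seed=3)
        blocks = detect_collinear_blocks(toy.genes_a, toy.genes_b, toy.hits)
        recovered = sorted(
            tuple(p[0].gene_id for p in b.pairs)
            for b in blocks
            if b.orientation == "-"
        )
        planted = sorted(tuple(seg) for seg in toy.registry["inversions"])
        assert recovered == planted
        # no spurious pairs anywhere
        true_pairs = set(map(tuple, toy.registry["pairs"]))
        for b in blocks:
            for ga, gb in b.pairs:
                assert (ga.gene_id, gb.gene_id) in true_pairs

    def test_unknown_gene_in_hit_rejected(self):
        A = make_genome("human", ["a1"])
        B = make_genome("chimp", ["b1"])
        with pytest.raises(ValueError):
            detect_collinear_blocks(A, B, [HomologyHit("a1", "nope", 1.0)])

    def test_raising_min_genes_never_increases_blocks(self):
        toy = generate_toy_genomes(80, n_inversions=1, n_tandem=2, seed=9)
        previous = None
        for mg in (3, 4, 6, 10):
            n = len(detect_collinear_blocks(toy.genes_a, toy.genes_b, toy.hits, min_genes=mg))
            if previous is not None:
                assert n <= previous
            previous = n


def pair_block(ga, gb, block_id=0, size=5):
    return SyntenyBlock(block_id, (ga.species, gb.species), [(ga, gb)], "+")


class TestResolveRules:
    def _genes(self):
        A = make_genome("human", ["a1", "a2", "a3"])
        B = make_genome("chimp", ["b1", "b2", "b3"])
        return A, B

    def test_high_identity_pair_retained(self):
        A, B = self._genes()
        blk = SyntenyBlock(0, ("human", "chimp"), [(A[0], B[0])], "+")
        pairs = resolve_ortholog_pairs(
            [blk], [HomologyHit("a1", "b1", 100.0)], identity=lambda a, b: 96.0
        )
        assert len(pairs) == 1 and pairs[0].identity_pct == 96.0

    def test_low_identity_with_better_hit_elsewhere_removed(self):
        A, B = self._genes()
        blk = SyntenyBlock(0, ("human", "chimp"), [(A[0], B[0])], "+")
        hits = [
            HomologyHit("a1", "b1", 100.0),
            HomologyHit("a1", "b3", 150.0),  # strictly better match elsewhere
        ]
        pairs = resolve_ortholog_pairs([blk], hits, identity=lambda a, b: 90.0)
        assert pairs == []

    def test_low_identity_without_better_hit_retained(self):
        A, B = self._genes()
        blk = SyntenyBlock(0, ("human", "chimp"), [(A[0], B[0])], "+")
        pairs = resolve_ortholog_pairs(
            [blk], [HomologyHit("a1", "b1", 100.0)], identity=lambda a, b: 90.0
        )
        assert len(pairs) == 1

    def test_equal_bitscore_tie_does_not_remove(self):
        A, B = self._genes()
        blk = SyntenyBlock(0, ("human", "chimp"), [(A[0], B[0])], "+")
        hits = [HomologyHit("a1", "b1", 100.0), HomologyHit("a1", "b3", 100.0)]
        pairs = resolve_ortholog_pairs([blk], hits, identity=lambda a, b: 90.0)
        assert len(pairs) == 1

    def test_gene_in_two_blocks_keeps_larger(self):
        A = make_genome("human", [f"a{i}" for i in range(1, 11)])
        B = make_genome("chimp", [f"b{i}" for i in range(1, 11)])
        small = SyntenyBlock(
            0, ("human", "chimp"), [(A[i], B[i]) for i in range(3)], "+"
        )
        # same human gene a1 paired with a different chimp gene in a larger block
        big = SyntenyBlock(
            1, ("human", "chimp"),
            [(A[0], B[5])] + [(A[i], B[i]) for i in range(3, 9)], "+",
        )
        hits = [HomologyHit(p[0].gene_id, p[1].gene_id, 100.0) for blk in (small, big) for p in blk.pairs]
        pairs = resolve_ortholog_pairs([small, big], hits, identity=lambda a, b: 99.0)
        a1 = [p for p in pairs if p.gene_a.gene_id == "a1"]
        assert len(a1) == 1 and a1[0].block_id == 1 and a1[0].block_size == 7

    def test_tandem_duplicate_pairs_removed(self):
        toy = generate_toy_genomes(40, n_tandem=1, seed=5)
        blocks = detect_collinear_blocks(toy.genes_a, toy.genes_b, toy.hits)
        pairs = resolve_ortholog_pairs(
            blocks, toy.hits, identity=exact_identity,
            genes=toy.genes_a + toy.genes_b,
        )
        (dup_id,) = toy.registry["tandem"]
        parent_id = dup_id[:-1]
        touched = {dup_id, parent_id}
        assert all(
            p.gene_a.gene_id not in touched and p.gene_b.gene_id not in touched
            for p in pairs
        )

    def test_output_is_one_to_one(self):
        toy = generate_toy_genomes(60, n_inversions=1, n_tandem=1, n_dispersed=1, seed=7)
        blocks = detect_collinear_blocks(toy.genes_a, toy.genes_b, toy.hits)
        pairs = resolve_ortholog_pairs(
            blocks, toy.hits, identity=exact_identity,
            genes=toy.genes_a + toy.genes_b,
        )
        a_ids = [p.gene_a.gene_id for p in pairs]
        b_ids = [p.gene_b.gene_id for p in pairs]
        assert len(a_ids) == len(set(a_ids)) and len(b_ids) == len(set(b_ids))

    def test_raising_identity_threshold_never_increases_pairs(self):
        toy = generate_toy_genomes(50, n_inversions=1, seed=13)
        blocks = detect_collinear_blocks(toy.genes_a, toy.genes_b, toy.hits)

        def noisy_identity(a, b):  # deterministic pseudo-identities
            return 90.0 + (hash((a.gene_id, b.gene_id)) % 100) / 10.0

        previous = None
        for thr in (90.0, 95.0, 99.0):
            n = len(
                resolve_ortholog_pairs(
                    blocks, toy.hits, identity=noisy_identity, identity_threshold=thr
                )
            )
            if previous is not None:
                assert n <= previous
            previous = n

    def test_identity_failure_names_pair(self):
        A, B = self._genes()
        blk = SyntenyBlock(0, ("human", "chimp"), [(A[0], B[0])], "+")

        def broken(a, b):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="a1 / b1"):
            resolve_ortholog_pairs([blk], [HomologyHit("a1", "b1", 1.0)], identity=broken)


def make_pairs(human_ids, species, skip=()):
    pairs = []
    for i, hid in enumerate(human_ids):
        if hid in skip:
            continue
        h = GeneRecord(hid, "human", "hc1", 1 + i * 1000, 500 + i * 1000, rank=i)
        o = GeneRecord(
            f"{species[:2]}_{hid}", species, f"{species}c1", 1 + i * 1000, 500 + i * 1000, rank=i
        )
        pairs.append(OrthologPair(h, o, block_id=0, block_size=len(human_ids)))
    return pairs


class TestAssembleFamilies:
    def test_full_overlap_and_missing_species(self):
        hids = [f"h{i}" for i in range(5)]
        fams = assemble_families(
            make_pairs(hids, "chimp"),
            make_pairs(hids, "gorilla"),
            make_pairs(hids, "gibbon", skip={"h2"}),
        )
        assert [f.human_gene_id for f in fams] == ["h0", "h1", "h3", "h4"]
        assert all(set(f.genes) == {"human", "chimp", "gorilla", "gibbon"} for f in fams)

    def test_planted_deletions_reduce_family_count_exactly(self):
        hids = [f"h{i:03d}" for i in range(100)]
        deleted = {f"h{i:03d}" for i in range(0, 100, 10)}  # 10 genes absent in gibbon
        fams = assemble_families(
            make_pairs(hids, "chimp"),
            make_pairs(hids, "gorilla"),
            make_pairs(hids, "gibbon", skip=deleted),
        )
        assert len(fams) == 90

    def test_duplicate_human_gene_rejected(self):
        dup = make_pairs(["h1"], "chimp") + make_pairs(["h1"], "chimp")
        with pytest.raises(ValueError):
            assemble_families(dup, make_pairs(["h1"], "gorilla"), make_pairs(["h1"], "gibbon"))


def test_completeness_on_collinear_genomes_with_identical_proteins():
    """Every gene of a rearrangement-free trio pivot forms a family."""
    toys = {
        sp: generate_toy_genomes(30, seed=s, species_a="human", species_b=sp)
        for sp, s in (("chimp", 1), ("gorilla", 2), ("gibbon", 3))
    }
    pair_lists = []
    for sp, toy in toys.items():
        blocks = detect_collinear_blocks(toy.genes_a, toy.genes_b, toy.hits)
        pair_lists.append(
            resolve_ortholog_pairs(
                blocks, toy.hits, identity=exact_identity,
                genes=toy.genes_a + toy.genes_b,
            )
        )
    fams = assemble_families(*pair_lists)
    assert len(fams) == 30


def test_global_identity_blosum62():
    ident = make_global_identity()
    assert ident("MKLVAN", "MKLVAN") == 100.0
    assert ident("MKLVANMKLVAN", "MKLVGNMKLVAN") == pytest.approx(100 * 11 / 12)


def test_gene_and_hit_tables_round_trip(tmp_path):
    toy = generate_toy_genomes(15, seed=4)
    gff = tmp_path / "a.gff3"
    tab = tmp_path / "hits.tsv"
    write_gene_table(toy.genes_a, gff)
    write_blast_tab(toy.hits, tab)
    genes = read_gene_table(gff, "human")
    hits = read_blast_tab(tab)
    assert [g.gene_id for g in genes] == [g.gene_id for g in toy.genes_a]
    assert [g.rank for g in genes] == [g.rank for g in toy.genes_a]
    assert {(h.query_id, h.subject_id) for h in hits} == {
        (h.query_id, h.subject_id) for h in toy.hits
    }
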