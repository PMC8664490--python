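"""Synteny-guided 1:1 ortholog calling.

Orthology is established positionally: genes that sit in runs of
conserved gene order (collinear blocks) between two genomes are taken as
positional orthologs, which sidesteps the paralog-contamination problems
of pure reciprocal-best-hit calling.  The caller works from two inputs a
practitioner already has: a gene-position table per genome (GFF-like) and
an all-vs-all protein homology hit table (BLAST outfmt-6-like).

Block detection chains homology anchors that advance monotonically in
both genomes (one orientation per chain) with at most ``max_gap``
skipped genes between consecutive anchors; chains shorter than
``min_genes`` are discarded.  Chains are extracted iteratively — longest
first, ties broken by compactness (smallest total rank slack), then
forward orientation, then leftmost start — with each anchor consumed by
one chain.  A gene may still occur in two blocks through different hits;
those conflicts are resolved by the pairing rules below.

Candidate pairs from the blocks then pass four parsing rules, in order:

1. a pair whose global-alignment identity is at least the threshold
   (default 95%) is retained outright;
2. otherwise the pair is dropped if either member has a strictly
   higher-bitscore hit to a different gene of the other species;
3. a gene occurring in pairs of two blocks keeps only the pair in the
   larger block (gene-pair count; ties keep the first-encountered block
   and are flagged);
4. pairs containing a tandem duplicate (one query hitting two
   same-chromosome genes at adjacent ranks) are dropped.

The surviving pairs are 1:1.  Families are assembled human-pivot style:
a human gene with a surviving partner in every other species forms one
four-species family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "HomologyHit",
    "SyntenyBlock",
    "OrthologPair",
    "OrthologFamily",
    "detect_collinear_blocks",
    "resolve_ortholog_pairs",
    "assemble_families",
    "make_global_identity",
    "read_gene_table",
    "write_gene_table",
    "read_blast_tab",
    "write_blast_tab",
]


@dataclass
class GeneRecord:
    """One protein-coding gene: position, order rank and protein sequence."""

    gene_id: str
    species: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int
    strand: str = "+"
    rank: int | None = None  # order index along the chromosome
    protein_sequence: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start {self.start} > end {self.end}")


@dataclass(frozen=True)
class HomologyHit:
    """A protein homology hit (BLAST tabular essentials)."""

    query_id: str
    subject_id: str
    bitscore: float
    percent_identity: float = 0.0

    def __post_init__(self) -> None:
        if self.bitscore < 0:
            raise ValueError("bitscore must be >= 0")


@dataclass
class SyntenyBlock:
    """A maximal collinear chain of gene pairs between two genomes."""

    block_id: int
    species_pair: tuple[str, str]
    pairs: list[tuple[GeneRecord, GeneRecord]]
    orientation: str  # "+" or "-"

    @property
    def size(self) -> int:
        return len(self.pairs)


@dataclass
class OrthologPair:
    """A retained 1:1 ortholog pair with its provenance."""

    gene_a: GeneRecord
    gene_b: GeneRecord
    block_id: int
    block_size: int
    identity_pct: float | None = None
    tie_flagged: bool = False


@dataclass
class OrthologFamily:
    """Four species' genes keyed by the human (pivot) gene."""

    human_gene_id: str
    genes: dict[str, GeneRecord]

    def __post_init__(self) -> None:
        if len(self.genes) != 4:
            raise ValueError("a family has exactly one gene per species")


def _assign_ranks(genes: Sequence[GeneRecord]) -> None:
    """Assign order ranks per chromosome (by start) where missing."""
    if all(g.rank is not None for g in genes):
        return
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chromosome, []).append(g)
    for chrom_genes in by_chrom.values():
        for i, g in enumerate(sorted(chrom_genes, key=lambda g: (g.start, g.gene_id))):
            g.rank = i


def detect_collinear_blocks(
    genes_a: Sequence[GeneRecord],
    genes_b: Sequence[GeneRecord],
    hits: Iterable[HomologyHit],
    min_genes: int = 3,
    max_gap: int = 2,
) -> list[SyntenyBlock]:
    """Chain homology anchors into orientation-consistent collinear blocks.

    Consecutive anchors of a chain must advance by at most ``max_gap + 1``
    ranks in both genomes, increasing in genome A and monotonically
    (direction fixed per chain) in genome B.  Hits naming genes absent
    from either table are rejected.
    """
    _assign_ranks(genes_a)
    _assign_ranks(genes_b)
    index_a = {g.gene_id: g for g in genes_a}
    index_b = {g.gene_id: g for g in genes_b}

    anchors: set[tuple[str, str]] = set()
    for h in hits:
        if h.query_id in index_a and h.subject_id in index_b:
            anchors.add((h.query_id, h.subject_id))
        elif h.query_id in index_b and h.subject_id in index_a:
            anchors.add((h.subject_id, h.query_id))
        else:
            raise ValueError(
                f"hit {h.query_id} -> {h.subject_id} references unknown genes"
            )

    groups: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for aid, bid in anchors:
        ga, gb = index_a[aid], index_b[bid]
        groups.setdefault((ga.chromosome, gb.chromosome), []).append(
            (ga.rank, gb.rank, aid, bid)  # type: ignore[arg-type]
        )

    species_pair = (genes_a[0].species, genes_b[0].species)
    blocks: list[SyntenyBlock] = []
    block_id = 0
    window = max_gap + 1
    for key in sorted(groups):
        pool = sorted(groups[key])
        while True:
            chain = _best_chain(pool, window)
            if chain is None or len(chain) < min_genes:
                break
            blocks.append(
                SyntenyBlock(
                    block_id=block_id,
                    species_pair=species_pair,
                    pairs=[(index_a[a], index_b[b]) for _, _, a, b in chain],
                    orientation=_chain_orientation(chain),
                )
            )
            block_id += 1
            used = set(chain)
            pool = [a for a in pool if a not in used]
    return blocks


def _chain_orientation(chain: list[tuple[int, int, str, str]]) -> str:
    if len(chain) < 2:
        return "+"
    return "+" if chain[1][1] > chain[0][1] else "-"


def _best_chain(
    pool: list[tuple[int, int, str, str]], window: int
) -> list[tuple[int, int, str, str]] | None:
    """Best chain in the pool: longest, then most compact, then forward, then leftmost."""
    if not pool:
        return None
    best_key = None
    best_chain = None
    for orient in (+1, -1):
        n = len(pool)
        length = [1] * n
        slack = [0] * n
        prev = [-1] * n
        for j in range(n):
            aj, bj = pool[j][0], pool[j][1]
            for i in range(j - 1, -1, -1):
                ai, bi = pool[i][0], pool[i][1]
                da = aj - ai
                if da > window:
                    break
                if da < 1:
                    continue
                db = orient * (bj - bi)
                if not 1 <= db <= window:
                    continue
                cand_len = length[i] + 1
                cand_slack = slack[i] + (da - 1) + (db - 1)
                if cand_len > length[j] or (
                    cand_len == length[j] and cand_slack < slack[j]
                ):
                    length[j], slack[j], prev[j] = cand_len, cand_slack, i
        for j in range(n):
            start = j
            while prev[start] != -1:
                start = prev[start]
            key = (length[j], -slack[j], orient, -pool[start][0])
            if best_key is None or key > best_key:
                best_key = key
                chain = []
                k = j
                while k != -1:
                    chain.append(pool[k])
                    k = prev[k]
                best_chain = chain[::-1]
    return best_chain


# ---------------------------------------------------------------------------
# Pair resolution
# ---------------------------------------------------------------------------


def make_global_identity(denominator: str = "alignment") -> Callable:
    """Global-alignment percent identity (BLOSUM62, gap open 10, extend 0.5).

    ``denominator`` selects the divisor: the full alignment length
    (default) or the shorter of the two sequences.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    if denominator not in ("alignment", "shortest"):
        raise ValueError("denominator must be 'alignment' or 'shortest'")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5

    def identity(a, b) -> float:
        seq_a = getattr(a, "protein_sequence", a)
        seq_b = getattr(b, "protein_sequence", b)
        aln = aligner.align(seq_a, seq_b)[0]
        counts = aln.counts()
        denom = aln.length if denominator == "alignment" else min(len(seq_a), len(seq_b))
        return 100.0 * counts.identities / denom

    return identity


def _tandem_flags(
    hits: Iterable[HomologyHit], gene_index: Mapping[str, GeneRecord], distance: int
) -> set[str]:
    """Genes hit by one query at adjacent ranks on the same chromosome."""
    by_query: dict[str, list[GeneRecord]] = {}
    for h in hits:
        subj = gene_index.get(h.subject_id)
        if subj is not None:
            by_query.setdefault(h.query_id, []).append(subj)
    flagged: set[str] = set()
    for subjects in by_query.values():
        by_chrom: dict[tuple[str, str], list[GeneRecord]] = {}
        for s in subjects:
            by_chrom.setdefault((s.species, s.chromosome), []).append(s)
        for group in by_chrom.values():
            group = sorted(group, key=lambda g: g.rank)  # type: ignore[arg-type]
            for s1, s2 in zip(group, group[1:]):
                if s2.rank - s1.rank <= distance and s1.gene_id != s2.gene_id:
                    flagged.add(s1.gene_id)
                    flagged.add(s2.gene_id)
    return flagged


def resolve_ortholog_pairs(
    blocks: Sequence[SyntenyBlock],
    hits: Iterable[HomologyHit],
    identity: Callable | None = None,
    identity_threshold: float = 95.0,
    tandem_distance: int = 1,
    genes: Iterable[GeneRecord] | None = None,
) -> list[OrthologPair]:
    """Apply the four parsing rules to block gene pairs; output is 1:1.

    Pass the full gene tables through ``genes`` so tandem duplicates can
    be recognised even when one copy did not make it into any block;
    otherwise only block members are rank-checkable.
    """
    if identity is None:
        identity = make_global_identity()
    hits = list(hits)
    gene_index: dict[str, GeneRecord] = {}
    for g in genes or ():
        gene_index.setdefault(g.gene_id, g)
    for blk in blocks:
        for ga, gb in blk.pairs:
            gene_index.setdefault(ga.gene_id, ga)
            gene_index.setdefault(gb.gene_id, gb)

    pair_score: dict[frozenset, float] = {}
    best_score: dict[str, float] = {}
    for h in hits:
        key = frozenset((h.query_id, h.subject_id))
        pair_score[key] = max(pair_score.get(key, 0.0), h.bitscore)
        for gid in (h.query_id, h.subject_id):
            best_score[gid] = max(best_score.get(gid, 0.0), h.bitscore)
    tandem = _tandem_flags(hits, gene_index, tandem_distance)

    # Rules 1-2 per candidate pair.
    candidates: list[OrthologPair] = []
    for blk in blocks:
        for ga, gb in blk.pairs:
            try:
                ident = float(identity(ga, gb))
            except Exception as exc:  # abort naming the offending pair
                raise RuntimeError(
                    f"identity computation failed for pair "
                    f"{ga.gene_id} / {gb.gene_id}"
                ) from exc
            if ident < identity_threshold:
                score = pair_score.get(frozenset((ga.gene_id, gb.gene_id)), 0.0)
                if best_score.get(ga.gene_id, 0.0) > score or best_score.get(
                    gb.gene_id, 0.0
                ) > score:
                    continue  # a strictly better match elsewhere: drop
            candidates.append(
                OrthologPair(ga, gb, blk.block_id, blk.size, identity_pct=ident)
            )

    # Rule 3: gene in pairs of two blocks keeps the larger block's pair.
    max_block: dict[str, int] = {}
    blocks_of: dict[str, set[int]] = {}
    for c in candidates:
        for gid in (c.gene_a.gene_id, c.gene_b.gene_id):
            max_block[gid] = max(max_block.get(gid, 0), c.block_size)
            blocks_of.setdefault(gid, set()).add(c.block_id)
    block_size_by_id = {c.block_id: c.block_size for c in candidates}
    n_max_blocks = {
        gid: sum(1 for b in bs if block_size_by_id[b] == max_block[gid])
        for gid, bs in blocks_of.items()
    }
    survivors: list[OrthologPair] = []
    claimed: dict[str, int] = {}  # gene -> block of its first max-size pair
    for c in candidates:
        ok = True
        for gid in (c.gene_a.gene_id, c.gene_b.gene_id):
            if len(blocks_of[gid]) > 1:
                if c.block_size < max_block[gid]:
                    ok = False
                    break
                first = claimed.setdefault(gid, c.block_id)
                if first != c.block_id:
                    ok = False  # size tie across blocks: keep first-encountered
                    break
                if n_max_blocks[gid] > 1:
                    c.tie_flagged = True
        if ok:
            survivors.append(c)

    # Rule 4: tandem duplicates.
    survivors = [
        c
        for c in survivors
        if c.gene_a.gene_id not in tandem and c.gene_b.gene_id not in tandem
    ]

    # Enforce 1:1 within what remains (duplicate hits inside one block).
    def sort_key(c: OrthologPair):
        return (
            -c.block_size,
            -pair_score.get(frozenset((c.gene_a.gene_id, c.gene_b.gene_id)), 0.0),
            -(c.identity_pct or 0.0),
            c.gene_a.gene_id,
            c.gene_b.gene_id,
        )

    final: list[OrthologPair] = []
    used: set[str] = set()
    for c in sorted(survivors, key=sort_key):
        if c.gene_a.gene_id in used or c.gene_b.gene_id in used:
            logger.info(
                "dropping %s/%s: gene already paired",
                c.gene_a.gene_id,
                c.gene_b.gene_id,
            )
            continue
        used.add(c.gene_a.gene_id)
        used.add(c.gene_b.gene_id)
        final.append(c)
    final.sort(key=lambda c: (c.gene_a.rank is None, c.gene_a.chromosome, c.gene_a.rank or 0))
    return final


def assemble_families(
    pairs_hc: Sequence[OrthologPair],
    pairs_hg: Sequence[OrthologPair],
    pairs_hb: Sequence[OrthologPair],
) -> list[OrthologFamily]:
    """Intersect the three human-vs-X pair lists into four-species families.

    Each list must be 1:1 on the human side (a duplicated human gene is a
    violated precondition).  Human genes missing from any list form no
    family; the per-species attrition is logged.
    """
    maps: list[dict[str, OrthologPair]] = []
    for pairs in (pairs_hc, pairs_hg, pairs_hb):
        m: dict[str, OrthologPair] = {}
        for p in pairs:
            human = p.gene_a if p.gene_a.species == "human" else p.gene_b
            if human.gene_id in m:
                raise ValueError(
                    f"human gene {human.gene_id} occurs twice in one pair list"
                )
            m[human.gene_id] = p
        maps.append(m)

    common = set(maps[0]) & set(maps[1]) & set(maps[2])
    for m in maps:
        other = next(iter(m.values()), None)
        if other is not None:
            sp = (
                other.gene_b.species
                if other.gene_a.species == "human"
                else other.gene_a.species
            )
            logger.info(
                "%d human genes without a %s partner dropped", len(m) - len(common), sp
            )
    families = []
    for hid in sorted(common):
        genes: dict[str, GeneRecord] = {}
        for m in maps:
            p = m[hid]
            human = p.gene_a if p.gene_a.species == "human" else p.gene_b
            other = p.gene_b if p.gene_a.species == "human" else p.gene_a
            genes["human"] = human
            genes[other.species] = other
        families.append(OrthologFamily(human_gene_id=hid, genes=genes))
    return families


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------

_BLAST_COLS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]


def read_gene_table(path, species: str, proteins: Mapping[str, str] | None = None) -> list[GeneRecord]:
    """Read a GFF3-like gene table (type == gene, ``ID=`` attribute)."""
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv
            )
            gid = attrs.get("ID")
            if gid is None:
                raise ValueError(f"gene line without ID attribute: {line}")
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    species=species,
                    chromosome=parts[0],
                    start=int(parts[3]),
                    end=int(parts[4]),
                    strand=parts[6],
                    protein_sequence=(proteins or {}).get(gid, ""),
                )
            )
    _assign_ranks(genes)
    return genes


def write_gene_table(genes: Sequence[GeneRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chromosome, g.start)):
            fh.write(
                "\t".join(
                    [
                        g.chromosome,
                        "aperates",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def read_blast_tab(path) -> list[HomologyHit]:
    """Read 12-column BLAST tabular (outfmt 6) hits."""
    df = pd.read_csv(path, sep="\t", names=_BLAST_COLS, comment="#")
    return [
        HomologyHit(
            query_id=str(r.qseqid),
            subject_id=str(r.sseqid),
            bitscore=float(r.bitscore),
            percent_identity=float(r.pident),
        )
        for r in df.itertuples()
    ]


def write_blast_tab(hits: Sequence[HomologyHit], path) -> None:
    rows = [
        {
            "qseqid": h.query_id,
            "sseqid": h.subject_id,
            "pident": h.percent_identity,
            "length": 0,
            "mismatch": 0,
            "gapopen": 0,
            "qstart": 0,
            "qend": 0,
            "sstart": 0,
            "send": 0,
            "evalue": 0.0,
            "bitscore": h.bitscore,
        }
        for h in hits
    ]
    pd.DataFrame(rows, columns=_BLAST_COLS).to_csv(path, sep="\t", header=False, index=False)
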