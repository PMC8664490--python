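"""Synthetic four-taxon ortholog families and toy genomes with known truth.

The generator evolves protein families on the fixed quartet
``((human, chimp), gorilla, gibbon)``: an ancestral sequence is drawn
uniformly over the twenty amino acids, and each column receives an
independent substitution event on each of the five branches with
probability ``rate_b * family_multiplier`` (times an episodic fold change
on one designated branch for a flagged subset of families).  An event on
a terminal branch replaces that taxon's residue with one of the 19
alternatives drawn uniformly — the downstream statistics measure identity
only, so exchangeability structure would add nothing.  An event on the
internal branch changes the common ancestor of human and chimp, so both
tips inherit the same replacement (unless their own terminal events
overwrite it).  The deeper stem towards gorilla is unpolarisable without
an outgroup and is folded into the gibbon branch rate, exactly as in the
downstream site classification.

Per-family rate multipliers follow a gamma distribution with mean 1
(shape configurable) to emulate family-rate heterogeneity; indels are
single-species deletion runs with geometric length (mean 3) that exercise
the gap-removal filter.  Multiple events on one column are allowed and
produce the discordant / no-identity site categories naturally.

Everything is driven by per-family seeds derived from the master seed, so
a fixed configuration reproduces bit-identical datasets, and the
ground-truth registry records every event for downstream assertions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .blocks import FamilyMSA
from .orthology import GeneRecord, HomologyHit
from .phylo import AMINO_ACIDS, BRANCHES, DEFAULT_BRANCH_RATES, TIPS

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedFamily",
    "generate_family",
    "generate_dataset",
    "ToyGenomePair",
    "generate_toy_genomes",
]

_N_AA = len(AMINO_ACIDS)
_AA_ARR = np.array(list(AMINO_ACIDS))
_TIP_BRANCH_INDEX = {"human": 0, "chimp": 1, "gorilla": 3, "gibbon": 4}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate the genome-wide ape quartet: per-site branch rates at
    the aggregate values, protein lengths 200–800 residues, gamma(shape 2)
    family-rate heterogeneity, a light indel load, and no episodic shifts
    unless ``episodic_fraction`` is raised.
    """

    branch_rates: tuple[float, ...] = tuple(DEFAULT_BRANCH_RATES[b] for b in BRANCHES)
    n_families: int = 1000
    length_min: int = 200
    length_max: int = 800
    family_rate_mean: float = 1.0
    family_rate_shape: float | None = 2.0  # None => multiplier fixed at the mean
    episodic_fraction: float = 0.0
    episodic_branch: str = "human"
    episodic_fold: float = 10.0
    indel_rate: float = 0.005  # per-column probability of starting a deletion run
    indel_mean_length: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.branch_rates) != len(BRANCHES):
            raise ValueError(f"need {len(BRANCHES)} branch rates")
        for r in self.branch_rates:
            if not np.isfinite(r) or not 0.0 <= r <= 1.0:
                raise ValueError(f"branch rate {r} outside [0, 1]")
        if not np.isfinite(self.indel_rate) or not 0.0 <= self.indel_rate <= 1.0:
            raise ValueError("indel_rate must be in [0, 1]")
        if not 0.0 <= self.episodic_fraction <= 1.0:
            raise ValueError("episodic_fraction must be in [0, 1]")
        if not self.episodic_fold > 0:
            raise ValueError("episodic_fold must be > 0")
        if self.episodic_branch not in BRANCHES:
            raise ValueError(f"unknown branch {self.episodic_branch!r}")
        if self.length_min < 1 or self.length_max < self.length_min:
            raise ValueError("need 1 <= length_min <= length_max")
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if self.family_rate_shape is not None and self.family_rate_shape <= 0:
            raise ValueError("family_rate_shape must be > 0 or None")

    def rates(self) -> dict[str, float]:
        return dict(zip(BRANCHES, self.branch_rates))


@dataclass
class GroundTruth:
    """Everything the generator knows about one family.

    ``events[i, j]`` records a substitution event on branch ``BRANCHES[i]``
    at ancestral column ``j``; ``counts`` are the per-branch event totals.
    ``exclusive_counts`` restricts to clean columns — exactly one event in
    the whole column and no gap — which downstream classification must
    recover exactly.
    """

    family_id: str
    counts: dict[str, int]
    events: np.ndarray  # (5, L) bool
    gaps: np.ndarray  # (4, L) bool
    multiplier: float
    episodic: bool
    episodic_branch: str | None

    @property
    def exclusive_counts(self) -> dict[str, int]:
        single = self.events.sum(axis=0) == 1
        clean = single & ~self.gaps.any(axis=0)
        return {
            b: int((self.events[i] & clean).sum()) for i, b in enumerate(BRANCHES)
        }


@dataclass
class SimulatedFamily:
    """A generated ortholog family; the alignment is the generating truth."""

    family_id: str
    msa: FamilyMSA

    @property
    def sequences(self) -> dict[str, str]:
        """Unaligned (gap-stripped) protein sequence per species."""
        return {
            sp: seq.replace("-", "")
            for sp, seq in zip(self.msa.species, self.msa.sequences)
        }


def _family_rng(config: SimulationConfig, family_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, family_index]))


def generate_family(
    config: SimulationConfig, family_index: int
) -> tuple[SimulatedFamily, GroundTruth]:
    """Generate one family plus its ground truth.

    The RNG stream consumes draws in a fixed order (episodic flag, length,
    multiplier, ancestral sequence, the 5 x L event matrix, replacements,
    indels), so configurations differing only in rates or fold changes
    share event-threshold draws — flagged and unflagged runs of the same
    seed are directly comparable.
    """
    rng = _family_rng(config, family_index)
    flagged = bool(rng.random() < config.episodic_fraction)
    L = int(rng.integers(config.length_min, config.length_max + 1))
    if config.family_rate_shape is None:
        mult = config.family_rate_mean
    else:
        mult = float(
            rng.gamma(
                config.family_rate_shape,
                config.family_rate_mean / config.family_rate_shape,
            )
        )
    p = np.array(config.branch_rates) * mult
    if flagged:
        p[BRANCHES.index(config.episodic_branch)] *= config.episodic_fold
    p = np.clip(p, 0.0, 1.0)

    anc = rng.integers(0, _N_AA, size=L)
    events = rng.random((5, L)) < p[:, None]

    def mutate(seq: np.ndarray, idx: np.ndarray) -> np.ndarray:
        out = seq.copy()
        if idx.size:
            # uniform over the 19 alternative residues
            out[idx] = (out[idx] + rng.integers(1, _N_AA, size=idx.size)) % _N_AA
        return out

    hc_anc = mutate(anc, np.flatnonzero(events[BRANCHES.index("internal")]))
    base = {"human": hc_anc, "chimp": hc_anc, "gorilla": anc, "gibbon": anc}
    tips = {
        tip: mutate(base[tip], np.flatnonzero(events[bi]))
        for tip, bi in _TIP_BRANCH_INDEX.items()
    }

    gaps = np.zeros((4, L), dtype=bool)
    if config.indel_rate > 0:
        starts = np.flatnonzero(rng.random(L) < config.indel_rate)
        for s0 in starts:
            species = int(rng.integers(0, 4))
            run = int(rng.geometric(1.0 / config.indel_mean_length))
            gaps[species, s0 : s0 + run] = True

    rows = []
    for si, tip in enumerate(TIPS):
        chars = _AA_ARR[tips[tip]].copy()
        chars[gaps[si]] = "-"
        rows.append("".join(chars))

    family_id = f"fam{family_index:05d}"
    fam = SimulatedFamily(
        family_id=family_id,
        msa=FamilyMSA(sequences=tuple(rows), species=TIPS, family_id=family_id),
    )
    truth = GroundTruth(
        family_id=family_id,
        counts={b: int(events[i].sum()) for i, b in enumerate(BRANCHES)},
        events=events,
        gaps=gaps,
        multiplier=mult,
        episodic=flagged,
        episodic_branch=config.episodic_branch if flagged else None,
    )
    return fam, truth


def generate_dataset(
    config: SimulationConfig,
) -> list[tuple[SimulatedFamily, GroundTruth]]:
    """Generate the full dataset; deterministic under a fixed seed."""
    return [generate_family(config, i) for i in range(config.n_families)]


def iter_dataset(config: SimulationConfig) -> Iterator[tuple[SimulatedFamily, GroundTruth]]:
    for i in range(config.n_families):
        yield generate_family(config, i)


# ---------------------------------------------------------------------------
# Toy genomes for the orthology module
# ---------------------------------------------------------------------------


@dataclass
class ToyGenomePair:
    """Two toy genomes with planted rearrangements and their homology hits.

    ``registry`` records the planted truth: ``pairs`` (true ortholog id
    pairs), ``inversions`` (lists of genome-A gene ids per inverted
    segment), ``tandem`` and ``dispersed`` (ids of the planted duplicate
    copies in genome B).
    """

    genes_a: list[GeneRecord]
    genes_b: list[GeneRecord]
    hits: list[HomologyHit]
    registry: dict


def _random_protein(rng: np.random.Generator, lo: int = 80, hi: int = 150) -> str:
    n = int(rng.integers(lo, hi + 1))
    return "".join(_AA_ARR[rng.integers(0, _N_AA, size=n)])


def generate_toy_genomes(
    n_genes: int,
    n_inversions: int = 0,
    n_tandem: int = 0,
    n_dispersed: int = 0,
    seed: int = 0,
    species_a: str = "human",
    species_b: str = "chimp",
) -> ToyGenomePair:
    """Build a collinear genome pair with planted features.

    Genome A lays ``n_genes`` genes in order on one chromosome; genome B
    carries the same genes, with ``n_inversions`` non-overlapping reversed
    segments of 4–8 genes, ``n_tandem`` duplicates inserted adjacent to
    their parent and ``n_dispersed`` duplicates placed far away.  Every
    true ortholog pair gets a reciprocal top-scoring homology hit;
    duplicates get weaker hits.  Gene ids in genome A depend only on
    ``n_genes`` and ``species_a``, so several pairs sharing one pivot
    genome can be generated with different seeds.
    """
    if n_genes < 10:
        raise ValueError("need at least 10 genes")
    if n_inversions * 10 > n_genes or n_tandem + n_dispersed > n_genes:
        raise ValueError("planted features exceed the genome size")
    rng = np.random.default_rng(np.random.SeedSequence([seed, n_genes]))

    a_ids = [f"{species_a[:2].upper()}g{i:04d}" for i in range(n_genes)]
    b_ids = [f"{species_b[:2].upper()}g{i:04d}" for i in range(n_genes)]
    proteins = {i: _random_protein(rng) for i in range(n_genes)}

    # Plant non-overlapping inversion segments of length 6-8: long enough
    # that a forward chain cannot hop through within the gap tolerance, so
    # every planted segment is unambiguously recoverable.
    order = list(range(n_genes))
    inverted: list[list[int]] = []
    occupied = np.zeros(n_genes, dtype=bool)
    attempts = 0
    while len(inverted) < n_inversions and attempts < 1000:
        attempts += 1
        length = int(rng.integers(6, 9))
        start = int(rng.integers(1, n_genes - length))  # keep first/last collinear
        if occupied[max(0, start - 1) : start + length + 1].any():
            continue
        occupied[start : start + length] = True
        order[start : start + length] = order[start : start + length][::-1]
        inverted.append(list(range(start, start + length)))
    if len(inverted) < n_inversions:
        raise ValueError("could not place the requested inversions")

    free = [i for i in range(n_genes) if not occupied[i]]
    rng.shuffle(free)
    tandem_parents = free[:n_tandem]
    dispersed_parents = free[n_tandem : n_tandem + n_dispersed]

    genes_a = [
        GeneRecord(
            gene_id=a_ids[i],
            species=species_a,
            chromosome=f"{species_a}_chr1",
            start=1 + 3000 * i,
            end=1000 + 3000 * i,
            strand="+",
            rank=i,
            protein_sequence=proteins[i],
        )
        for i in range(n_genes)
    ]

    # Genome B layout: ordered genes plus inserted duplicates.
    b_layout: list[tuple[str, int, str]] = []  # (gene_id, source index, strand)
    for pos, src in enumerate(order):
        strand = "-" if occupied[src] else "+"
        b_layout.append((b_ids[src], src, strand))
        if src in tandem_parents:
            b_layout.append((b_ids[src] + "t", src, "+"))
    for src in dispersed_parents:
        at = int(rng.integers(0, len(b_layout) + 1))
        b_layout.insert(at, (b_ids[src] + "d", src, "+"))

    genes_b = [
        GeneRecord(
            gene_id=gid,
            species=species_b,
            chromosome=f"{species_b}_chr1",
            start=1 + 3000 * pos,
            end=1000 + 3000 * pos,
            strand=strand,
            rank=pos,
            protein_sequence=proteins[src],
        )
        for pos, (gid, src, strand) in enumerate(b_layout)
    ]

    hits: list[HomologyHit] = []

    def add_hit(q: str, s: str, bitscore: float, pident: float) -> None:
        hits.append(HomologyHit(query_id=q, subject_id=s, bitscore=bitscore, percent_identity=pident))

    for i in range(n_genes):
        add_hit(a_ids[i], b_ids[i], 500.0, 100.0)
        add_hit(b_ids[i], a_ids[i], 500.0, 100.0)
    for src in tandem_parents:
        add_hit(a_ids[src], b_ids[src] + "t", 450.0, 95.0)
        add_hit(b_ids[src] + "t", a_ids[src], 450.0, 95.0)
    for src in dispersed_parents:
        add_hit(a_ids[src], b_ids[src] + "d", 450.0, 95.0)
        add_hit(b_ids[src] + "d", a_ids[src], 450.0, 95.0)

    registry = {
        "pairs": [(a_ids[i], b_ids[i]) for i in range(n_genes)],
        "inversions": [[a_ids[i] for i in seg] for seg in inverted],
        "tandem": [b_ids[i] + "t" for i in tandem_parents],
        "dispersed": [b_ids[i] + "d" for i in dispersed_parents],
    }
    return ToyGenomePair(genes_a=genes_a, genes_b=genes_b, hits=hits, registry=registry)
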