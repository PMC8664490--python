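"""Site-pattern classification and branch-specific substitution counts.

Every gap-free column of a filtered family alignment falls into exactly
one of seven pattern categories, determined by which of the four residues
(human, chimp, gorilla, gibbon) are identical:

``IDENTICAL``
    all four residues equal — no substitution.
``SPECIES_SPECIFIC``
    exactly one taxon differs from the other three: a single substitution
    on that terminal branch.
``INTERNAL``
    human = chimp, gorilla = gibbon, and the two pairs differ: a single
    substitution on the human+chimp stem.
``INCONSISTENT_2STATE``
    two states paired across the species tree (human = gorilla with
    chimp = gibbon, or human = gibbon with chimp = gorilla) — discordant
    with the topology, the signature of incomplete lineage sorting or
    introgression rather than a single branch event.
``CONSISTENT_3STATE``
    three states whose identical pair is a clade (human/chimp or
    gorilla/gibbon): parsimony-consistent but requiring two events.
``INCONSISTENT_3STATE``
    three states whose identical pair crosses the human+chimp split.
``NO_IDENTITY``
    four distinct residues (at least three independent events; such
    columns are rare enough to be flagged as candidate hypermutable
    sites).

Only ``SPECIES_SPECIFIC`` and ``INTERNAL`` columns — columns explicable
by a single substitution on one branch — contribute to the per-branch
counts ``n_b``; all multi-event and discordant categories are tallied but
excluded from rate estimation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .blocks import FilteredAlignment
from .phylo import AMINO_ACIDS, BRANCHES

__all__ = [
    "SiteCategory",
    "ColumnPattern",
    "FamilyCounts",
    "classify_column",
    "count_family",
    "expected_no_identity",
]


class SiteCategory(enum.Enum):
    IDENTICAL = "identical"
    SPECIES_SPECIFIC = "species_specific"
    INTERNAL = "internal"
    INCONSISTENT_2STATE = "inconsistent_2state"
    CONSISTENT_3STATE = "consistent_3state"
    INCONSISTENT_3STATE = "inconsistent_3state"
    NO_IDENTITY = "no_identity"


#: Categories that count toward a branch-specific substitution.
BRANCH_CATEGORIES = (SiteCategory.SPECIES_SPECIFIC, SiteCategory.INTERNAL)

_RESIDUES = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class ColumnPattern:
    """Classification of one aligned column."""

    residues: tuple[str, str, str, str]
    category: SiteCategory
    branch: str | None = None  # set only for SPECIES_SPECIFIC / INTERNAL


def classify_column(h: str, c: str, g: str, b: str) -> ColumnPattern:
    """Classify one gap-free column given the four residues.

    Arguments are the residues of human, chimp, gorilla and gibbon in that
    order.  Gaps and non-standard symbols are rejected: the block filter
    guarantees they never reach this stage.
    """
    residues = (h, c, g, b)
    for r in residues:
        if r not in _RESIDUES:
            raise ValueError(f"invalid residue {r!r} in column {residues}")
    hc, hg, hb = h == c, h == g, h == b
    cg, cb, gb = c == g, c == b, g == b
    if hc and hg and hb:
        return ColumnPattern(residues, SiteCategory.IDENTICAL)
    if cg and cb and not hc:  # c == g == b != h
        return ColumnPattern(residues, SiteCategory.SPECIES_SPECIFIC, "human")
    if hg and hb and not hc:
        return ColumnPattern(residues, SiteCategory.SPECIES_SPECIFIC, "chimp")
    if hc and hb and not hg:
        return ColumnPattern(residues, SiteCategory.SPECIES_SPECIFIC, "gorilla")
    if hc and hg and not hb:
        return ColumnPattern(residues, SiteCategory.SPECIES_SPECIFIC, "gibbon")
    if hc and gb and not hg:
        return ColumnPattern(residues, SiteCategory.INTERNAL, "internal")
    if (hg and cb) or (hb and cg):
        return ColumnPattern(residues, SiteCategory.INCONSISTENT_2STATE)
    n_states = len(set(residues))
    if n_states == 3:
        if hc or gb:
            return ColumnPattern(residues, SiteCategory.CONSISTENT_3STATE)
        return ColumnPattern(residues, SiteCategory.INCONSISTENT_3STATE)
    assert n_states == 4
    return ColumnPattern(residues, SiteCategory.NO_IDENTITY)


@dataclass
class FamilyCounts:
    """Per-branch substitution counts and category tallies for one family."""

    family_id: str
    L: int
    n: dict[str, int]
    category_counts: dict[SiteCategory, int] = field(default_factory=dict)

    @property
    def N(self) -> int:
        """Total branch-specific substitutions across the five branches."""
        return sum(self.n.values())

    def __post_init__(self) -> None:
        missing = set(BRANCHES) - set(self.n)
        if missing:
            raise ValueError(f"{self.family_id}: missing branch counts {sorted(missing)}")
        if self.N > self.L:
            raise ValueError(f"{self.family_id}: N={self.N} exceeds L={self.L}")


def count_family(filtered: FilteredAlignment) -> FamilyCounts:
    """Tally site categories and per-branch counts over a filtered alignment.

    The per-branch count of the four terminal branches is the number of
    columns where only that taxon differs; the internal count is the
    number of human=chimp vs gorilla=gibbon columns.  The gibbon count
    implicitly contains the unpolarisable deeper stem.  Runs vectorised;
    agrees column-for-column with :func:`classify_column`.
    """
    cats = {cat: 0 for cat in SiteCategory}
    n = {b: 0 for b in BRANCHES}
    if filtered.L == 0:
        return FamilyCounts(filtered.family_id, 0, n, cats)
    a = np.array([list(s) for s in filtered.sequences])
    h, c, g, b = a[0], a[1], a[2], a[3]
    hc, hg, hb = h == c, h == g, h == b
    cg, cb, gb = c == g, c == b, g == b
    identical = hc & hg & hb
    human_s = cg & cb & ~hc
    chimp_s = hg & hb & ~hc
    gorilla_s = hc & hb & ~hg
    gibbon_s = hc & hg & ~hb
    internal = hc & gb & ~hg
    incons2 = ((hg & cb) | (hb & cg)) & ~hc
    n_pairs = (
        hc.astype(np.int8) + hg + hb + cg + cb + gb
    )  # 0 pairs => 4 states, 1 pair => 3 states
    three_state = n_pairs == 1
    cons3 = three_state & (hc | gb)
    incons3 = three_state & ~(hc | gb)
    no_ident = n_pairs == 0

    n["human"] = int(human_s.sum())
    n["chimp"] = int(chimp_s.sum())
    n["gorilla"] = int(gorilla_s.sum())
    n["gibbon"] = int(gibbon_s.sum())
    n["internal"] = int(internal.sum())
    cats[SiteCategory.IDENTICAL] = int(identical.sum())
    cats[SiteCategory.SPECIES_SPECIFIC] = (
        n["human"] + n["chimp"] + n["gorilla"] + n["gibbon"]
    )
    cats[SiteCategory.INTERNAL] = n["internal"]
    cats[SiteCategory.INCONSISTENT_2STATE] = int(incons2.sum())
    cats[SiteCategory.CONSISTENT_3STATE] = int(cons3.sum())
    cats[SiteCategory.INCONSISTENT_3STATE] = int(incons3.sum())
    cats[SiteCategory.NO_IDENTITY] = int(no_ident.sum())
    assert sum(cats.values()) == filtered.L
    return FamilyCounts(filtered.family_id, filtered.L, n, cats)


def expected_no_identity(r1: float, r2: float, r3: float, L: int) -> float:
    """Expected count of columns independently substituted on three lineages.

    A four-state column requires at least three independent events; with
    per-site rates ``r1, r2, r3`` on the three fastest lineages and ``L``
    aligned sites the expectation is simply ``r1 * r2 * r3 * L``.
    """
    for r in (r1, r2, r3):
        if not (0.0 <= r <= 1.0) or not np.isfinite(r):
            raise ValueError(f"rate {r} outside [0, 1]")
    if L < 0:
        raise ValueError("L must be >= 0")
    return r1 * r2 * r3 * L
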