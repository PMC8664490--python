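"""Branch-length statistics: relative lengths, per-site rates, Poisson
correction and the mean tree.

All statistics are simple functions of the per-branch branch-specific
substitution counts ``n_b`` and the alignment overlap ``L``:

* relative branch length: ``n_b / sum_b n_b`` — used both as a report
  column and as the event probabilities of the multinomial null;
* % substitutions per site: ``100 * n_b / L`` (or with the total
  substituted-site count in the numerator for the overall rate);
* Poisson-corrected (PC) branch length: ``-ln(1 - n_b / L)``, the
  standard multiple-hit correction for protein distances; undefined at
  ``n_b = L`` (saturated), which is treated as an error rather than
  clamped since it cannot occur at these shallow divergences;
* the mean tree: per-branch arithmetic mean of PC lengths across all
  families with at least one substitution — the reference "average
  divergence" tree for the deviation tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .phylo import BRANCHES, BRANCH_LABELS
from .sites import FamilyCounts

__all__ = [
    "SaturationError",
    "relative_branch_lengths",
    "pct_substitutions_per_site",
    "pc_branch_length",
    "family_tree",
    "MeanTree",
    "mean_tree",
    "branch_stats_table",
]


class SaturationError(ValueError):
    """Raised when every site of a branch is substituted (PC length infinite)."""


def _as_totals(totals) -> dict[str, float]:
    if isinstance(totals, Mapping):
        return {b: totals[b] for b in BRANCHES}
    vals = list(totals)
    if len(vals) != len(BRANCHES):
        raise ValueError(f"expected {len(BRANCHES)} totals, got {len(vals)}")
    return dict(zip(BRANCHES, vals))


def relative_branch_lengths(totals) -> dict[str, float]:
    """Per-branch share of all branch-specific substitutions (sums to 1).

    ``totals`` is a mapping or a sequence in branch order.  Undefined when
    all totals are zero.
    """
    t = _as_totals(totals)
    s = sum(t.values())
    if s < 1:
        raise ValueError("relative branch lengths undefined for all-zero totals")
    return {b: t[b] / s for b in BRANCHES}


def pct_substitutions_per_site(n: int, L: int) -> float:
    """``100 * n / L`` — substituted sites per 100 aligned sites."""
    if L < 1:
        raise ValueError("L must be >= 1 (zero-overlap families are excluded upstream)")
    if not 0 <= n <= L:
        raise ValueError(f"substitution count {n} outside [0, {L}]")
    return 100.0 * n / L


def pc_branch_length(n: int, L: int) -> float:
    """Poisson-corrected branch length ``-ln(1 - n/L)``.

    Monotone in ``n`` and always at least the raw proportion ``n/L``.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if not 0 <= n <= L:
        raise ValueError(f"substitution count {n} outside [0, {L}]")
    if n == L:
        raise SaturationError(
            f"all {L} sites substituted: Poisson-corrected length is infinite"
        )
    return -math.log1p(-n / L)


def family_tree(counts: FamilyCounts) -> dict[str, float]:
    """PC length of each of the five branches for one family."""
    return {b: pc_branch_length(counts.n[b], counts.L) for b in BRANCHES}


@dataclass
class MeanTree:
    """Per-branch average PC length over families with >= 1 substitution."""

    pc: dict[str, float]
    n_families_used: int
    n_zero_excluded: int

    @property
    def tree_length(self) -> float:
        return sum(self.pc.values())


def mean_tree(families: Iterable[FamilyCounts]) -> MeanTree:
    """Average the PC branch lengths over all substituted families.

    Families with no substitution carry no tree and are excluded (their
    count is reported separately); an empty eligible set is an error.
    """
    sums = {b: 0.0 for b in BRANCHES}
    used = 0
    zero = 0
    for fc in families:
        if fc.N == 0:
            zero += 1
            continue
        tree = family_tree(fc)
        for b in BRANCHES:
            sums[b] += tree[b]
        used += 1
    if used == 0:
        raise ValueError("mean tree undefined: no family has a substitution")
    return MeanTree({b: sums[b] / used for b in BRANCHES}, used, zero)


def branch_stats_table(
    totals,
    L_total: int,
    times_mya: Mapping[str, float],
    mean: MeanTree | None = None,
) -> pd.DataFrame:
    """Aggregate per-branch summary table.

    Columns mirror the standard genome-wide report: branch time (Mya),
    total branch-specific substitutions, relative branch length (4 d.p.),
    % substitutions per site (2 d.p.) and per Mya (3 d.p.), plus the mean
    tree PC length (3 d.p.) when a mean tree is supplied.  Rounding is
    applied only here; all internal computation is full precision.
    """
    t = _as_totals(totals)
    rel = relative_branch_lengths(t)
    rows = []
    for b in BRANCHES:
        pct = pct_substitutions_per_site(int(t[b]), L_total)
        row = {
            "branch": BRANCH_LABELS[b],
            "branch_key": b,
            "time_mya": times_mya[b],
            "total_subs": int(t[b]),
            "relative_length": round(rel[b], 4),
            "pct_per_site": round(pct, 2),
            "pct_per_site_per_mya": round(pct / times_mya[b], 3),
        }
        if mean is not None:
            row["mean_tree_pc"] = round(mean.pc[b], 3)
        rows.append(row)
    return pd.DataFrame(rows)
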