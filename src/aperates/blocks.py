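"""Conserved-block filtering of four-sequence protein alignments.

A family alignment is reduced to the concatenation of its gap-free
conserved blocks before any substitution counting.  With four sequences
and the strict settings used throughout (every sequence must agree for a
position to count as conserved, no gaps allowed), the filter is:

1. every column containing a gap is removed;
2. any maximal run of more than ``max_nonconserved_run`` consecutive
   non-conserved columns is removed entirely (three or more contiguous
   substituted positions are more plausibly an unannotated indel or
   misalignment than independent point substitutions at this divergence);
3. the surviving columns are split into blocks at every removed column,
   block margins are trimmed back to conserved columns, and blocks
   shorter than ``min_block`` columns are dropped.

The number of surviving columns is the *alignment overlap* L, the
denominator of every per-site statistic downstream.  Because the filtered
alignment is gap-free, L can never exceed the length of the shortest
unaligned ortholog; the ratio of the two is the *alignment saturation*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phylo import GAP, TIPS

__all__ = [
    "FamilyMSA",
    "FilteredAlignment",
    "filter_blocks",
    "alignment_saturation",
    "length_variation",
]

@dataclass(frozen=True)
class FamilyMSA:
    """A four-sequence protein multiple alignment (rows may contain gaps)."""

    sequences: tuple[str, str, str, str]
    species: tuple[str, str, str, str] = TIPS
    family_id: str = "family"

    def __post_init__(self) -> None:
        if len(self.sequences) != 4 or len(self.species) != 4:
            raise ValueError("a family alignment has exactly four rows")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError(
                f"{self.family_id}: aligned sequences differ in length {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    def ungapped_lengths(self) -> tuple[int, ...]:
        return tuple(len(s) - s.count(GAP) for s in self.sequences)


@dataclass
class FilteredAlignment:
    """Concatenated gap-free conserved blocks of one family alignment.

    ``kept_columns`` holds the 0-based indices of surviving columns in the
    original alignment (machine convention; human-readable reports add 1).
    ``block_spans`` are half-open ``(start, stop)`` intervals in original
    coordinates, one per retained block.
    """

    family_id: str
    species: tuple[str, str, str, str]
    sequences: tuple[str, str, str, str]
    kept_columns: np.ndarray
    block_spans: tuple[tuple[int, int], ...]
    L: int
    shortest_len: int
    saturation: float

    @property
    def non_overlapping(self) -> bool:
        """True when no block survived: the family has no usable overlap."""
        return self.L == 0


def filter_blocks(
    msa: FamilyMSA,
    min_block: int = 10,
    max_nonconserved_run: int = 2,
) -> FilteredAlignment:
    """Apply the gap-free conserved-block filter to one family alignment.

    Parameters
    ----------
    msa
        Four aligned amino-acid sequences of equal length.
    min_block
        Minimum number of columns for a block to be retained.
    max_nonconserved_run
        Longest run of consecutive non-conserved columns allowed inside a
        block; longer runs are removed entirely.
    """
    if min_block < 1 or max_nonconserved_run < 0:
        raise ValueError("min_block must be >= 1 and max_nonconserved_run >= 0")
    arr = np.array([list(s) for s in msa.sequences])
    n_cols = arr.shape[1]
    gap_col = (arr == GAP).any(axis=0)
    conserved = (~gap_col) & (arr == arr[0]).all(axis=0)
    removed = gap_col.copy()

    # Remove over-long runs of non-conserved columns.  Runs are counted in
    # original coordinates; gap columns and conserved columns both break a
    # run (a non-conserved column stranded against a gap is caught by the
    # margin trim below).
    run_start = None
    for i in range(n_cols + 1):
        in_run = i < n_cols and not gap_col[i] and not conserved[i]
        if in_run and run_start is None:
            run_start = i
        elif not in_run and run_start is not None:
            if i - run_start > max_nonconserved_run:
                removed[run_start:i] = True
            run_start = None

    # Split surviving columns into blocks at removed columns, trim margins
    # back to conserved columns, enforce the minimum block length.
    spans: list[tuple[int, int]] = []
    kept_idx: list[np.ndarray] = []
    start = None
    for i in range(n_cols + 1):
        alive = i < n_cols and not removed[i]
        if alive and start is None:
            start = i
        elif not alive and start is not None:
            lo, hi = start, i  # half-open candidate block
            while lo < hi and not conserved[lo]:
                lo += 1
            while hi > lo and not conserved[hi - 1]:
                hi -= 1
            if hi - lo >= min_block:
                spans.append((lo, hi))
                kept_idx.append(np.arange(lo, hi))
            start = None

    kept = np.concatenate(kept_idx) if kept_idx else np.empty(0, dtype=int)
    seqs = tuple("".join(arr[r, kept]) for r in range(4))
    shortest = min(msa.ungapped_lengths())
    if shortest < 1:
        raise ValueError(f"{msa.family_id}: a sequence is empty after removing gaps")
    L = int(kept.size)
    return FilteredAlignment(
        family_id=msa.family_id,
        species=msa.species,
        sequences=seqs,  # type: ignore[arg-type]
        kept_columns=kept,
        block_spans=tuple(spans),
        L=L,
        shortest_len=shortest,
        saturation=alignment_saturation(L, shortest),
    )


def alignment_saturation(L: int, shortest_len: int) -> float:
    """Percent of the shortest ortholog retained in the filtered alignment.

    ``100 * L / shortest_len``, reported to two decimals.  A gap-free
    alignment can never be longer than its shortest sequence, so values
    are always in [0, 100].
    """
    if shortest_len < 1:
        raise ValueError("shortest_len must be >= 1")
    if not 0 <= L <= shortest_len:
        raise ValueError(
            f"alignment overlap {L} outside [0, {shortest_len}]: a gap-free "
            "alignment cannot exceed the shortest sequence"
        )
    return round(100.0 * L / shortest_len, 2)


def length_variation(sequences) -> float:
    """Length spread of a family: (longest - shortest) per 100 residues of the shortest."""
    lengths = [len(s) for s in sequences]
    if not lengths or min(lengths) < 1:
        raise ValueError("length_variation requires non-empty sequences")
    return 100.0 * (max(lengths) - min(lengths)) / min(lengths)
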