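"""Branch conventions and default calibration for the ape quartet.

The analysis works on the fixed four-taxon tree

    ((human, chimp), gorilla, gibbon)

with five branches carrying substitutions: the four terminal branches and
the internal branch subtending human+chimp.  Without an outgroup the deeper
internal branch (subtending human+chimp+gorilla) cannot be polarised and is
absorbed into the gibbon branch, so "gibbon" here always means the gibbon
terminal branch plus that stem.

The default per-site substitution probabilities and branch times shipped
here are the genome-wide aggregate values for human, chimpanzee, gorilla
and white-cheeked gibbon (divergence times from timetree.org); they are
configuration defaults, not computed quantities.
"""

from __future__ import annotations

#: Branch order used everywhere: arrays of per-branch quantities follow it.
BRANCHES: tuple[str, ...] = ("human", "chimp", "internal", "gorilla", "gibbon")

#: Terminal taxa in the row order of every four-sequence alignment.
TIPS: tuple[str, ...] = ("human", "chimp", "gorilla", "gibbon")

#: Human-readable branch labels for report tables.
BRANCH_LABELS: dict[str, str] = {
    "human": "Human",
    "chimp": "Chimpanzee",
    "internal": "Human+Chimp stem",
    "gorilla": "Gorilla",
    "gibbon": "Gibbon (incl. deeper stem)",
}

#: Aggregate per-site substitution probability of each branch (dimensionless).
DEFAULT_BRANCH_RATES: dict[str, float] = {
    "human": 0.0027,
    "chimp": 0.0026,
    "internal": 0.0009,
    "gorilla": 0.0036,
    "gibbon": 0.0134,
}

#: Branch durations in million years (timetree calibration).
DEFAULT_BRANCH_TIMES_MYA: dict[str, float] = {
    "human": 6.65,
    "chimp": 6.65,
    "internal": 2.41,
    "gorilla": 9.06,
    "gibbon": 31.24,
}

#: Genome-wide branch-specific substitution totals of the reference
#: four-ape ortholog survey, used as a worked-example input in tests and
#: reports (sum = 168,768).
REFERENCE_BRANCH_TOTALS: dict[str, int] = {
    "human": 19815,
    "chimp": 18818,
    "internal": 6279,
    "gorilla": 26026,
    "gibbon": 97830,
}

#: Total aligned gap-free sites of the reference survey.
REFERENCE_ALIGNED_SITES: int = 7_313_620

#: The twenty standard amino acids, in the fixed code order used by the
#: simulator (index 0..19).
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

GAP: str = "-"
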