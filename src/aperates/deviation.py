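"""Deviation statistics: bootstrap RF Z-test and the multinomial branch test.

Two complementary tests ask whether a family's divergence departs from the
dataset-wide average:

**Branch-length-aware RF score.**  For a family with Poisson-corrected
branch lengths ``PC_b`` and the mean tree ``PCbar_b``, the score is the L1
distance ``z_i = sum_b |PC_b - PCbar_b|``.  Its sampling variance ``V`` is
estimated by bootstrap over the family's own alignment columns (B = 1000
replicates, mean tree held fixed — it is estimated from thousands of
families, so its own resampling variance is negligible), and
``Z = z_i / sqrt(V)`` is referred to a two-sided standard normal, with
Benjamini–Hochberg FDR across families.  A significant Z says the family
diverges at its own overall rate, without naming a branch.

**Multinomial branch test.**  Under a family-independent clock, the ``N``
branch-specific substitutions of a family fall on the five branches with
probabilities equal to the dataset-wide relative branch lengths.  For each
observed ``N``, the null distribution of per-branch counts is built from
``S = 100,000`` multinomial simulations (cached and reused across families
with the same ``N``).  Each branch gets an empirical two-tailed rank
p-value, doubling the smaller tail with the observed value included in
both tails (minimum attainable p is therefore ``1/S``); significance uses
the Bonferroni-adjusted fixed threshold ``alpha / 5 = 0.01``.

Because the test works on *shares* of N, inflating one branch necessarily
deflates the apparent share of every other branch: a strong acceleration
on one lineage can legitimately co-occur with "slower" calls elsewhere in
the same family.  That coupling is a property of the statistic, not an
artifact of the implementation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .phylo import BRANCHES
from .rates import MeanTree
from .sites import FamilyCounts
from .blocks import FilteredAlignment
from . import sites

__all__ = [
    "rf_score",
    "bootstrap_rf_variance",
    "BootstrapDegenerateError",
    "RFResult",
    "rf_z_test",
    "SimulationNull",
    "simulate_null",
    "NullCache",
    "BranchDeviation",
    "branch_deviation_test",
    "summarize_deviations",
]


def rf_score(pc: Mapping[str, float], mean_pc: Mapping[str, float]) -> float:
    """L1 distance between a family tree and a reference tree (branch-wise)."""
    return float(sum(abs(pc[b] - mean_pc[b]) for b in BRANCHES))


class BootstrapDegenerateError(RuntimeError):
    """More than 10% of bootstrap replicates had a saturated branch."""


def _group_counts(counts: FamilyCounts) -> np.ndarray:
    """Column-class counts: five branch-specific classes plus everything else."""
    branch = np.array([counts.n[b] for b in BRANCHES], dtype=np.int64)
    other = counts.L - branch.sum()
    return np.concatenate([branch, [other]])


def bootstrap_rf_variance(
    filtered: FilteredAlignment | FamilyCounts,
    mean: MeanTree,
    B: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap mean and variance of a family's RF score.

    Each replicate resamples the family's L alignment columns with
    replacement, re-derives the per-branch counts, recomputes the PC
    branch lengths and scores the replicate against the fixed mean tree.
    Since a column only enters the score through its branch class, the
    resampling is drawn directly as a multinomial over the six column
    classes, which is distribution-identical to resampling columns one by
    one.  Replicates in which a branch saturates (count = L, PC undefined)
    are discarded; more than 10% discarded aborts the family.

    Returns the replicate mean and the variance with the ``B - 1``
    denominator.
    """
    counts = filtered if isinstance(filtered, FamilyCounts) else sites.count_family(filtered)
    if counts.L < 1:
        raise ValueError(f"{counts.family_id}: cannot bootstrap an empty alignment")
    if B < 2:
        raise ValueError("need at least two bootstrap replicates")
    k = _group_counts(counts)
    L = counts.L
    rng = np.random.default_rng(np.random.SeedSequence([seed]))
    m = rng.multinomial(L, k / L, size=B)  # (B, 6)
    branch_counts = m[:, :5]
    ok = (branch_counts < L).all(axis=1)
    n_bad = int(B - ok.sum())
    if n_bad > 0.1 * B:
        raise BootstrapDegenerateError(
            f"{counts.family_id}: {n_bad}/{B} bootstrap replicates saturated"
        )
    bc = branch_counts[ok]
    pc = -np.log1p(-bc / L)  # (B_ok, 5)
    mean_vec = np.array([mean.pc[b] for b in BRANCHES])
    z = np.abs(pc - mean_vec).sum(axis=1)
    zbar = float(z.mean())
    # identical replicates are a true point mass: report exactly zero so
    # the degenerate-family rule in rf_z_test can fire
    v = 0.0 if np.all(z == z[0]) else float(z.var(ddof=1))
    return zbar, v


@dataclass
class RFResult:
    """RF Z-test outcome for one family."""

    family_id: str
    z: float  # observed RF score against the mean tree
    zbar: float  # bootstrap mean of the score
    V: float  # bootstrap variance (B - 1 denominator)
    Z: float = float("nan")
    p: float = float("nan")
    q: float = float("nan")
    untestable: bool = False


def rf_z_test(
    entries: Iterable[RFResult],
    fdr_alpha: float = 0.05,
) -> list[RFResult]:
    """Two-sided normal Z-test of RF scores with Benjamini–Hochberg FDR.

    ``Z = z / sqrt(V)``; families with ``V = 0`` get ``p = 1`` when their
    score is exactly zero (no departure, no noise) and are otherwise
    flagged untestable and excluded from the FDR ranking.
    """
    results = list(entries)
    testable: list[RFResult] = []
    for r in results:
        if r.V > 0:
            r.Z = r.z / np.sqrt(r.V)
            r.p = float(2.0 * stats.norm.sf(abs(r.Z)))
            testable.append(r)
        elif r.z == 0:
            r.Z, r.p = 0.0, 1.0
            testable.append(r)
        else:
            r.untestable = True
    if testable:
        reject, q, _, _ = multipletests(
            [r.p for r in testable], alpha=fdr_alpha, method="fdr_bh"
        )
        for r, qi in zip(testable, q):
            r.q = float(qi)
    return results


@dataclass
class SimulationNull:
    """Cached multinomial null for one value of N.

    ``marginals[b, k]`` is the number of the S replicates in which branch
    ``b`` received exactly ``k`` of the N events.
    """

    N: int
    S: int
    probs: np.ndarray
    marginals: np.ndarray  # (5, N + 1) int64

    def branch_pvalue(self, branch: str, n_obs: int) -> float:
        """Empirical two-tailed rank p: twice the smaller tail, capped at 1.

        The observed value is included in both tails and each tail is
        floored at one replicate, so the smallest attainable tail is
        ``1/S`` (two-tailed ``2/S``) — an observation can never be called
        impossible by a finite simulation.
        """
        bi = BRANCHES.index(branch)
        if not 0 <= n_obs <= self.N:
            raise ValueError(f"observed count {n_obs} outside [0, {self.N}]")
        cum = np.cumsum(self.marginals[bi])
        lower = max(int(cum[n_obs]), 1) / self.S
        upper = max(int(self.S - (cum[n_obs - 1] if n_obs > 0 else 0)), 1) / self.S
        return min(1.0, 2.0 * min(lower, upper))


def simulate_null(
    N: int,
    probs: Sequence[float] | Mapping[str, float],
    S: int = 100_000,
    seed: int = 0,
) -> SimulationNull:
    """Draw S multinomial replicates of N events over the five branches."""
    if N < 1:
        raise ValueError("null distribution requires N >= 1")
    if isinstance(probs, Mapping):
        p = np.array([probs[b] for b in BRANCHES], dtype=float)
    else:
        p = np.asarray(probs, dtype=float)
    if p.shape != (5,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probs must be five non-negative values summing to 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, N]))
    draws = rng.multinomial(N, p, size=S)
    marg = np.stack(
        [np.bincount(draws[:, b], minlength=N + 1) for b in range(5)]
    ).astype(np.int64)
    return SimulationNull(N=N, S=S, probs=p, marginals=marg)


class NullCache:
    """Per-N cache of multinomial nulls (probabilities fixed for a run)."""

    def __init__(self, probs, S: int = 100_000, seed: int = 0) -> None:
        if isinstance(probs, Mapping):
            probs = [probs[b] for b in BRANCHES]
        self.probs = np.asarray(probs, dtype=float)
        self.S = S
        self.seed = seed
        self._cache: dict[int, SimulationNull] = {}

    def get(self, N: int) -> SimulationNull:
        if N not in self._cache:
            self._cache[N] = simulate_null(N, self.probs, S=self.S, seed=self.seed)
        return self._cache[N]


@dataclass
class BranchDeviation:
    """Deviation-test outcome for one family and one branch."""

    family_id: str
    branch: str
    n_obs: int
    expected: float  # N * p_b under the multinomial null
    p: float
    direction: str  # faster | slower | none
    significant: bool


def branch_deviation_test(
    counts: FamilyCounts,
    null: NullCache | SimulationNull,
    alpha: float = 0.05,
    n_branches_tested: int = 5,
) -> list[BranchDeviation]:
    """Test each branch of a family against the multinomial null.

    Significance compares the empirical two-tailed p against the fixed
    Bonferroni-adjusted threshold ``alpha / n_branches_tested`` (0.01 at
    defaults).  A family with no substitutions has nothing to test: all
    five p-values are 1.
    """
    threshold = alpha / n_branches_tested
    N = counts.N
    out: list[BranchDeviation] = []
    if N == 0:
        for b in BRANCHES:
            out.append(BranchDeviation(counts.family_id, b, 0, 0.0, 1.0, "none", False))
        return out
    sim = null.get(N) if isinstance(null, NullCache) else null
    if sim.N != N:
        raise ValueError(f"null built for N={sim.N}, family has N={N}")
    for bi, b in enumerate(BRANCHES):
        n_obs = counts.n[b]
        expected = N * float(sim.probs[bi])
        p = sim.branch_pvalue(b, n_obs)
        if n_obs > expected:
            direction = "faster"
        elif n_obs < expected:
            direction = "slower"
        else:
            direction = "none"
        sig = p < threshold
        out.append(BranchDeviation(counts.family_id, b, n_obs, expected, p, direction, sig))
    return out


def summarize_deviations(results: Iterable[BranchDeviation]):
    """Tabulate significant families per branch and branch combination.

    Families significant on a single branch are counted under that branch
    (split into lower/higher than expected); families significant on
    several branches are reported as combination rows labelled with the
    branches and their directions.
    """
    import pandas as pd

    by_family: dict[str, list[BranchDeviation]] = {}
    for r in results:
        by_family.setdefault(r.family_id, []).append(r)
    single = {b: {"slower": 0, "faster": 0} for b in BRANCHES}
    combos: dict[tuple, int] = {}
    for fam, rows in by_family.items():
        sig = [r for r in rows if r.significant]
        if not sig:
            continue
        if len(sig) == 1:
            single[sig[0].branch][sig[0].direction] += 1
        else:
            key = tuple(sorted((r.branch, r.direction) for r in sig))
            combos[key] = combos.get(key, 0) + 1
    rows_out = []
    for b in BRANCHES:
        rows_out.append(
            {
                "branches": b,
                "lower_than_expected": single[b]["slower"],
                "higher_than_expected": single[b]["faster"],
                "mixed_direction": 0,
            }
        )
    for key, count in sorted(combos.items()):
        label = " + ".join(f"{b}({d})" for b, d in key)
        directions = {d for _, d in key}
        row = {
            "branches": label,
            "lower_than_expected": 0,
            "higher_than_expected": 0,
            "mixed_direction": 0,
        }
        if directions == {"faster"}:
            row["higher_than_expected"] = count
        elif directions == {"slower"}:
            row["lower_than_expected"] = count
        else:
            row["mixed_direction"] = count
        rows_out.append(row)
    return pd.DataFrame(rows_out)
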