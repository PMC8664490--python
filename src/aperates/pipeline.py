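"""End-to-end orchestration and report tables.

The pipeline runs the stages in order — (optional orthology) ->
block filtering -> site classification -> branch rates -> deviation
tests -> reports — over either a synthetic dataset (the default test
surface) or a directory of per-family four-sequence alignments, and
emits one TSV per report.  Every family entering a stage either appears
in that stage's output or in the attrition log, and a fixed seed
reproduces the whole output tree byte for byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import deviation as dev
from . import rates as rates_mod
from .blocks import FamilyMSA, FilteredAlignment, filter_blocks
from .phylo import BRANCHES, DEFAULT_BRANCH_TIMES_MYA, TIPS
from .rates import MeanTree, family_tree, mean_tree
from .simulate import SimulationConfig, generate_dataset
from .sites import FamilyCounts, SiteCategory, count_family

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "run_pipeline",
    "rank_candidates",
    "load_alignments",
    "write_family_fasta",
]


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run."""

    mode: str = "synthetic"  # synthetic | real
    sim: SimulationConfig | None = None
    alignments_dir: str | Path | None = None
    outdir: str | Path | None = None
    branch_times_mya: dict = field(
        default_factory=lambda: dict(DEFAULT_BRANCH_TIMES_MYA)
    )
    min_block: int = 10
    max_nonconserved_run: int = 2
    bootstrap_reps: int = 1000
    sim_reps: int = 100_000
    alpha: float = 0.05
    branches_tested: int = 5
    fdr_alpha: float = 0.05
    top_k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ValueError("mode must be 'synthetic' or 'real'")
        if self.mode == "synthetic" and self.sim is None:
            self.sim = SimulationConfig(seed=self.seed)
        if self.mode == "real" and self.alignments_dir is None:
            raise ValueError("real mode requires alignments_dir")


@dataclass
class PipelineResult:
    alignment_stats: pd.DataFrame
    site_counts: pd.DataFrame
    branch_stats: pd.DataFrame
    mean_tree: MeanTree | None
    family_trees: pd.DataFrame
    rf_tests: pd.DataFrame
    deviation_tests: pd.DataFrame
    deviation_summary: pd.DataFrame
    candidates_faster: pd.DataFrame
    candidates_slower: pd.DataFrame
    attrition: pd.DataFrame
    counts: list[FamilyCounts]


def load_alignments(directory: str | Path) -> list[FamilyMSA]:
    """Read per-family aligned FASTA files (record ids ``species|gene``)."""
    from Bio import SeqIO

    msas = []
    for path in sorted(Path(directory).glob("*.fa*")):
        rows: dict[str, str] = {}
        gene_ids: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            species, _, gene = rec.id.partition("|")
            rows[species] = str(rec.seq).upper()
            gene_ids[species] = gene
        missing = set(TIPS) - set(rows)
        if missing:
            raise ValueError(f"{path}: missing species {sorted(missing)}")
        msas.append(
            FamilyMSA(
                sequences=tuple(rows[sp] for sp in TIPS),
                species=TIPS,
                family_id=path.stem,
            )
        )
    return msas


def write_family_fasta(msa: FamilyMSA, path: str | Path, gene_ids=None) -> None:
    with open(path, "w") as fh:
        for sp, seq in zip(msa.species, msa.sequences):
            gene = (gene_ids or {}).get(sp, msa.family_id)
            fh.write(f">{sp}|{gene}\n{seq}\n")


def _alignment_stats_row(fa: FilteredAlignment) -> dict:
    spans = ";".join(f"{a}-{b}" for a, b in fa.block_spans)
    return {
        "family_id": fa.family_id,
        "L": fa.L,
        "shortest_len": fa.shortest_len,
        "saturation": fa.saturation,
        "n_blocks": len(fa.block_spans),
        "block_spans": spans,
    }


def _site_counts_row(fc: FamilyCounts) -> dict:
    row = {"family_id": fc.family_id, "L": fc.L}
    for b in BRANCHES:
        row[f"n_{b}"] = fc.n[b]
    row["N"] = fc.N
    for cat in (
        SiteCategory.IDENTICAL,
        SiteCategory.INCONSISTENT_2STATE,
        SiteCategory.CONSISTENT_3STATE,
        SiteCategory.INCONSISTENT_3STATE,
        SiteCategory.NO_IDENTITY,
    ):
        row[cat.value] = fc.category_counts.get(cat, 0)
    return row


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; write TSVs when ``config.outdir`` is set."""
    if config.mode == "synthetic":
        msas = [fam.msa for fam, _ in generate_dataset(config.sim)]
    else:
        msas = load_alignments(config.alignments_dir)

    attrition: list[dict] = []
    filtered: list[FilteredAlignment] = []
    for msa in msas:
        fa = filter_blocks(msa, config.min_block, config.max_nonconserved_run)
        if fa.non_overlapping:
            attrition.append(
                {
                    "family_id": fa.family_id,
                    "stage": "filter",
                    "reason": "no alignment overlap after block filtering",
                }
            )
        else:
            filtered.append(fa)

    counts = [count_family(fa) for fa in filtered]
    stats_df = pd.DataFrame([_alignment_stats_row(fa) for fa in filtered])
    counts_df = pd.DataFrame([_site_counts_row(fc) for fc in counts])

    hyper = counts_df[counts_df.get("no_identity", pd.Series(dtype=int)) > 1]
    if len(hyper):
        logger.warning(
            "%d families contain more than one no-identity column — "
            "possible alignment problems: %s",
            len(hyper),
            ", ".join(hyper.family_id),
        )

    totals = {b: int(sum(fc.n[b] for fc in counts)) for b in BRANCHES}
    L_total = int(sum(fc.L for fc in counts))
    all_zero = sum(totals.values()) == 0

    trees_rows: list[dict] = []
    rf_df = pd.DataFrame()
    dev_df = pd.DataFrame()
    summary_df = pd.DataFrame()
    cand_fast = pd.DataFrame()
    cand_slow = pd.DataFrame()
    mt: MeanTree | None = None

    if all_zero:
        branch_df = pd.DataFrame(
            {
                "branch": list(BRANCHES),
                "time_mya": [config.branch_times_mya[b] for b in BRANCHES],
                "total_subs": 0,
            }
        )
        logger.info("no substitutions anywhere: rate tables and tests skipped")
    else:
        testable: list[FamilyCounts] = []
        for fc in counts:
            if any(fc.n[b] == fc.L for b in BRANCHES):
                attrition.append(
                    {
                        "family_id": fc.family_id,
                        "stage": "rates",
                        "reason": "saturated branch (all sites substituted)",
                    }
                )
            else:
                testable.append(fc)
        mt = mean_tree(testable)
        branch_df = rates_mod.branch_stats_table(
            totals, L_total, config.branch_times_mya, mean=mt
        )

        # Per-family trees + RF bootstrap Z-test (substituted families only).
        rf_entries: list[dev.RFResult] = []
        seed_root = np.random.SeedSequence([config.seed, 104729])
        for i, fc in enumerate(testable):
            tree = family_tree(fc)
            trees_rows.append(
                {
                    "family_id": fc.family_id,
                    **{f"pc_{b}": tree[b] for b in BRANCHES},
                    "tree_length": sum(tree.values()),
                }
            )
            if fc.N == 0:
                continue
            z = dev.rf_score(tree, mt.pc)
            try:
                zbar, v = dev.bootstrap_rf_variance(
                    fc, mt, B=config.bootstrap_reps, seed=int(config.seed * 1_000_003 + i)
                )
            except dev.BootstrapDegenerateError as exc:
                attrition.append(
                    {"family_id": fc.family_id, "stage": "rf_test", "reason": str(exc)}
                )
                continue
            rf_entries.append(dev.RFResult(fc.family_id, z, zbar, v))
        rf_results = dev.rf_z_test(rf_entries, fdr_alpha=config.fdr_alpha)
        rf_df = pd.DataFrame(
            [
                {
                    "family_id": r.family_id,
                    "rf_score": r.z,
                    "bootstrap_mean": r.zbar,
                    "bootstrap_var": r.V,
                    "Z": r.Z,
                    "p": r.p,
                    "q": r.q,
                    "untestable": r.untestable,
                    "stratum": (
                        "untestable"
                        if r.untestable
                        else ("significant" if r.q < config.fdr_alpha else "ns")
                    ),
                }
                for r in rf_results
            ]
        )

        # Multinomial branch deviation test.
        probs = rates_mod.relative_branch_lengths(totals)
        cache = dev.NullCache(probs, S=config.sim_reps, seed=config.seed)
        dev_rows: list[dev.BranchDeviation] = []
        for fc in testable:
            dev_rows.extend(
                dev.branch_deviation_test(
                    fc, cache, alpha=config.alpha, n_branches_tested=config.branches_tested
                )
            )
        dev_df = pd.DataFrame(
            [
                {
                    "family_id": r.family_id,
                    "branch": r.branch,
                    "n_obs": r.n_obs,
                    "expected": r.expected,
                    "p": r.p,
                    "direction": r.direction,
                    "significant": r.significant,
                }
                for r in dev_rows
            ]
        )
        summary_df = dev.summarize_deviations(dev_rows)
        cand_fast = rank_candidates(dev_df, stats_df, rf_df, config.top_k, "faster")
        cand_slow = rank_candidates(dev_df, stats_df, rf_df, config.top_k, "slower")

    trees_df = pd.DataFrame(trees_rows)
    attr_df = pd.DataFrame(attrition, columns=["family_id", "stage", "reason"])
    result = PipelineResult(
        alignment_stats=stats_df,
        site_counts=counts_df,
        branch_stats=branch_df,
        mean_tree=mt,
        family_trees=trees_df,
        rf_tests=rf_df,
        deviation_tests=dev_df,
        deviation_summary=summary_df,
        candidates_faster=cand_fast,
        candidates_slower=cand_slow,
        attrition=attr_df,
        counts=counts,
    )
    if config.outdir is not None:
        _write_outputs(result, Path(config.outdir))
    return result


def rank_candidates(
    dev_df: pd.DataFrame,
    stats_df: pd.DataFrame,
    rf_df: pd.DataFrame,
    top_k: int = 5,
    direction: str = "faster",
) -> pd.DataFrame:
    """Top candidates per branch among significantly deviating families.

    Faster lists are sorted by branch-specific % substitutions per site,
    highest first; slower lists lowest first.  A free-text ``comment``
    column is emitted for downstream manual curation.
    """
    if direction not in ("faster", "slower"):
        raise ValueError("direction must be 'faster' or 'slower'")
    if dev_df.empty:
        return pd.DataFrame(
            columns=[
                "branch",
                "family_id",
                "branch_pct_per_site",
                "L",
                "saturation",
                "deviation_p",
                "rf_q",
                "comment",
            ]
        )
    sig = dev_df[(dev_df.significant) & (dev_df.direction == direction)].copy()
    meta = stats_df.set_index("family_id")
    rfq = (
        rf_df.set_index("family_id")["q"] if not rf_df.empty else pd.Series(dtype=float)
    )
    rows = []
    for r in sig.itertuples():
        L = int(meta.loc[r.family_id, "L"])
        rows.append(
            {
                "branch": r.branch,
                "family_id": r.family_id,
                "branch_pct_per_site": round(100.0 * r.n_obs / L, 2),
                "L": L,
                "saturation": meta.loc[r.family_id, "saturation"],
                "deviation_p": r.p,
                "rf_q": float(rfq.get(r.family_id, np.nan)),
                "comment": "",
            }
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    ascending = direction == "slower"
    out = (
        out.sort_values(
            ["branch", "branch_pct_per_site", "family_id"],
            ascending=[True, ascending, True],
        )
        .groupby("branch", group_keys=False)
        .head(top_k)
        .reset_index(drop=True)
    )
    return out


_OUTPUT_FILES = {
    "alignment_stats": "alignment_stats.tsv",
    "site_counts": "site_counts.tsv",
    "branch_stats": "branch_stats.tsv",
    "family_trees": "family_trees.tsv",
    "rf_tests": "rf_tests.tsv",
    "deviation_tests": "deviation_tests.tsv",
    "deviation_summary": "deviation_summary.tsv",
    "candidates_faster": "candidates_faster.tsv",
    "candidates_slower": "candidates_slower.tsv",
    "attrition": "attrition.tsv",
}


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _OUTPUT_FILES.items():
        df: pd.DataFrame = getattr(result, attr)
        df.to_csv(outdir / fname, sep="\t", index=False)
    if result.mean_tree is not None:
        mt = result.mean_tree
        pd.DataFrame(
            [
                {"branch": b, "mean_pc": mt.pc[b]}
                for b in BRANCHES
            ]
            + [
                {"branch": "_families_used", "mean_pc": mt.n_families_used},
                {"branch": "_zero_substitution_families", "mean_pc": mt.n_zero_excluded},
            ]
        ).to_csv(outdir / "mean_tree.tsv", sep="\t", index=False)
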