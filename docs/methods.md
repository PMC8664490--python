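# Methods

## Scope and model

`aperates` measures lineage-specific departures from clock-like protein
evolution on the fixed quartet `((human, chimp), gorilla, gibbon)`.
Topology is never inferred; the only free quantities are per-branch
substitution counts and the statistics built from them. Without an
outgroup the internal branch subtending human+chimp+gorilla cannot be
polarised, so it is folded into the gibbon branch throughout — in the
simulator, in the site classifier and in all rate tables. "Gibbon branch"
therefore always means gibbon terminal plus that stem.

All inference is identity-based: a substitution is a residue difference,
never weighted by exchangeability. That choice keeps the per-site
statistics model-free and is the reason the alignment filter is so
strict — every retained column must be confidently homologous in all
four sequences.

## Ortholog calling

Collinear blocks are chains of homology anchors advancing monotonically
in both genomes, one orientation per chain, with at most `max_gap = 2`
skipped genes between consecutive anchors and at least `min_genes = 3`
anchors per chain. Chains are extracted iteratively: best chain first
(longest; ties by smallest total rank slack, then forward orientation,
then leftmost start), anchors consumed exclusively. The exclusive-greedy
extraction was a genuinely open design point: allowing anchors in every
admissible chain produces "hop" chains that bridge across short inverted
segments within the gap tolerance, which block-overlap resolution cannot
repair; consuming anchors longest-chain-first removes those while leaving
genuine multi-block membership (through duplicate hits) intact.

Candidate pairs then pass four rules in order: retain at global-alignment
identity ≥ 95% (Needleman–Wunsch with BLOSUM62, gap open 10, extend 0.5,
identity = identical positions / alignment length; the denominator is
configurable); otherwise drop when either gene has a strictly
higher-bitscore hit elsewhere (ties do not drop — the conservative
reading of "better"); a gene in two blocks keeps the pair in the larger
block, size ties keeping the first-encountered block and flagging the
pair; pairs touching a tandem duplicate (one query hitting two
same-chromosome genes within one rank) are dropped. Families are the
intersection of the three human-vs-X 1:1 lists on the human gene id.

## Alignment block filter

With four sequences and "all sequences must agree" as the conservation
rule, the filter reduces to: remove every gap column; remove maximal runs
of more than 2 consecutive non-conserved columns (three contiguous
differences at these divergences are more plausibly an indel or
misalignment than independent substitutions); split at removed columns;
trim block margins back to conserved columns; discard blocks shorter
than 10. The surviving concatenation is gap-free, has no non-conserved
run longer than 2, and its length L ≤ length of the shortest ortholog.
Saturation (`100·L/shortest`) measures how much of the shortest ortholog
survived. Families with L = 0 are excluded from all statistics (logged in
the attrition table); families with small positive L are retained.
Whether a non-conserved column adjacent to a removed gap column survives
exactly as in other block filters cannot be pinned down in general;
here such columns always sit at a block margin and are trimmed, which is
the strict choice. Kept columns are 0-based half-open in machine output.

## Site classification

Every gap-free column falls in exactly one of seven categories (see
`aperates.sites`); only single-event-explicable columns — one taxon
differing (terminal branches), or human=chimp vs gorilla=gibbon
(internal) — contribute to `n_b`. Three-state columns whose identical
pair is a clade are parsimony-consistent yet require two events, so they
are *excluded* from branch counts; this exclusion is what makes the
"branch-specific" totals internally consistent with the category
decomposition. Columns with four distinct residues need ≥ 3 independent
events; their expectation under independence is `r1·r2·r3·L`, and
families containing more than one such column are flagged as a
data-quality warning (never an error).

## Rates, trees, deviation tests

Poisson correction `PC = −ln(1 − n/L)` is the standard multiple-hit
correction; it is undefined at `n = L` and such families are excluded
with a logged saturation error rather than clamped (unreachable at these
divergences in practice). The mean tree averages `PC_b` over families
with ≥ 1 substitution.

**RF Z-test.** The family score is the L1 distance to the mean tree. Its
variance is estimated from B = 1000 bootstrap replicates of the family's
own columns; because a column enters the score only through its branch
class, resampling is drawn as a multinomial over the six column classes —
distribution-identical to per-column resampling and much cheaper. The
mean tree is held fixed across replicates (it is estimated from the full
family set; its resampling variance is negligible next to a single
family's). Replicates with a saturated branch are discarded; > 10%
discarded aborts the family as untestable. The test is two-sided
(`Z = z/√V`, normal reference), with Benjamini–Hochberg FDR across
families. Degenerate families (V = 0) get p = 1 when their score is 0 and
are otherwise flagged untestable rather than given p = 0. The per-family
bootstrap (rather than resampling a concatenated all-family alignment) is
a deliberate reading of an ambiguous convention; the alternative is noted
but not implemented.

**Multinomial branch test.** Under the family-independent clock, the N
branch-specific events of a family are multinomial over the five branches
with the dataset-wide relative branch lengths as probabilities. The null
for each observed N is built once from S = 100,000 draws and cached
(probabilities are fixed per run, so the cache key is N alone). The
two-tailed rank p doubles the smaller empirical tail with the observed
value included in both tails; each tail is floored at one replicate, so
the smallest attainable p is 2/S. Significance is the fixed comparison
p < α/5 = 0.01 (threshold form of Bonferroni, not p-value inflation).

Because the test works on shares of N, inflating one branch necessarily
deflates the apparent share of every other branch: families with a strong
acceleration on one lineage can legitimately receive "slower" calls
elsewhere, increasingly so at large N. This coupling is a property of the
statistic — mixed faster/slower combinations within a family are expected
output, not errors — and recovery guarantees are therefore stated for
same-direction (faster) mis-attribution, which stays at the null level.

## Synthetic data

The generator *is* the study condition set. Defaults: per-site branch
event probabilities (0.0027, 0.0026, 0.0009, 0.0036, 0.0134) for
(human, chimp, internal, gorilla, gibbon) — the genome-wide aggregate
calibration, with branch times (6.65, 6.65, 2.41, 9.06, 31.24) Mya from
timetree; ancestral lengths uniform on 200–800 residues (the genome-wide
mean aligned length is ≈ 580 sites); per-family gamma rate multipliers
with mean 1 and shape 2 (coefficient of variation ≈ 0.7, broad enough
that the RF test has real heterogeneity to detect); episodic shifts off
by default, and when enabled a 10× fold on one designated branch for a
flagged fraction of families; indel runs started per column with
probability 0.005 in one random species, geometric length with mean 3
(exercises the gap filter without dominating attrition).

Events are drawn independently per column and branch; an internal-branch
event mutates the human+chimp ancestor so both tips inherit it;
replacements are uniform over the 19 alternative residues (identity-based
statistics are insensitive to exchangeability structure). Multiple hits
on one column arise naturally and produce the discordant/no-identity
categories; there is no separate homoplasy control. Per-family RNG
streams are derived from the master seed, giving bit-identical datasets
and enabling paired flagged/unflagged comparisons. The ground truth
records every event, the gap mask, the multiplier and the episodic flag.

What the generator does *not* emulate: among-site rate variation,
correlated substitutions, selection, alignment error (alignments are
correct by construction — real MSA software can misalign around indels),
incomplete lineage sorting as a coalescent process (discordant patterns
arise only through multiple hits, at much lower frequency than ILS
produces in real ape data). Passing tests therefore certify the
statistical machinery and its error control under the stated generative
model, not robustness to alignment or coalescent artifacts.

Toy genomes for the orthology stage plant inversions of 6–8 genes —
long enough that a forward chain cannot hop across within the gap
tolerance, making every planted feature unambiguously recoverable —
plus tandem (adjacent) and dispersed duplicate copies with weaker
homology hits.

## Numerical and testing choices

Internal computation is full precision; report tables round to the
conventional display precision (relative lengths 4 d.p., percentages
2 d.p., per-Mya and mean-tree PC 3 d.p.). Statistical assertions in the
test suite use explicitly derived Monte-Carlo tolerances (3 SE bands from
binomial/multinomial or delta-method variances); grid-wide comparisons
use the simultaneous form (≥ 99% of points within 3 SE, all within a
6-SE multiplicity cap). Dataset-level checks run at 2,000 families of
500 residues, the smallest size at which the short internal branch
(~0.04% of sites per Mya-unit) accumulates enough events for the fixed
acceptance bands. All stochastic components are seeded; fixed seeds
reproduce outputs byte for byte.

## Known limitations

- The collinear-chain caller is a deterministic reconstruction of the
  two parameters that matter (`min_genes`, `max_gap`); it does not score
  chains by e-value and will not reproduce any particular external
  synteny tool's block boundaries gene for gene.
- Rate estimates ignore among-site rate variation; the Poisson
  correction handles multiple hits per site only marginally.
- The multinomial test conditions on N, so it cannot separate "faster on
  branch b" from "slower everywhere else"; directionality of mixed calls
  needs the RF test and the raw counts alongside.
- Real-data mode consumes externally produced alignments and homology
  hits; producing them (aligners, BLAST) is out of scope.
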