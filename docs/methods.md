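# Methods

This note documents the models behind `mirpipe`, the parameter choices that
matter, what the synthetic-data generator does and does not emulate, and the
numerical decisions taken where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## The experimental design being modelled

The pipeline targets the classic two-library small RNA-seq comparison: RNA
from several animals pooled into one library per condition, sequenced
deeply, with no biological replicates. In that design, differential
expression cannot be assessed with dispersion-modelling frameworks (negative
binomial GLMs need replicates); instead, each miRNA's counts x and y in the
two libraries are compared against the library totals N1 and N2 with exact
count statistics. That is the regime every default in this package is
chosen for. Multi-condition designs and replicate-aware testing are out of
scope by construction.

## Read processing

Reads are insert + 3' adapter (+ downstream bases), so the insert is
recovered by locating the left-most adapter occurrence. A match at position
i must extend over `min(len(adapter), len(read) - i)` bases — i.e. interior
matches require the full adapter, while at the 3' end a prefix of at least
`min_adapter_overlap` (default 6) bases suffices. Reads with no match are
discarded: their insert exceeds the read length and cannot be sized. Reads
whose match is at position 0 have an empty insert and are likewise
discarded.

The filter cascade applies three per-tag predicates in order: length
(14–27 nt), composition, copy number. Two readings of the composition rule
are possible; we use "no single nucleotide accounts for ≥ 80% of the read"
(the alternative — total ACGT share below 80% — would discard nearly every
read). N bases are governed solely by the `max_n` ≤ 2 rule and never count
toward the single-base fraction. The copy-number rule (> 3 reads) is
applied to the combined count across both libraries by default: filtering
per library would silently delete library-specific tags, which are exactly
the objects the library-sharing partition counts later. A
`copy_filter_scope="per-library"` option applies the threshold to each
library separately instead. Because all three predicates are per-tag and
independent, the final tag set does not depend on their order (tested by
permuting them); only the per-stage accounting does.

Contaminant removal emulates a BLAST screen against rRNA/tRNA/snRNA/snoRNA/
repeat references with an internal matcher: ungapped placement of the full
tag with at most one mismatch, both strands for repeats, forward strand only
for structural RNAs (their reads are single-stranded transcripts; repeats
occur on both strands genomically).

## Classification hierarchy

Tags are assigned by the first matching branch: (1) hit on a known-tier
precursor; (2) hit on a conserved-tier precursor that itself occurs in the
genome; (3) genome-only tags longer than 18 nt, clustered by single linkage
(gap ≤ 10 nt, same contig and strand) into loci of at most 30 nt, each
extended by 60 nt of genomic flank per side and folded. The 18-nt floor
mirrors the practice of excluding short, multi-mapping reads from novel
miRNA prediction. Alignment is ungapped full-length matching with at most
one mismatch (configurable); an N in a tag mismatches everything. Ties
among equally good hits resolve deterministically (fewest mismatches, then
reference name, then coordinate). The mismatch tolerance and cluster gap
are not dictated by the procedure being reproduced; both are exposed as
configuration with the stated defaults.

## Hairpin folding and acceptance

Thermodynamic folding is replaced by weighted base-pair maximisation
(Nussinov dynamic programming) with GC=3, AU=2, GU=1 and a minimum loop of
3 — deterministic, dependency-free, and exhaustively testable: the suite
verifies DP optimality against brute-force enumeration over all nested
pairings for hundreds of short sequences, and validity (involution, no
crossings, minimum loop) is asserted on every fold object constructed. The
traceback is deterministic: for each subproblem the rightmost base takes
the admissible partner with the smallest left index, which extends helices
inward; a `folder` hook lets an external MFE folder be plugged in for
comparison.

A candidate locus is accepted as a precursor when its fold passes five
rules: (a) the mature cluster lies entirely on one arm of the dominant stem
(the hairpin loop enclosed by the most pairs); (b) at least 60% of mature
bases pair into the opposite arm; (c) at least `min_helix_run` = 6 of those
pairs are consecutively stacked Watson–Crick pairs; (d) the terminal loop
spans 3–25 nt; (e) the fold score reaches `score_min` = 40 (for ~140-nt
candidates). Rule (c) deserves comment: random ~140-mers fold to high
Nussinov scores (typically ≈ 125, making (e) non-discriminating on its
own), but their pairs scatter; the signature of a real precursor is a long
uninterrupted helix. A 22-nt mature with at most 2 mismatched positions
always retains a stacked run of at least ⌈20/3⌉ = 7, so the threshold of 6
can never reject a constructed precursor, while random candidates pass all
five rules at well under 5% (measured in the test suite). All five
thresholds are configuration, since hairpin acceptance criteria are a
design choice rather than a published rule.

## isomiR consolidation

Tags from one precursor arm form an isomiR class. The class reference is
the member with the highest combined count; ties go to the longer sequence,
then the lexicographically smaller (the published procedure picks "the most
abundant" without a tie rule, so determinism is imposed here). Class counts
sum over members by default (`count_mode="reference"` restricts counting to
the reference tag). Records whose reference sequences are identical —
distinct precursors encoding the same mature — are additionally collapsed
into a unique-sequence view; both views are emitted. Within a multi-arm
precursor the minor arm is flagged as the star (miRNA*) product.

## Differential expression

The Audic–Claverie conditional distribution p(y | x) with ratio r = N2/N1
is the negative binomial with x+1 successes and success probability
N1/(N1+N2); it is evaluated through the scipy negative-binomial cdf/sf
(regularised incomplete beta, log-space internally), which is stable for
counts up to 10⁷. The two-sided p doubles the smaller tail and caps at 1,
matching common IDEG6 usage; one-sided tails are available via `sided`. The
chi-squared test omits the Yates correction by default — tested counts
exceed 1000 after the abundance filter, where the correction is negligible —
with a flag to enable it. Fisher's test is two-sided by the standard
"sum of tables no more probable than observed" rule.

N1/N2 default to the totals of classified miRNA counts per library, not raw
read totals: the tests compare relative miRNA abundance, and non-miRNA
reads would otherwise dilute both proportions. Raw totals can be supplied
explicitly.

Bonferroni correction uses m = the number of abundance-filtered miRNAs,
applied to each of the three tests separately (the correction is across
miRNAs, not across tests); the abundance filter retains miRNAs with
strictly more than `abundance_min` = 1000 reads in either library. A miRNA
is DE only when all three adjusted p-values fall below α = 0.001 — the
consensus is therefore conservative: its call set is a subset of any single
test's calls at the same threshold (property-tested). An `adjust=False`
mode reproduces raw-p calling for comparison, since whether the original
IDEG6 runs corrected p-values or thresholds is not documented.

Reported percentages round half-up to two decimals, matching how such
tables are conventionally printed.

## The synthetic-data generator

`simdata` emulates the study, not just its file formats. Precursors are
built as `arm + loop + revcomp(arm)` (arm = 4-nt pad + mature + 4-nt pad,
loop 8–15 nt) with 0–2 mismatches injected into the 3' arm, so every locus
is a true hairpin by construction and classification truth is analytic.
Mature lengths are N(22, 0.8) rounded and clipped to 20–24 nt. Known and
conserved precursors are embedded verbatim on the + strand (so tier
membership is verifiable by substring search); novel loci are embedded on a
random strand and appear in no precursor FASTA. Conserved precursors use a
distinct name prefix so tier membership is testable by name and by set.

Reads are drawn per library: a source (miRNA / contaminant / junk) with
probabilities (0.85, 0.10, 0.05 by default), then for miRNA reads a locus
(proportional to per-library weights) and independent 5'/3' isomiR offsets
from `isomir_template_shifts` (default mass 0.8 at offset 0, the rest on
±1/±2). Contaminant reads are drawn from a small pool of "expressed
fragments" per contaminant record (8 windows of 18–26 nt), mimicking the
specific degradation fragments real libraries contain — and giving them
enough copy number to reach the contaminant-removal stage rather than dying
at the copy filter. Junk reads are unique random sequences of 10–34 nt and
are eliminated by the length and copy-number rules. Each insert gets the 3'
adapter appended, random padding, and truncation to the 40-nt machine read
length, with uniform maximal base quality (the filters modelled are
sequence-based only). Per-locus baseline abundance is log-normal with
σ = 1.

Differential loci (fraction `de_fraction` = 0.3) have their library-A
weight multiplied and library-B weight divided by √de_fold (or the
reverse), giving an expected A:B ratio of `de_fold` = 8. Directions are
assigned by greedy mass balancing — heaviest DE locus first, to the
currently lighter side — rather than independent coin flips. This keeps the
two libraries' totals nearly equal, which matters: the count tests compare
proportions x/N1 vs y/N2, and an imbalanced total would shift every non-DE
miRNA's proportion by a common, easily detectable factor, making the
simulation's "non-DE" labels false on the proportion scale that the tests
actually measure.

The genome background is random DNA with one constraint: a 6-mer and its
reverse complement never co-occur within 160 nt (including against the
k-mers of an upcoming embedded precursor). A helix of 6 stacked
Watson–Crick pairs requires exactly such a co-occurrence, so no hairpin
candidate drawn from background can satisfy acceptance rule (c): "the
genome contains no hairpin locus outside the embedded precursors" holds by
construction, deterministically, and the test suite verifies it by
exhaustive scan. Only ~4% of background bases are resampled, leaving
composition and mappability essentially uniform.

### What the generator does not emulate

- **Dynamic range.** Real libraries span counts from 3 to millions with
  most miRNAs in low abundance; the σ = 1 log-normal keeps every simulated
  locus comfortably detectable. Consequently nearly all simulated miRNAs
  are shared between libraries (the library-specific partition is
  near-degenerate at 100% shared), and recovery results say nothing about
  sensitivity to miRNAs near the detection floor.
- **Length distribution sharpness.** Real libraries concentrate ~60% of
  reads at exactly 22 nt; the simulated distribution has its mode at 22 nt
  but is broader (~40% at the mode), because mature-length variation and
  isomiR offsets are sampled independently.
- **Sequencing error and quality.** Substitution error is available
  (`substitution_rate`) but off by default; quality strings are uniform.
- **Replicates.** One pooled library per condition, matching the design
  being modelled; replicate structure is deliberately not simulated.

Passing recovery tests therefore demonstrate correctness of the procedure
under clean, well-powered conditions — not robustness to the noise floor of
real data.

## qPCR module

qBase-style normalization computes, per gene g and sample s, the relative
quantity Q = E_g^(Ct_min,g − Ct_s,g) with the per-gene minimum Ct (highest
expression) as calibrator and E the amplification efficiency in (1, 2]
(default 2.0); each sample's normalization factor is the geometric mean of
its reference-gene Q values, and normalized quantities are Q/NF. Adding a
constant to one reference gene's Ct across all samples provably leaves all
normalized quantities unchanged (property-tested). The classic ΔΔCt fold
change (ΔCt against the mean reference-gene Ct, E = 2, fold = 2^−ΔΔCt)
agrees exactly with the qBase route in the single-reference, E = 2 case,
which the suite asserts. Cross-platform agreement between sequencing and
qPCR fold changes is computed as Pearson correlation on the log2 scale
(fold changes are ratios; correlating them linearly would let a single
large fold change dominate).

## Target-list consensus

"Pairwise overlaps of three predictors" is implemented as the union of
pairwise intersections — genes supported by at least two of the three
programs — with `mode="all-three"` for the stricter triple intersection,
since the phrase admits either reading.

## Problem sizes

The acceptance script runs five seeds of the default conditions: two
libraries × 100,000 reads over 50 loci (20 known, 10 conserved, 20 novel)
in a 60-kb genome, chosen as the smallest configuration in which every
stage operates in its intended regime (thousands of reads per locus,
meaningful contaminant/junk admixture, all three tiers populated). The
folding-optimality check uses 500 random sequences of length ≤ 12, where
exhaustive enumeration of nested pairings is tractable; the null
calibration check uses 10⁵ Poisson(100) pairs.

## Known limitations

- Nussinov scoring is not thermodynamics: scores rank pairings, not free
  energies, and the acceptance thresholds are calibrated for ~140-nt
  candidates only.
- The internal matcher is ungapped; indel isomiRs and gapped contaminant
  matches are invisible to it.
- Multi-mapping tags are assigned to their single best alignment
  (deterministic tie-break) rather than fractionally.
- The Bonferroni-consensus caller is conservative by design; it inherits
  the single-replicate design's inability to separate biological from
  library variation.
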