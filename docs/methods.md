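# Methods

`gonomir` re-implements a pooled-library small-RNA gonad analysis as a tested
pipeline: three sequencing libraries (XX ovary, XY testis, YY super-male
testis), each a single pool with no biological replicates, are preprocessed,
annotated by a sequential cascade, and compared pairwise with count-based
exact tests. Because the pipeline is exercised on synthetic data, this note
describes both the analysis model and what the simulator does and does not
emulate.

## The simulator (`simlib`)

`generate_reference` builds a toy reference bundle: a single random
chromosome hosting one near-palindromic stem-loop precursor per miRNA
(5' arm of 3-nt pads around a 22-23 nt mature, an 8-nt loop, and the
reverse-complement arm carrying at most 2 engineered substitutions, ~66 nt
total), plus random housekeeping ncRNA references (rRNA 120 nt, tRNA 76 nt,
snRNA 110 nt, snoRNA 90 nt), mRNA fragments (200 nt), repeats (150 nt) and
piRNAs (26-31 nt, length-weighted toward the 26-28 nt PIWI-bound mode).
Precursors are placed without overlap; a genome too short to host them raises
a capacity error.

`simulate_library` draws per-category read counts multinomially from the
mixture fractions (defaults: miRNA 0.35, piRNA 0.25, rRNA 0.08, tRNA 0.08,
snRNA 0.04, snoRNA 0.04, mRNA 0.05, repeat 0.05, random 0.06; an optional
gamma perturbation adds overdispersion). miRNA abundances follow a Zipf
(1/rank) baseline unless given; differential entries multiply a miRNA's
weight by 2^log2FC in the high group, and group-exclusive species are zeroed
elsewhere. Reads are written at a fixed machine length of 40 nt: insert, then
the TruSeq small-RNA 3' adapter filling the remainder, with uniform
substitution errors (default 0.001/base) and 2% junk reads (random sequence
at Phred 2). The 40-nt read length is chosen so that even the longest (31 nt)
piRNA insert leaves at least 6 nt of adapter, the trimmer's minimum overlap —
at 36 nt the longest piRNAs would be untrimmable and lost to the length
filter as an artefact of the read geometry rather than of the biology.
One RNG stream per (seed, group) makes every library byte-reproducible.

What the simulator does not model: ligation bias, PCR duplication, RNA
modifications, isomiR heterogeneity, inter-individual variance (the pooled
design has none), and realistic sequence composition (references are i.i.d.
uniform). Passing tests therefore demonstrate the pipeline's correctness
under its stated model, not performance on real libraries — in particular,
the distinct-sequence length histogram of real data shows the Dicer/piRNA
bimodality, while with only ~50 simulated mature species that bimodality
appears in the read-weighted histogram instead.

## Preprocessing (`preprocess`)

Adapter trimming scans every alignment of an adapter prefix (minimum overlap
6 nt) against the read, allowing up to 1 substitution and no indels; the
leftmost hit wins, and reads without a hit are kept whole but flagged. Clean
reads must have trimmed length in [16, 30] inclusive, no ambiguous bases, and
mean Phred >= 20 — the junk-read definition is this package's convention, as
is the inclusive reading of the 16-30 nt window; both are configurable.
Filtering statistics partition the input exactly (kept plus per-reason drops
equals total), an invariant asserted throughout the suite. Clean reads are
collapsed to unique tags with one raw count per library; the tag table is
sorted by sequence, so it is independent of read order. Length profiles are
computed over distinct sequences (default) or total reads, with peak windows
defined as maximal runs of bins exceeding 1.5x the median bin.

## The annotation cascade (`annotate`)

Categories are assigned in fixed priority order — mRNA, rRNA, tRNA, snRNA,
snoRNA, repeat (removal steps, exact match by default), then conserved
miRNA, novel miRNA, piRNA homolog, nohit — and each tag receives exactly one
category, so categories always partition the tag set. Multi-mapping ties
break by fewest mismatches, then lexicographic reference id. Curated sets
(matures, piRNAs) are matched on their forward strand; the genome on both
strands. Coordinates are 0-based half-open internally.

Mature-miRNA matching allows one substitution. A matched tag whose precursor
occurs in the genome is `conserved_miRNA_genome`; if the precursor is absent
but the tag's own genomic context folds into a valid hairpin it is
`conserved_miRNA_hairpin`; a matched tag with neither line of evidence falls
through the remaining cascade (ultimately to nohit), mirroring the exclusion
of unmappable, unfoldable reads from the miRNA catalogue. Unmatched tags that
map exactly to the genome are tested as novel miRNAs: two candidate windows
per locus (70 nt upstream + tag, and tag + 70 nt downstream, in mapped-strand
orientation) are folded, and either passing yields `novel_miRNA`.

### Hairpin validation

The default folder is an in-package Nussinov maximum-pairing dynamic program
(Watson-Crick plus G:U wobble, minimum hairpin loop 3, deterministic
traceback); `backend="rnafold"` delegates to the ViennaRNA `RNAfold` binary
when thermodynamic energies are wanted. A candidate passes when (a) one
top-level helix component holds at least 70% of all base pairs and contains
the mature's pairing partners (the "single predominant stem-loop" rule —
strictly forbidding any secondary helix would reject nearly every
maximum-pairing structure with flanking sequence), (b) the mature lies
entirely in the 5' or 3' arm, (c) at least 14 mature bases are paired, and
(d) the score clears the backend threshold: paired fraction >= 0.55 for the
built-in folder, MFE <= -18 kcal/mol for RNAfold. Maximum-pairing scores are
a permissive surrogate for free energy: random flanking sequence folds
promiscuously, so the built-in backend is best treated as a recall-oriented
screen, with RNAfold available where precision matters.

### piRNA homology

Tags surviving the earlier steps are matched against the piRNA set with at
most one substitution, and the best hit is accepted only when its ungapped
Karlin-Altschul E-value E = K·m·n·exp(-lambda·S) falls below 1e-4, with
S = matches - 2·mismatches (the +1/-2 scheme), m the tag length, n the summed
piRNA database length, and lambda the positive root of
sum p_i p_j exp(lambda s_ij) = 1 on uniform composition (~1.332 for +1/-2),
solved numerically. K has no convenient closed form for this scheme and is
fixed at 0.3 (configurable); since lambda·S dominates the exponent, the
accept/reject boundary is insensitive to K within an order of magnitude.

## Differential expression (`destats`)

Counts are normalized to reads per million: NE = count / total × 1e6. The
default total is the library's summed miRNA count (so NE columns sum to
exactly 1e6); a clean-read total is available as a switch, reflecting the two
conventions such reports use side by side.

For each library pair (A, B): rows with NE < 1 in all three libraries are
`filtered` and excluded from testing and from the multiple-testing family;
rows with zero NE in exactly one pair member are `specific` to the other and
are not tested (so tested rows never need a pseudocount — the 0 -> 0.01
replacement exists only for log-scale plotting); rows undetected in both
pair members (possible for a third-group-exclusive species) are likewise
excluded. Remaining rows are tested on raw counts with:

- **Audic-Claverie**: p(y|x) = (N2/N1)^y (x+y)! / (x! y! (1+N2/N1)^(x+y+1)),
  two-sided p = min(1, 2·min(P(K<=y), P(K>=y))), evaluated in log space with
  a direct-summation fallback for the upper tail. Note the doubled-tail
  construction is not exactly symmetric under exchanging the two libraries
  (the discrete tail index sets differ between conditionings), though the
  underlying conditional model is.
- **Fisher's exact test** (two-sided, point-probability rule) and the 2x2
  **chi-squared test** (1 df, continuity correction off by default) on
  [[x, N1-x], [y, N2-y]], via scipy.

The working p-value (default policy: Audic-Claverie; `consensus` takes the
maximum of the three) is Bonferroni-multiplied by the number of tested rows
in that pair. A row is `up`/`down` when adjusted p < 0.05 and
log2(NE_A/NE_B) > 1 or < -1. Abundance tiers compare raw counts to the
dataset mean copy: High above the mean, Middle above 10 and at most the mean,
Low at most 10 (boundaries assigned downward). The qPCR side provides
RQ = 2^(-ddCt) with dCt = Ct(target) - Ct(reference per condition), and a
Welch t-test for replicate comparisons.

## Set accounting and reports (`setrep`)

Detection means NE > 0 (configurable minimum count). `venn_partition`
computes the seven-region partition of the three detection sets;
`solve_partition` reconstructs the full partition from the marginals a
report prints — per-set totals, exclusive counts, and one pairwise-only
region — by solving the induced 3x3 linear system and rejecting negative or
non-integer solutions. Pairwise co-detection is the pair-only region plus the
triple overlap; percentages of the union are reported to one decimal.
Hierarchical clustering of log10 NE (zeros replaced by 0.01) uses Euclidean
distances with complete linkage by default — the metric/linkage are not
dictated by the analysis and are configurable — with rows pre-sorted by id
for order-independent output. `run_pipeline` chains the stages and writes
all tables as TSV plus JSON summaries; figures are never load-bearing.

## Problem sizes used in the test suite

The suite exercises the pipeline at reference sizes of 15-50 miRNAs and
library depths of 4,000-100,000 reads — the parameter-recovery run uses
three libraries of 100,000 reads with 50 miRNAs, ten true differential
species at |log2FC| = 2 and three group-exclusive species — and the
statistical calibration uses 10,000 Poisson replicates at rate 50 with
library sizes of 10^6. These sizes give stable recovery statistics while
keeping the whole suite in the minutes range on a single core.

## Known limitations

- The Nussinov backend over-predicts pairing on random flanks; novel-miRNA
  specificity on real genomes needs the RNAfold backend.
- The Audic-Claverie implementation sums the conditional distribution
  directly; for counts far beyond ~10^6 a normal approximation would be
  preferable.
- The E-value's K constant is nominal; absolute E-values near the 1e-4
  boundary should not be over-interpreted.
- No FDR control beyond Bonferroni, and no replicate-aware dispersion
  modelling — the pooled single-library design provides nothing to estimate
  dispersion from.
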