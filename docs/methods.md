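# Methods

This note documents the models, algorithms, defaults and limitations of
the package. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Panel design

**Masking.** Known variants (ref-allele span) and the target ± 5 bp are
replaced by `N` before primer search; a primer over a polymorphism
risks allelic dropout, and one over the target would block measurement.
Masking is idempotent and length-preserving.

**Melting temperature.** Nearest-neighbor thermodynamics with the
unified dinucleotide parameter set (SantaLucia 1998), entropy salt
correction $0.368 (N{-}1) \ln[\mathrm{Na}^+]$, fixed at 50 mM monovalent
salt and 250 nM primer ($C_T/4$ in the non-self-complementary case).
The fixed regime makes designs reproducible; the test suite checks the
implementation against an independent implementation of the same
published table to 0.1 °C. Defaults: target 60 °C, accepted range
59–62 °C; primer lengths 18–27 nt.

**Candidate search and selection.** Exhaustive sliding-window
enumeration within 400 bp of the target; every pair must satisfy TM
bounds, amplicon length 225–300 bp, no masked base in a primer, and the
target strictly inside the insert. Pairs are ranked by
$|T_f - 60| + |T_r - 60|$ (a surrogate ranking: the tools this replaces
do not publish their scoring) and selected greedily under two
constraints: primer intervals pairwise disjoint, and target offsets
within the inserts differing by ≥ 20 bp where feasible (relaxed when it
cannot be met, since only the goal — different positions per amplicon —
is stated by the protocol, not a threshold).

**In-silico PCR uniqueness.** A primer anneals where it matches with at
most one mismatch outside its 3′-terminal 5 nt and none within them; a
product is any plus-site/minus-site pairing within twice the maximum
amplicon length. A pair is accepted iff exactly one product forms on
the supplied reference. Checking is lazy: only selected pairs are
verified, and failures trigger re-selection.

**Barcodes, UMIs, adapters.** Per-amplicon 10 nt barcodes are sampled
(seed-controlled) from a pairwise-Hamming-≥ 4 code so that
demultiplexing at ≤ 3 mismatches cannot cross-assign; UMIs are
degenerate prefixes of 10 nt (Ion mode) or 5 nt (Illumina mode);
platform adapters are opaque constants.

**Tiling mode.** For novel-variant scanning every base of a region must
sit under ≥ 4 amplicon inserts (≤ 285 bp including primers). Amplicons
are laid out in four staggered phases; the scheduler always extends the
phase that reaches least far, searching primer windows near the phase
boundary and relaxing tile length progressively when a neighborhood is
crowded, with a final patch pass over any under-covered bases. Primer
sites must be disjoint between any two amplicons whose *inserts*
overlap (a "covering group"); amplicons measuring disjoint base sets
may abut. Random sequence occasionally lacks the required primer
windows (as real loci do); the designer then raises an error listing
the uncoverable intervals rather than degrading coverage.

## Simulator

The generator emulates the two stages that govern low-AAF detection:

1. **Molecules.** `molecules_from_mass`: $N = \mathrm{round}(m \cdot
   1000 / 3.3)$ haploid copies for $m$ ng (3.3 pg per haploid genome,
   chosen so 25 ng ≈ 3,788 cells). Alternate copies entering a reaction
   are $\mathrm{Binomial}(N, \mathrm{AAF})$. By default all amplicons
   of a panel share one molecule pool — one multiplexed reaction — so
   their AAFs co-fluctuate with the draw and differ only by read
   sampling; `shared_input=False` models independent reactions.
2. **Reads.** Each read samples the molecule pool, then acquires
   substitution errors at `sub_rate` (default 7×10⁻⁵ per base,
   uniformly to the three other bases) plus `polymerase_rate` (default
   8.8×10⁻⁶ per base — the fidelity estimate for the *whole* PCR, so it
   is added once, not per cycle), indel errors at 1×10⁻⁵ per base
   scaled ×2 per homopolymer base beyond 3 (capped ×50), and Phred
   qualities from a clipped normal (mean 30, SD 5).

The count-level path (`simulate_counts`) draws the per-position tallies
directly — binomial thinning for quality, binomial alt/ref split,
binomial-split error redistribution — and is statistically equivalent
to the read-level path followed by processing with no alignment loss
(verified pairwise in the tests). Depth-heavy experiments use it;
read-level simulation exists to exercise demultiplexing, trimming,
alignment and UMI handling.

What the generator does **not** model: PCR amplification trees and
jackpot effects (polymerase errors are a flat rate, so consensus-based
error suppression is understated), GC/length amplification bias,
platform flow-space artifacts, paired-end structure, and primer-site
mutations arising during cycling. Passing tests therefore show
correctness of the pipeline's statistics under the stated error model,
not performance on any particular instrument run.

## Read processing

Demultiplexing matches the 15 informative leading nucleotides (10 nt
barcode + first 5 nt of the forward primer, skipping the UMI when one
is present) with ≤ 3 mismatches; equidistant best matches are left
unassigned — stricter than first-match splitters, but order-independent.
Trimming removes the barcode head (capturing the UMI), then 3′-quality
trims at cutoff 10 by the partial-sum rule: remove the suffix
maximizing $\sum (\mathrm{cutoff} - q)$, the global optimum over all
suffixes (the brute-force equivalence is a property test).

Alignment is banded (± 30) affine-gap global alignment of the read
against its known 225–300 bp amplicon reference: match +1, mismatch −4,
gap open −6 (first base), extend −1, reference end gaps free.
Alignments scoring below half the read length are rejected. Gap runs
are then shifted to their leftmost equivalent positions, which
deterministically normalizes homopolymer indels and substitutes for a
separate realignment pass. Mapping quality is the scaled score
(cap 60); only its ≥ 20 gate matters downstream. Primer-overlapping
bases are soft-clipped and excluded from counting.

UMI families (same amplicon, same UMI) can be collapsed to one
consensus read: per position the majority base at ≥ 60% wins, otherwise
the position is masked at quality 0 so it fails the pileup gate.

## Quantification and calling

Pileups count a base iff its quality ≥ 20 and the read's mapping
quality ≥ 20 (pileup-style thresholds); deletions count at each deleted
position with the full-event span tracked separately (indel AAF
denominators use reads spanning the whole event; partial spanning reads
are excluded); insertions attach to the preceding position.

The background error of an amplicon is measured at 50 flanking
positions per side of the target (truncated at insert edges; fewer than
30 positions sets a low-confidence flag), excluding known germline
sites. The default background statistic pools the three alternative
bases (matching what pileup parsers report); the target-base-specific
fraction is also computed and can be selected. This asymmetry — the
target's AAF is allele-specific (null expectation ≈ background/3) while
the background pools all three — gives the detection rule an intrinsic
specificity margin.

**Detection.** Welch one-sided two-sample t-test of the per-amplicon
AAFs against the pooled non-excluded flanking fractions, significant at
0.05, **and** the 95% Student CI lower bound above the background error
rate. The CI threshold is configurable as background mean + $k$ SD with
$k = 0$ by default: raising $k$ buys specificity, but at high depth the
across-position background SD is counting-noise-dominated
($\sqrt{\mathrm{bg}/\mathrm{depth}}$), so $k = 2$ already rejects
accurate measurements near 0.1% AAF at 10,000X. A single amplicon
cannot support the t-based rule; its verdict falls back to a
Clopper–Pearson binomial CI and is flagged.

**Consensus scan.** Per position and allele, a covering amplicon is
*supporting* when the allele fraction exceeds that amplicon's
leave-one-out background mean + 3 SD; a call requires support in
≥ 3/4 of covering amplicons. No multiple-testing correction is applied
by default — the k-of-n rule is the specificity mechanism (the type-I
property test shows zero calls on mutation-free input at 10,000X in
≥ 95% of seeds).

**Dropout.** An amplicon is flagged when its AAF deviates > 50%
(relative) from the median of the others *and* lies outside their 95%
CI; a known variant under one of its primers is annotated as the likely
cause. Both thresholds operationalize "dramatically skewed" and are
configurable; flagged amplicons can be excluded from pooling.

**Phasing.** Reads covering both the target and a nearby germline site
and carrying the target's alternate allele are informative; ≥ 90% of
them carrying the germline alternate ⇒ cis, ≤ 10% ⇒ trans, otherwise
undetermined (minimum 10 informative reads).

## Reproduction experiments and problem sizes

`scripts/acceptance.py` and the acceptance tests run the method at the
study conditions, all count-level: a 13-point two-fold series (50% →
0.012%) with 3 amplicons at 50,000X and 50 or 25 ng; depth titration by
hypergeometric downsampling to 10,000X; a 4-amplicon tiled panel at
13,766X with an 8-point series (10% → 0.01%); heterozygote control at
10,000X. Detection limits are averaged over five seeds; sensitivity
over three replicate series. A full run takes a few seconds on one CPU.

**Known limitation — the molecule-sampling floor.** At 0.025% AAF a
50 ng reaction receives on average 3.7 alternate molecules (1.9 at
25 ng), so the realized fraction of any single reaction scatters with
CV ≈ 50–70%, and the smallest-detected-AAF statistic is heavy-tailed.
Averages over seeds therefore sit systematically above what a single
(lucky) physical realization can show: the simulated detection limits
land around 0.03–0.04% AAF where single realizations reach 0.012–0.025%,
and the 10,000X accuracy limit lands near 0.13–0.2% against 0.1% for a
single run. The per-seed values and the averaging are reported as-is;
no parameter is tuned to close this gap, because it is a property of
counting statistics, not of the pipeline.
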