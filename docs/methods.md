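# Methods

## Scope

`pirnakit` quantifies the hallmarks of germline piRNA biogenesis in a
small RNA-seq library and attributes pathway expression to cell
populations in mixed testis tissue.  The library-level descriptors are:
the read-length distribution with its miRNA / piRNA / tRNA-fragment
bands, the 1U and 10A nucleotide biases, the fraction of reads derived
from transposable elements (TEs), the ping-pong 10-nt overlap Z-score,
and the number of probabilistically called piRNA clusters.  The
expression-level analysis is a marker-correlation report separating
germ-cell signal (DDX4, DAZL) from GCNIS/TGCT signal (NANOG, POU5F1).
A deterministic synthetic-data generator produces toy genomes,
libraries and expression tables with known ground truth so that every
stage is testable end to end.

## Alignment model

Reads are aligned to the genome by exact substring match on both
strands, with no mismatches or indels.  Small RNAs often carry short
non-templated 3' additions (uridylation/adenylation by terminal
nucleotidyl transferases), which defeat exact matching; the aligner
therefore retries each unaligned read after removing one 3' nucleotide
at a time, up to three nucleotides, and accepts the first trim level
that yields at least one hit.  All hits at that level are reported, a
read is never reported at more than one trim level, and a trim that
would leave fewer than 15 nt is not attempted.

Multimapping is resolved by 1/N weighting: a read with N genomic
placements contributes 1/N of its copy count to each placement.  N is
counted per unique sequence (identical sequences have identical hit
sets), the weight is stored as the exact rational 1/N, and all mass
accounting is done in rational arithmetic, so the identity

    sum over hits of (copies x 1/N)  =  aligned read copies

holds exactly, not to floating-point tolerance.  Reads with more than
10,000 placements are flagged over-cap, excluded from every weighted
statistic and tallied in the run report; the cap is configurable.

The index is a 15-mer position table over the forward genome; a query's
first 15 bases seed candidate placements (for the minus strand, the
reverse complement is looked up) and candidates are verified by direct
string comparison, so the answer set is identical to a naive scan — a
property enforced by test against an independent brute-force oracle.
Genome positions containing N never match, because queries are N-free
by the filtering contract.

Minus-strand hits are reported on forward-strand coordinates; the
read's 5' end is then at `end - 1`.  Output ordering is (chrom, start,
strand, read id) lexicographic so that repeated runs are byte-identical.

## Signatures

**Length bands.** Copy-weighted histograms over 15-50 nt, with band
fractions for miRNA (21-23 nt), piRNA (25-31 nt) and tRNA fragments
(31-33 nt).  The 31-nt column intentionally belongs to both the piRNA
and tRF bands; band fractions are descriptive, not a partition.

**1U / 10A.** Fractions of copy-weighted reads whose first base is T
and whose tenth base is A, computed by default over the piRNA band
(25-31 nt); full-range mode is available.  The 10A denominator counts
only reads of length >= 10.  An empty selection yields an explicit
degenerate flag rather than a zero.

**TE coverage.** A genomic hit contributes its weight (copies x 1/N) to
every TE subfamily whose annotated intervals it overlaps by >= 1 bp.
Per-subfamily totals may therefore double-count a hit spanning two
overlapping annotations, but the global TE total counts each hit once,
so `te_total + non_te_total` equals the aligned copies exactly.  The
TE fraction reported is the once-counted version.

**Consensus alignment.** Reads are scanned ungapped against each TE
consensus at every offset on both strands, keeping placements with
Hamming distance <= 2 (configurable).  Per-read weight is 1 over the
total number of consensus placements.  Reads longer than a consensus
are skipped for that consensus and tallied.  Per-position, per-strand
coverage profiles conserve weighted mass exactly.

**Ping-pong.** For a plus-strand read with 5' end p and a minus-strand
read with 5' end q (forward coordinates), the 5'-5' overlap is
d = q - p + 1.  Weighted pair counts (product of the two 1/N x copy
weights) are accumulated for d in 1..20 within each reference
(chromosome or consensus), histograms are summed across references, and

    z10 = (count(10) - mean(background)) / sd(background)

with background d in {1..9, 11..20} and the sample standard deviation
(ddof = 1).  If the background is constant the profile is flagged
degenerate and z10 is None.  This is the field-standard definition; the
background set is configurable in principle by editing the module
constants.  z10 is invariant under uniform rescaling of the weights.
The per-library report flags z10 > 3.29 (the two-sided p < 0.001 normal
quantile) as significant.

## Cluster calling

Candidate loci are formed by merging piRNA-band hits (aligned length
25-31 nt) separated by at most 1 kb.  Low-complexity reads — one
nucleotide accounting for more than 75% of the read — are dropped
first, a deliberately simple stand-in for dust-style masking.  A
candidate becomes a cluster if it passes, in order:

1. **mass**: weighted read mass >= `min_reads` (default 10 copies);
2. **density**: with total aligned mass M over a genome of G bp, the
   binomial tail probability P(X >= k), X ~ Binomial(round(M), s/G)
   for a span of s bp holding mass k, is below `pdens` (default 0.05);
3. **composition**: the weighted fraction of reads with 5' T or 10th
   base A is >= 0.1, or the fraction with both is >= 0.1;
4. **strandedness**: the majority strand holds >= `clstrand` (default
   0.5) of the mass; otherwise a bidirectional split is attempted — a
   split point is accepted when both sides are mono-strand and each
   side independently passes the density test at `clsplit` (0.05),
   and the most strand-balanced acceptable split is emitted as two
   calls flagged bidirectional.

This module implements the documented semantics of these thresholds
with a uniform-placement binomial null; it is a behavioural analogue of
proTRAC-style callers, not a re-implementation of any particular tool's
internal scoring.  Lowering `pdens` can only shrink the call set.
Reference overlap counts a call as recovered if it shares >= 1 bp with
any interval of a reference cluster list (half-open coordinates
throughout).

## Marker correlation

Expression values (RPKM-like, samples x genes) are divided per sample
by the ACTB value, making the reference column exactly 1; a missing or
non-positive reference is an error naming the sample.  Pairwise Pearson
correlations are computed among a configurable pathway gene set
(shipped default: a conventional 14-gene PIWI/piRNA core — PIWIL1/2/3/4,
MAEL, HENMT1, PLD6, TDRD1/5/9, TDRKH, MOV10L1, FKBP6, GPAT2 — an
editable placeholder, not a canonical list), the germline markers and
the TGCT markers, optionally on log2(x+1) values and optionally within
one sample group.  Zero-variance genes are excluded from the summaries
with a warning.  Per-gene relative standard deviation is reported as
100 x sd / mean.  Correlations are computed on normalized values
without log transform by default.

## Synthetic data

One integer seed determines every output byte; each stage (genome,
library, expression) draws from its own derived substream so stages can
be regenerated independently.

**Genome.**  Uniform-random background sequence; per-family random
consensus sequences whose copies are planted non-overlapping on random
strands after per-base substitution at the divergence rate (default
0.05, every substitution changes the base); piRNA-cluster intervals
(default 3 x 5 kb in 200 kb) reserved disjoint from TE copies; fixed
22-nt miRNA-like and 32-nt tRF-like donor loci.  Requests exceeding the
genome's capacity raise an error.

**Library.**  Read classes are drawn by configured fractions (defaults:
60% piRNA-like, 15% miRNA-like, 10% tRF-like, remainder background).
piRNA reads take their genomic span (25-31 nt, mode 29) from cluster or
TE loci; miRNA/tRF reads reuse their donor loci with a geometrically
skewed usage, giving the dominant-species structure of real libraries;
background reads are uniform, 18-35 nt.  Non-templated 3' tails
(default: 70% none, 15%/10%/5% of 1/2/3 nt) are appended with bases
drawn to differ from the genomic continuation, so the trim loop is
exercised exactly `tail_len` times — a guarantee that is exact for
single-copy source loci but can be broken by design for TE-derived
reads, where a diverged sister copy may genuinely template the tail.

Because reads are genome-templated, base biases are imposed by site
selection rather than by editing reads.  Geometry ties the constraints
of a ping-pong pair together: with an exact 10-nt 5'-5' overlap the
partner's 10th base equals the primary's first base, so the two cannot
be set independently.  Mirroring the biology — uridine-1 marks primary
piRNAs, adenine-10 marks ping-pong secondaries — unpaired reads are
placed with 5'-T probability `p_1U` (default 0.8) and pair anchors with
probability `p_10A` (default 0.7); the partner's own first base is left
unconstrained.  Applying a 10A constraint to unpaired reads would
anchor plus-strand 5' ends and minus-strand 10th bases on the same
genomic T positions and manufacture a strong spurious 10-overlap excess
in libraries with no ping-pong — a synthetic version of the known
composition-bias inflation of ping-pong scores — which is why the
generator does not do it.

A configurable fraction of piRNA reads (`pingpong_fraction`, default
0.5) is emitted as opposite-strand pairs with an exact 10-nt overlap;
the pairing indicator is Bernoulli per read (rounded to whole pairs),
so the paired fraction is recoverable to binomial error.

**Expression.**  Each sample carries a germ-cell-content latent g and
an independent GCNIS/TGCT-content latent t set by group (10 samples per
group by default): normal testis g ~ lognormal(0, 0.75) and t ~ 0 — the
lognormal spread reproduces the high per-gene relative SD seen for
pathway genes in bulk testis, where expression tracks germ-cell content;
adjacent tissues intermediate mixtures (non-seminoma-adjacent higher g
than seminoma-adjacent); tumors g ~ 0, t ~ 1.  Germ-driven genes (the
pathway set plus DDX4/DAZL) are `scale x (loading x g + noise)` with
per-gene lognormal scales, loading 0.95 and noise sd 0.1 in latent
units, clipped at zero; TGCT-driven genes (NANOG, POU5F1 and two
miR-302/371-class rows) likewise from t; ACTB is a constant-scale
housekeeping gene whose relative noise is 1% of the configured noise
sd, so the noiseless limit is exactly noise-free after normalization.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: sequencing error and quality-score
structure (qualities are constant), adapter contamination, realistic
human genome composition (GC structure, nested/fragmented repeats,
assembly gaps), piRNA cluster substructure (uni/bi-directional
promoter architecture, phased trailing), RNA secondary structure, and
library-preparation biases.  Conclusions from the closure tests are
about the correctness of the computations, not about biological
sensitivity/specificity on real tissue.

## Numerical and design choices

- Coordinates are 0-based half-open everywhere; RepeatMasker input is
  converted on load; the read 5' end on the minus strand is `end - 1`.
- Mass accounting uses `fractions.Fraction`; Z-scores, density
  p-values and correlations use floats.
- Quality filtering drops a read if any base is below the threshold
  (default Q20), outside 15-50 nt, or contains N; collapsing sorts by
  descending count then sequence, so ids are deterministic.
- The density test rounds total mass to the nearest integer and takes
  the ceiling of interval mass, which is conservative for fractional
  multimapper weights.
- Writers emit fixed column orders, `\n` line endings and 6-significant-
  digit floats; identical inputs give identical bytes.
- Test and verification problem sizes are package choices: aligner
  oracle equivalence on 20 seeded 50 kb genomes x 500 reads; bias and
  ping-pong recovery at 5,000 reads x 10 seeds (20 for the null
  calibration); the pairing-fraction monotonicity sweep at 2,000 reads
  x 4 fractions x 10 seeds; cluster recovery on 1 Mb genomes with one
  planted 5 kb cluster, 500 cluster reads and 500 background reads x
  10 seeds; expression recovery at 50 samples.

## Known limitations

- The aligner is exact-match only; genuinely mismatched genomic copies
  of a read (SNVs, RNA editing) are found only through the separate
  consensus-alignment path.
- The cluster caller's binomial null assumes uniform placement and
  ignores mappability structure; on small dense genomes background
  reads can occasionally merge into a spurious call, so somatic-like
  libraries are expected to yield near-zero, not always exactly zero,
  calls at desk scale.
- proTRAC's exact scoring internals are not reproduced; parameter
  values carry the documented semantics only.
- The 14-gene pathway set is a configurable placeholder.
- Report plots are not generated; all outputs are TSV/BED/FASTA/FASTQ
  tables suitable for external plotting.
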