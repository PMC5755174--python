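"""piRNA biogenesis descriptors.

This module computes the diagnostic statistics of germline piRNA
production from a collapsed, aligned small-RNA library:

* read-length histograms with miRNA (21-23 nt), piRNA (25-31 nt) and
  tRNA-fragment (31-33 nt) band fractions;
* 1U / 10A nucleotide biases (uridine at position 1, adenine at
  position 10, in DNA space T/A);
* 1/N-weighted read coverage summed by transposable-element subfamily;
* ungapped alignment of reads to TE consensus sequences with up to two
  mismatches, and per-position coverage profiles along the consensus;
* the ping-pong signature: the histogram of 5'-5' overlaps between
  opposite-strand read pairs and its Z-score at the canonical 10-nt
  overlap.

The ping-pong Z-score uses the field-standard definition: the weighted
pair count at overlap 10 versus the mean and sample standard deviation
of the counts at overlaps 1-9 and 11-20.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io_formats import CollapsedRead, TEAnnotation
from .trim_align import AlignmentHit, revcomp

__all__ = [
    "LengthHistogram",
    "BiasStats",
    "PingPongProfile",
    "ConsensusHit",
    "TECoverage",
    "length_distribution",
    "nt_bias",
    "te_weighted_coverage",
    "align_to_consensus",
    "consensus_profile",
    "pingpong_zscore",
    "pingpong_from_genome_hits",
    "pingpong_from_consensus_hits",
]

MIRNA_BAND = (21, 23)
PIRNA_BAND = (25, 31)
TRF_BAND = (31, 33)

MAX_OVERLAP = 20
PING_PONG_D = 10


@dataclass
class LengthHistogram:
    """Copy-weighted read-length histogram with small-RNA class bands."""

    counts: dict[int, int]
    n: int
    frac_mirna_band: float
    frac_pirna_band: float
    frac_trf_band: float


def _band_fraction(counts: dict[int, int], band: tuple[int, int], n: int) -> float:
    if n == 0:
        return 0.0
    lo, hi = band
    return sum(c for L, c in counts.items() if lo <= L <= hi) / n


def length_distribution(reads: Sequence[CollapsedRead]) -> LengthHistogram:
    """Copy-weighted length histogram and band fractions (empty input -> n=0)."""
    counts: dict[int, int] = {}
    for r in reads:
        counts[len(r)] = counts.get(len(r), 0) + r.count
    n = sum(counts.values())
    return LengthHistogram(
        counts=counts,
        n=n,
        frac_mirna_band=_band_fraction(counts, MIRNA_BAND, n),
        frac_pirna_band=_band_fraction(counts, PIRNA_BAND, n),
        frac_trf_band=_band_fraction(counts, TRF_BAND, n),
    )


@dataclass
class BiasStats:
    """1U / 10A bias fractions (copy-weighted); degenerate when no reads qualify."""

    frac_1U: float | None
    frac_10A: float | None
    n: int
    n_10: int  # denominator for 10A (reads of length >= 10)
    degenerate: bool = False


def nt_bias(
    reads: Sequence[CollapsedRead],
    length_range: tuple[int, int] = PIRNA_BAND,
) -> BiasStats:
    """Fractions of copy-weighted reads with 5' T (1U) and 10th base A (10A).

    Restricted to ``length_range`` (default: the piRNA band, 25-31 nt);
    pass ``(1, 10**9)`` for full-range mode.  With no reads in range the
    result is flagged degenerate and the fractions are None, not zero.
    """
    lo, hi = length_range
    n = n10 = first_t = tenth_a = 0
    for r in reads:
        if not lo <= len(r) <= hi:
            continue
        n += r.count
        if r.sequence[0] == "T":
            first_t += r.count
        if len(r) >= 10:
            n10 += r.count
            if r.sequence[9] == "A":
                tenth_a += r.count
    if n == 0:
        return BiasStats(None, None, 0, 0, degenerate=True)
    return BiasStats(
        frac_1U=first_t / n,
        frac_10A=tenth_a / n10 if n10 else None,
        n=n,
        n_10=n10,
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# TE coverage


@dataclass
class TECoverage:
    """1/N-weighted read mass per TE subfamily.

    ``per_subfamily`` may double-count a hit that overlaps intervals of two
    subfamilies; ``te_total`` counts every hit once, so
    ``te_total + non_te_total`` equals the aligned read copies exactly
    (rational arithmetic).
    """

    per_subfamily: dict[str, Fraction]
    te_total: Fraction
    non_te_total: Fraction

    @property
    def te_fraction(self) -> float:
        total = self.te_total + self.non_te_total
        return float(self.te_total / total) if total else 0.0


def te_weighted_coverage(
    hits: Iterable[AlignmentHit],
    reads: dict[str, CollapsedRead],
    annotation: TEAnnotation,
) -> TECoverage:
    """Sum ``count x 1/N`` hit weights by TE subfamily.

    A hit contributes its full weight to every subfamily whose intervals it
    overlaps by >= 1 bp, and once to the global TE total; hits overlapping
    no TE go to the non-TE total.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for iv in annotation.intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv.subfamily)

    per_subfamily: dict[str, Fraction] = {}
    te_total = Fraction(0)
    non_te_total = Fraction(0)
    for h in hits:
        w = Fraction(reads[h.read_id].count, h.n_hits)
        tree = trees.get(h.chrom)
        overlaps = tree.overlap(h.start, h.end) if tree is not None else ()
        if overlaps:
            for sub in {o.data for o in overlaps}:
                per_subfamily[sub] = per_subfamily.get(sub, Fraction(0)) + w
            te_total += w
        else:
            non_te_total += w
    return TECoverage(per_subfamily, te_total, non_te_total)


# ---------------------------------------------------------------------------
# Consensus alignment


@dataclass(frozen=True)
class ConsensusHit:
    """One ungapped placement of a read on a TE consensus.

    ``position`` is the 0-based offset of the leftmost matched base on the
    consensus; for a minus-strand hit the read's 5' end sits at
    ``position + length - 1``.
    """

    read_id: str
    subfamily: str
    position: int
    strand: str
    mismatches: int
    length: int
    n_placements: int  # placements of this read across all consensi

    @property
    def weight(self) -> Fraction:
        return Fraction(1, self.n_placements)

    @property
    def five_prime(self) -> int:
        return self.position if self.strand == "+" else self.position + self.length - 1


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def align_to_consensus(
    reads: Sequence[CollapsedRead],
    consensi: dict[str, str],
    max_mismatch: int = 2,
) -> tuple[list[ConsensusHit], dict[str, int]]:
    """Ungapped scan of each read against each consensus, both strands.

    Every offset with Hamming distance <= ``max_mismatch`` is reported.
    Reads longer than a consensus are skipped for that consensus and
    tallied in the returned ``skipped`` mapping (subfamily -> count).
    Each read's weight is 1/(total placements across all consensi).
    """
    if not consensi:
        raise ValueError("no consensus sequences supplied")
    enc = {sub: _encode(seq) for sub, seq in consensi.items()}
    skipped: dict[str, int] = {}
    hits: list[ConsensusHit] = []
    for read in reads:
        L = len(read)
        placements: list[tuple[str, int, str, int]] = []
        fwd = _encode(read.sequence)
        rev = _encode(revcomp(read.sequence))
        for sub in sorted(consensi):
            carr = enc[sub]
            if L > len(carr):
                skipped[sub] = skipped.get(sub, 0) + 1
                continue
            windows = sliding_window_view(carr, L)
            for strand, probe in (("+", fwd), ("-", rev)):
                mm = (windows != probe).sum(axis=1)
                for pos in np.nonzero(mm <= max_mismatch)[0]:
                    placements.append((sub, int(pos), strand, int(mm[pos])))
        n = len(placements)
        for sub, pos, strand, mm_count in placements:
            hits.append(ConsensusHit(read.id, sub, pos, strand, mm_count, L, n))
    return hits, skipped


def consensus_profile(
    hits: Iterable[ConsensusHit],
    subfamily: str,
    consensus_length: int,
    reads: dict[str, CollapsedRead],
) -> dict[str, np.ndarray]:
    """Per-position, per-strand weighted read coverage along one consensus.

    Each hit adds ``count x 1/placements`` over ``[position, position + length)``
    on its strand.  Raises if the subfamily has no hits at all.
    """
    profile = {"+": np.zeros(consensus_length), "-": np.zeros(consensus_length)}
    seen = False
    for h in hits:
        if h.subfamily != subfamily:
            continue
        seen = True
        w = float(h.weight) * reads[h.read_id].count
        profile[h.strand][h.position : h.position + h.length] += w
    if not seen:
        raise ValueError(f"no consensus hits for subfamily {subfamily!r}")
    return profile


# ---------------------------------------------------------------------------
# Ping-pong


@dataclass
class PingPongProfile:
    """5'-5' overlap histogram between opposite-strand reads, and its Z10.

    ``overlap_counts[d]`` is the weighted number of (plus, minus) read pairs
    whose 5' ends overlap by exactly d nucleotides; z10 compares the count
    at d = 10 against the mean/sd of the background overlaps.
    """

    overlap_counts: dict[int, float]
    z10: float | None
    degenerate: bool
    background: tuple[int, ...] = tuple(
        d for d in range(1, MAX_OVERLAP + 1) if d != PING_PONG_D
    )


def zscore_from_counts(overlap_counts: dict[int, float]) -> PingPongProfile:
    """Z-score of the d=10 overlap against the d in {1..9, 11..20} background."""
    background = tuple(d for d in range(1, MAX_OVERLAP + 1) if d != PING_PONG_D)
    bg = np.array([overlap_counts.get(d, 0.0) for d in background])
    s10 = overlap_counts.get(PING_PONG_D, 0.0)
    sd = float(bg.std(ddof=1))
    if sd == 0.0:
        return PingPongProfile(dict(overlap_counts), None, True, background)
    z10 = (s10 - float(bg.mean())) / sd
    return PingPongProfile(dict(overlap_counts), z10, False, background)


def pingpong_zscore(
    five_prime_records: Iterable[tuple[int, str, float]],
) -> PingPongProfile:
    """Ping-pong profile from (5'-coordinate, strand, weight) records.

    All records must come from one reference (a consensus or one genomic
    region).  For a plus-strand read with 5' end at p and a minus-strand
    read with 5' end at q (forward coordinates), the 5'-5' overlap is
    ``d = q - p + 1``; pairs with d in 1..20 are accumulated with product
    weights.  The canonical ping-pong signal is d = 10.
    """
    plus: dict[int, float] = {}
    minus: dict[int, float] = {}
    for pos, strand, w in five_prime_records:
        side = plus if strand == "+" else minus
        side[pos] = side.get(pos, 0.0) + w
    counts = {d: 0.0 for d in range(1, MAX_OVERLAP + 1)}
    for q, wq in minus.items():
        for d in range(1, MAX_OVERLAP + 1):
            wp = plus.get(q - d + 1)
            if wp is not None:
                counts[d] += wp * wq
    return zscore_from_counts(counts)


def pingpong_from_genome_hits(
    hits: Iterable[AlignmentHit],
    reads: dict[str, CollapsedRead],
    chrom: str | None = None,
) -> PingPongProfile:
    """Ping-pong profile from genomic hits.

    Overlaps are formed within each chromosome separately and the overlap
    histograms summed before the Z-score (restrict with ``chrom`` for a
    single reference).
    """
    by_chrom: dict[str, list[tuple[int, str, float]]] = {}
    for h in hits:
        if chrom is not None and h.chrom != chrom:
            continue
        by_chrom.setdefault(h.chrom, []).append(
            (h.five_prime, h.strand, float(h.weight) * reads[h.read_id].count)
        )
    totals = {d: 0.0 for d in range(1, MAX_OVERLAP + 1)}
    for records in by_chrom.values():
        prof = pingpong_zscore(records)
        for d, c in prof.overlap_counts.items():
            totals[d] += c
    return zscore_from_counts(totals)


def pingpong_from_consensus_hits(
    hits: Iterable[ConsensusHit],
    reads: dict[str, CollapsedRead],
    subfamily: str,
) -> PingPongProfile:
    """TE-specific ping-pong profile from consensus alignments."""
    records = [
        (h.five_prime, h.strand, float(h.weight) * reads[h.read_id].count)
        for h in hits
        if h.subfamily == subfamily
    ]
    return pingpong_zscore(records)
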