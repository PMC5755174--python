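"""Probabilistic piRNA-cluster prediction.

piRNA clusters are genomic loci that produce many piRNAs; they appear in
aligned small-RNA data as intervals whose weighted read mass far exceeds
what uniform placement over the genome would give.  This module is a
behavioural analogue of the proTRAC criteria it is configured after — a
density significance threshold (``pdens``), a 1T/10A base-composition
filter, a majority-strand requirement with an optional bidirectional
split (``clstrand`` / ``clsplit``) — not a re-implementation of proTRAC's
internal scoring.

Candidate loci are built by merging piRNA-band hits separated by at most
``merge_gap`` bp.  The density test is a binomial tail: with total aligned
weighted mass M genome-wide and an interval spanning s of G genomic bases,
the probability of observing at least the interval's mass under uniform
placement is ``P(X >= k), X ~ Binomial(round(M), s/G)``.

Low-complexity reads (one base making up more than 75% of the read) are
dropped before clustering, a simple stand-in for dedicated dust masking.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy.stats import binom

from .io_formats import CollapsedRead
from .trim_align import AlignmentHit

__all__ = ["ClusterParams", "ClusterCall", "call_clusters", "overlap_reference"]

PIRNA_LEN_RANGE = (25, 31)


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds for cluster acceptance (defaults follow standard practice)."""

    pdens: float = 0.05  # max binomial tail probability for the read density
    min_1T_or_10A: float = 0.1  # min fraction of reads with 5' T or 10th base A
    min_1T_and_10A: float = 0.1  # alternative composition rule (OR-combined)
    clstrand: float = 0.5  # min majority-strand fraction for a mono-strand call
    clsplit: float = 0.05  # per-side density threshold for bidirectional splits
    min_reads: float = 10.0  # min weighted read copies per cluster
    merge_gap: int = 1000  # max bp between hits merged into one candidate
    low_complexity_frac: float = 0.75  # drop reads dominated by one base above this


@dataclass(frozen=True)
class ClusterCall:
    """A predicted piRNA cluster with its supporting statistics."""

    chrom: str
    start: int
    end: int
    weighted_reads: float
    density_p: float
    frac_1T_or_10A: float
    frac_1T_and_10A: float
    main_strand_frac: float
    bidirectional: bool

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def strand(self) -> str:
        return "."


def _is_low_complexity(seq: str, max_frac: float) -> bool:
    return max(seq.count(b) for b in "ACGT") / len(seq) > max_frac


def _density_p(mass: float, span: int, genome_len: int, total_mass: float) -> float:
    """Binomial tail probability of >= ``mass`` weighted reads in ``span`` bp."""
    n = max(1, round(total_mass))
    k = max(1, math.ceil(mass))
    p = min(1.0, span / genome_len)
    return float(binom.sf(k - 1, n, p))


@dataclass
class _Candidate:
    chrom: str
    hits: list[AlignmentHit]
    weights: list[float]
    seqs: list[str]

    @property
    def start(self) -> int:
        return min(h.start for h in self.hits)

    @property
    def end(self) -> int:
        return max(h.end for h in self.hits)

    @property
    def mass(self) -> float:
        return sum(self.weights)


def _composition(cand_seqs: Sequence[str], weights: Sequence[float]) -> tuple[float, float]:
    total = sum(weights)
    w_or = w_and = 0.0
    for seq, w in zip(cand_seqs, weights):
        has_1t = seq[0] == "T"
        has_10a = len(seq) >= 10 and seq[9] == "A"
        if has_1t or has_10a:
            w_or += w
        if has_1t and has_10a:
            w_and += w
    return w_or / total, w_and / total


def _strand_frac(hits: Sequence[AlignmentHit], weights: Sequence[float]) -> float:
    plus = sum(w for h, w in zip(hits, weights) if h.strand == "+")
    total = sum(weights)
    return max(plus, total - plus) / total


def _make_call(
    cand: _Candidate,
    genome_len_total: int,
    total_mass: float,
    bidirectional: bool,
) -> ClusterCall:
    frac_or, frac_and = _composition(cand.seqs, cand.weights)
    return ClusterCall(
        chrom=cand.chrom,
        start=cand.start,
        end=cand.end,
        weighted_reads=cand.mass,
        density_p=_density_p(cand.mass, cand.end - cand.start, genome_len_total, total_mass),
        frac_1T_or_10A=frac_or,
        frac_1T_and_10A=frac_and,
        main_strand_frac=_strand_frac(cand.hits, cand.weights),
        bidirectional=bidirectional,
    )


def _try_split(
    cand: _Candidate,
    genome_len_total: int,
    total_mass: float,
    params: ClusterParams,
) -> list[ClusterCall]:
    """Attempt a bidirectional split of a strand-mixed candidate.

    A split point is accepted if both sides are mono-strand
    (majority-strand fraction >= clstrand) and each side independently
    passes the density test at ``clsplit``; among acceptable splits the
    one with the most balanced strand purity wins.
    """
    order = sorted(range(len(cand.hits)), key=lambda i: cand.hits[i].start)
    hits = [cand.hits[i] for i in order]
    weights = [cand.weights[i] for i in order]
    seqs = [cand.seqs[i] for i in order]
    best: tuple[float, list[ClusterCall]] | None = None
    for cut in range(1, len(hits)):
        left = _Candidate(cand.chrom, hits[:cut], weights[:cut], seqs[:cut])
        right = _Candidate(cand.chrom, hits[cut:], weights[cut:], seqs[cut:])
        if left.end > right.start:  # sides must not overlap
            continue
        sides = []
        ok = True
        for side in (left, right):
            if side.mass < params.min_reads:
                ok = False
                break
            call = _make_call(side, genome_len_total, total_mass, bidirectional=True)
            if call.main_strand_frac < params.clstrand or call.density_p >= params.clsplit:
                ok = False
                break
            sides.append(call)
        if ok:
            score = min(c.main_strand_frac for c in sides)
            if best is None or score > best[0]:
                best = (score, sides)
    return best[1] if best else []


def call_clusters(
    hits: Iterable[AlignmentHit],
    reads: dict[str, CollapsedRead],
    genome_lengths: dict[str, int],
    params: ClusterParams | None = None,
    length_range: tuple[int, int] = PIRNA_LEN_RANGE,
) -> list[ClusterCall]:
    """Predict piRNA clusters from weighted genomic hits.

    Only hits whose aligned length (after 3' trimming) falls in
    ``length_range`` are used.  Candidates are merged at ``merge_gap``,
    then filtered on weighted mass, density significance, 1T/10A
    composition, and strandedness (with a bidirectional-split rescue).
    Output is coordinate-sorted and non-overlapping.
    """
    params = params or ClusterParams()
    filtered: list[tuple[AlignmentHit, float, str]] = []
    total_mass = 0.0
    for h in hits:
        if h.chrom not in genome_lengths:
            raise ValueError(f"hit on chromosome {h.chrom!r} absent from genome lengths")
        read = reads[h.read_id]
        if not length_range[0] <= (h.end - h.start) <= length_range[1]:
            continue
        if _is_low_complexity(read.sequence, params.low_complexity_frac):
            continue
        w = read.count / h.n_hits
        total_mass += w
        filtered.append((h, w, read.sequence))
    if not filtered:
        return []
    genome_len_total = sum(genome_lengths.values())

    # merge into candidates, per chromosome, gap <= merge_gap
    filtered.sort(key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    candidates: list[_Candidate] = []
    cur: _Candidate | None = None
    cur_end = -1
    for h, w, seq in filtered:
        if cur is not None and h.chrom == cur.chrom and h.start - cur_end <= params.merge_gap:
            cur.hits.append(h)
            cur.weights.append(w)
            cur.seqs.append(seq)
            cur_end = max(cur_end, h.end)
        else:
            cur = _Candidate(h.chrom, [h], [w], [seq])
            candidates.append(cur)
            cur_end = h.end
    calls: list[ClusterCall] = []
    for cand in candidates:
        if cand.mass < params.min_reads:
            continue
        call = _make_call(cand, genome_len_total, total_mass, bidirectional=False)
        if call.density_p >= params.pdens:
            continue
        if not (
            call.frac_1T_or_10A >= params.min_1T_or_10A
            or call.frac_1T_and_10A >= params.min_1T_and_10A
        ):
            continue
        if call.main_strand_frac >= params.clstrand:
            calls.append(call)
        else:
            calls.extend(_try_split(cand, genome_len_total, total_mass, params))
    calls.sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls


def overlap_reference(
    calls: Sequence[ClusterCall],
    reference: Sequence[tuple[str, int, int]],
) -> tuple[int, int]:
    """Count predicted clusters sharing >= 1 bp with any reference interval.

    Returns ``(n_predicted, n_overlapping_reference)``.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for chrom, start, end in reference:
        trees.setdefault(chrom, IntervalTree()).addi(start, end)
    n_overlap = sum(
        1
        for c in calls
        if c.chrom in trees and trees[c.chrom].overlaps(c.start, c.end)
    )
    return len(calls), n_overlap
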