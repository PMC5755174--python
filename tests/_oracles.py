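"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive (direct string scans, all-pairs
interval intersection, double-loop Hamming comparison) and shares no code
with the package's fast paths.
"""
from __future__ import annotations

from fractions import Fraction

_RC = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_RC)[::-1]


def naive_find_all(genome: dict[str, str], query: str) -> list[tuple[str, int, str]]:
    """Every exact occurrence of ``query`` on both strands, by str.find scan."""
    hits = []
    for strand, probe in (("+", query), ("-", rc(query))):
        for chrom, seq in genome.items():
            pos = seq.find(probe)
            while pos != -1:
                hits.append((chrom, pos, strand))
                pos = seq.find(probe, pos + 1)
    return sorted(hits)


def naive_trim_align(genome: dict[str, str], seq: str, max_trim: int = 3,
                     min_len: int = 15):
    """Scan all four trim levels directly; return (trim, hits) or None."""
    for trim in range(max_trim + 1):
        if len(seq) - trim < min_len:
            return None
        query = seq[: len(seq) - trim] if trim else seq
        hits = naive_find_all(genome, query)
        if hits:
            return trim, hits
    return None


def naive_subfamily_totals(hits, reads, intervals):
    """All-pairs interval intersection totals, exact rationals.

    ``hits``: AlignmentHit-likes; ``intervals``: (chrom, start, end, subfamily).
    Returns (per_subfamily, te_total, non_te_total).
    """
    per_sub: dict[str, Fraction] = {}
    te_total = Fraction(0)
    non_te = Fraction(0)
    for h in hits:
        w = Fraction(reads[h.read_id].count, h.n_hits)
        subs = {
            sub
            for chrom, start, end, sub in intervals
            if chrom == h.chrom and start < h.end and h.start < end
        }
        if subs:
            for sub in subs:
                per_sub[sub] = per_sub.get(sub, Fraction(0)) + w
            te_total += w
        else:
            non_te += w
    return per_sub, te_total, non_te


def naive_consensus_scan(read_seq: str, consensi: dict[str, str], max_mm: int):
    """Double-loop Hamming scan; returns {(subfamily, pos, strand): mismatches}."""
    out = {}
    for sub, cons in consensi.items():
        L = len(read_seq)
        if L > len(cons):
            continue
        for strand, probe in (("+", read_seq), ("-", rc(read_seq))):
            for pos in range(len(cons) - L + 1):
                mm = sum(1 for a, b in zip(probe, cons[pos : pos + L]) if a != b)
                if mm <= max_mm:
                    out[(sub, pos, strand)] = mm
    return out


def naive_overlap_count(calls, reference) -> int:
    """All-pairs >= 1 bp overlap count of calls against reference intervals."""
    n = 0
    for c in calls:
        for chrom, start, end in reference:
            if chrom == c.chrom and start < c.end and c.start < end:
                n += 1
                break
    return n
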