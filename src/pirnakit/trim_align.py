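"""Zero-mismatch genomic alignment with iterative 3'-end trimming.

Small RNAs frequently carry short non-templated 3' tails (added after
transcription, absent from the genome), so an exact-match aligner misses
them.  The aligner here retries each unaligned read after removing one
3'-terminal nucleotide at a time, up to three nucleotides; the first trim
level that yields at least one exact genomic hit is accepted and all hits
at that level are reported.

Multimapping is handled by 1/N weighting: a read with N genomic placements
contributes weight 1/N to each, stored as the exact rational ``1/n_hits``
so that read mass is conserved without floating-point drift.  Reads with
more than ``max_hits`` placements (default 10,000) are flagged ``over_cap``
and excluded from weighted statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, NamedTuple

from .io_formats import CollapsedRead

__all__ = [
    "GenomeIndex",
    "AlignmentHit",
    "AlignResult",
    "AlignmentReport",
    "build_index",
    "iterative_trim_align",
    "align_library",
    "assign_weights",
    "revcomp",
    "write_sam",
    "write_hit_table",
    "read_hit_table",
]

MIN_QUERY_LEN = 15  # shortest query the index answers; also the seed k-mer size
MAX_TRIM = 3
DEFAULT_MAX_HITS = 10_000

_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


class ExactMatches(NamedTuple):
    hits: list[tuple[str, int, str]]  # (chrom, start, strand), forward coordinates
    over_cap: bool


class GenomeIndex:
    """Exact-substring index over both strands of a genome.

    A k-mer (k = 15) position table seeds candidate placements; candidates
    are verified by direct string comparison, so the answer set equals a
    naive scan.  Genome positions containing N never match (queries are
    N-free by contract).
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("empty genome")
        if len(set(sequences)) != len(sequences):
            raise ValueError("duplicate chromosome names")
        self.sequences = {name: seq.upper() for name, seq in sequences.items()}
        self.lengths = {name: len(seq) for name, seq in self.sequences.items()}
        k = MIN_QUERY_LEN
        seeds: dict[str, list[tuple[str, int]]] = {}
        for chrom in sorted(self.sequences):
            seq = self.sequences[chrom]
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                seeds.setdefault(kmer, []).append((chrom, i))
        self._seeds = seeds

    def find_exact(self, query: str, max_hits: int = DEFAULT_MAX_HITS) -> ExactMatches:
        """All exact occurrences of ``query`` on both strands.

        Minus-strand hits are reported on forward-strand coordinates of the
        matched interval (the read's 5' end is then at ``start + len - 1``).
        If the number of occurrences exceeds ``max_hits`` the read is
        flagged over_cap and no hits are returned.
        """
        if len(query) < MIN_QUERY_LEN:
            raise ValueError(
                f"query length {len(query)} below index minimum {MIN_QUERY_LEN}"
            )
        if not set(query) <= set("ACGT"):
            raise ValueError(f"query has non-ACGT characters: {query!r}")
        hits: list[tuple[str, int, str]] = []
        L = len(query)
        for strand, probe in (("+", query), ("-", revcomp(query))):
            for chrom, pos in self._seeds.get(probe[:MIN_QUERY_LEN], ()):
                if self.sequences[chrom][pos : pos + L] == probe:
                    hits.append((chrom, pos, strand))
        if len(hits) > max_hits:
            return ExactMatches([], True)
        hits.sort()
        return ExactMatches(hits, False)


def build_index(genome: dict[str, str]) -> GenomeIndex:
    """Build a :class:`GenomeIndex` from a chrom -> sequence mapping."""
    return GenomeIndex(genome)


@dataclass(frozen=True)
class AlignmentHit:
    """One genomic placement of a (possibly 3'-trimmed) read."""

    read_id: str
    chrom: str
    start: int
    end: int  # half-open; end - start = read length - trim
    strand: str
    trim: int
    n_hits: int

    @property
    def weight(self) -> Fraction:
        return Fraction(1, self.n_hits)

    @property
    def five_prime(self) -> int:
        """Forward-strand coordinate of the read's 5' end."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass(frozen=True)
class AlignResult:
    read_id: str
    status: str  # aligned | unaligned | over_cap | too_short
    hits: tuple[AlignmentHit, ...] = ()


@dataclass
class AlignmentReport:
    """Per-library tallies from the trim-alignment loop (copy-weighted)."""

    n_reads: int = 0
    n_copies: int = 0
    aligned_copies: int = 0
    unaligned_copies: int = 0
    over_cap_copies: int = 0
    too_short_copies: int = 0
    copies_by_trim: dict[int, int] = field(default_factory=dict)


def iterative_trim_align(
    read: CollapsedRead,
    index: GenomeIndex,
    max_trim: int = MAX_TRIM,
    max_hits: int = DEFAULT_MAX_HITS,
) -> AlignResult:
    """Align one read exactly, retrying with 1..``max_trim`` 3' nt removed.

    Trim levels are attempted in order 0, 1, 2, 3 and the loop stops at the
    first level with >= 1 exact hit; every hit then carries that trim value
    and ``n_hits`` = number of placements at that level.  A trim that would
    leave fewer than 15 nt is not attempted.
    """
    seq = read.sequence
    for trim in range(max_trim + 1):
        if len(seq) - trim < MIN_QUERY_LEN:
            return AlignResult(read.id, "too_short")
        query = seq[: len(seq) - trim] if trim else seq
        matches = index.find_exact(query, max_hits=max_hits)
        if matches.over_cap:
            return AlignResult(read.id, "over_cap")
        if matches.hits:
            n = len(matches.hits)
            hits = tuple(
                AlignmentHit(read.id, chrom, pos, pos + len(query), strand, trim, n)
                for chrom, pos, strand in matches.hits
            )
            return AlignResult(read.id, "aligned", hits)
    return AlignResult(read.id, "unaligned")


def align_library(
    reads: Iterable[CollapsedRead],
    index: GenomeIndex,
    max_trim: int = MAX_TRIM,
    max_hits: int = DEFAULT_MAX_HITS,
) -> tuple[list[AlignmentHit], AlignmentReport]:
    """Align a collapsed library; returns all hits plus a run report.

    Hit order is (chrom, start, strand, read_id) lexicographic for
    byte-stable downstream output.
    """
    report = AlignmentReport()
    all_hits: list[AlignmentHit] = []
    for read in reads:
        report.n_reads += 1
        report.n_copies += read.count
        res = iterative_trim_align(read, index, max_trim=max_trim, max_hits=max_hits)
        if res.status == "aligned":
            report.aligned_copies += read.count
            trim = res.hits[0].trim
            report.copies_by_trim[trim] = report.copies_by_trim.get(trim, 0) + read.count
            all_hits.extend(res.hits)
        elif res.status == "over_cap":
            report.over_cap_copies += read.count
        elif res.status == "too_short":
            report.too_short_copies += read.count
        else:
            report.unaligned_copies += read.count
    all_hits.sort(key=lambda h: (h.chrom, h.start, h.strand, h.read_id))
    return all_hits, report


def assign_weights(hits: list[AlignmentHit]) -> list[AlignmentHit]:
    """Re-derive 1/N weights for the hits of a single read at one trim level.

    Provided for hit lists assembled outside :func:`iterative_trim_align`
    (e.g. re-read from a table with stale N).  Weights sum to exactly 1.
    """
    if not hits:
        raise ValueError("empty hit list")
    if len({(h.read_id, h.trim) for h in hits}) != 1:
        raise ValueError("hits must come from one read at one trim level")
    n = len(hits)
    return [
        AlignmentHit(h.read_id, h.chrom, h.start, h.end, h.strand, h.trim, n)
        for h in hits
    ]


# ---------------------------------------------------------------------------
# Interchange formats

_HIT_COLUMNS = ["read_id", "chrom", "start", "end", "strand", "trim", "n_hits"]


def write_hit_table(hits: Iterable[AlignmentHit], path) -> None:
    """Write hits as the canonical TSV interchange (weight derived from N)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("\t".join(_HIT_COLUMNS) + "\n")
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.chrom}\t{h.start}\t{h.end}\t{h.strand}\t{h.trim}\t{h.n_hits}\n"
            )


def read_hit_table(path) -> list[AlignmentHit]:
    hits = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _HIT_COLUMNS:
            raise ValueError(f"unexpected hit table header: {header}")
        for line in fh:
            rid, chrom, start, end, strand, trim, n = line.rstrip("\n").split("\t")
            hits.append(
                AlignmentHit(rid, chrom, int(start), int(end), strand, int(trim), int(n))
            )
    return hits


def write_sam(
    hits: Iterable[AlignmentHit],
    reads: dict[str, CollapsedRead],
    genome_lengths: dict[str, int],
    path,
) -> None:
    """Optional SAM output (unsorted; tags XT=trim, XN=n_hits, XW=weight)."""
    import pysam

    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": chrom, "LN": length}
                for chrom, length in sorted(genome_lengths.items())
            ],
        }
    )
    refid = {chrom: i for i, chrom in enumerate(sorted(genome_lengths))}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for h in hits:
            read = reads[h.read_id]
            aligned_len = h.end - h.start
            seg = pysam.AlignedSegment(header)
            seg.query_name = h.read_id
            seg.reference_id = refid[h.chrom]
            seg.reference_start = h.start
            seg.mapping_quality = 255
            seq = read.sequence[:aligned_len]
            if h.strand == "-":
                seg.flag = 16
                seq = revcomp(seq)
            seg.query_sequence = seq
            seg.cigarstring = f"{aligned_len}M"
            seg.set_tags(
                [
                    ("XT", h.trim, "i"),
                    ("XN", h.n_hits, "i"),
                    ("XW", float(h.weight), "f"),
                ]
            )
            out.write(seg)
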