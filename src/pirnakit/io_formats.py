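"""Readers, writers and read collapsing for the small-RNA pipeline.

Supported external formats: FASTQ (plain or gzip), FASTA, BED6 with two
optional extra columns (subfamily, class), RepeatMasker ``.out`` tables and
TSV reports.  All genomic coordinates are 0-based half-open internally;
RepeatMasker's 1-based inclusive coordinates are converted on load.

Raw libraries are collapsed into unique sequences with copy counts so that
multimapper 1/N weighting is well defined per unique sequence.
"""
from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "CollapsedRead",
    "FilterReport",
    "TEInterval",
    "TEAnnotation",
    "ExpressionTable",
    "read_fastq",
    "collapse_reads",
    "read_fasta",
    "read_te_annotation",
    "read_expression_table",
    "write_expression_table",
    "write_bed",
    "read_bed_intervals",
    "write_tsv",
]

TE_CLASSES = ("LINE", "SINE", "LTR", "DNA", "Other")

#: float formatting used by every writer, so identical inputs give identical bytes
FLOAT_FMT = "%.6g"


@dataclass(frozen=True)
class CollapsedRead:
    """A unique small-RNA sequence and the number of library copies it had."""

    id: str
    sequence: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError(f"count must be >= 1, got {self.count}")
        if not set(self.sequence) <= set("ACGTN"):
            raise ValueError(f"sequence has non-ACGTN characters: {self.sequence!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterReport:
    """Counts of raw reads kept and dropped, by reason."""

    n_input: int = 0
    n_kept: int = 0
    too_short: int = 0
    too_long: int = 0
    low_quality: int = 0
    contains_n: int = 0

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "too_short": self.too_short,
            "too_long": self.too_long,
            "low_quality": self.low_quality,
            "contains_n": self.contains_n,
        }


@dataclass(frozen=True)
class TEInterval:
    chrom: str
    start: int
    end: int
    strand: str
    subfamily: str
    te_class: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"interval start >= end: {self.chrom}:{self.start}-{self.end}"
            )
        if not self.subfamily:
            raise ValueError("empty subfamily name")
        if self.te_class not in TE_CLASSES:
            raise ValueError(f"unknown TE class {self.te_class!r}")


@dataclass
class TEAnnotation:
    """Genomic TE intervals by subfamily, plus optional consensus sequences."""

    intervals: list[TEInterval] = field(default_factory=list)
    consensi: dict[str, str] = field(default_factory=dict)

    @property
    def subfamilies(self) -> list[str]:
        return sorted({iv.subfamily for iv in self.intervals} | set(self.consensi))


@dataclass
class ExpressionTable:
    """Samples x genes non-negative expression matrix with group labels.

    ``data`` is indexed by sample id; ``groups`` maps sample id -> group label.
    """

    data: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing values in expression table, genes: {bad}")
        if not self.data.index.equals(self.groups.index):
            raise ValueError("groups index does not match sample index")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    @property
    def genes(self) -> list[str]:
        return list(self.data.columns)


# ---------------------------------------------------------------------------
# FASTQ / FASTA


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fastq(
    path,
    min_len: int = 15,
    max_len: int = 50,
    min_qual: int = 20,
) -> tuple[list[str], FilterReport]:
    """Read a FASTQ file and quality/length-filter the reads.

    A read is dropped if any base quality is below ``min_qual``, if its
    length falls outside ``[min_len, max_len]``, or if it contains N (exact
    match alignment cannot place it).  Returns the kept sequences (uppercase)
    and a :class:`FilterReport`.
    """
    report = FilterReport()
    kept: list[str] = []
    with _open_text(path) as fh:
        parser = SeqIO.parse(fh, "fastq")
        idx = 0
        while True:
            try:
                rec = next(parser)
            except StopIteration:
                break
            except ValueError as exc:
                raise ValueError(f"malformed FASTQ record at index {idx}: {exc}") from exc
            idx += 1
            report.n_input += 1
            seq = str(rec.seq).upper()
            quals = rec.letter_annotations["phred_quality"]
            if len(seq) < min_len:
                report.too_short += 1
            elif len(seq) > max_len:
                report.too_long += 1
            elif "N" in seq:
                report.contains_n += 1
            elif quals and min(quals) < min_qual:
                report.low_quality += 1
            else:
                report.n_kept += 1
                kept.append(seq)
    return kept, report


def collapse_reads(reads: Iterable[str]) -> list[CollapsedRead]:
    """Collapse sequences into unique reads with counts.

    Output is sorted by descending count, then lexicographic sequence, and
    ids are assigned in that (deterministic) order.  Counts sum to the input
    size exactly.
    """
    tally = Counter(reads)
    ordered = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    return [
        CollapsedRead(id=f"u{i:06d}", sequence=seq, count=n)
        for i, (seq, n) in enumerate(ordered)
    ]


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered name -> uppercase sequence mapping."""
    out: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate sequence name {rec.id!r}")
            out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ValueError(f"no sequences in {path}")
    return out


def write_fasta(sequences: Mapping[str, str], path, width: int = 80) -> None:
    with open(path, "w", newline="\n") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# TE annotation

# crude fall-back used only when a BED file carries no explicit class column
_CLASS_PREFIXES = (
    ("L1", "LINE"), ("L2", "LINE"), ("LINE", "LINE"), ("CR1", "LINE"),
    ("Alu", "SINE"), ("MIR", "SINE"), ("SINE", "SINE"), ("SVA", "SINE"),
    ("LTR", "LTR"), ("ERV", "LTR"), ("HERV", "LTR"), ("MLT", "LTR"), ("THE", "LTR"),
    ("DNA", "DNA"), ("hAT", "DNA"), ("Charlie", "DNA"), ("Tigger", "DNA"), ("MER", "DNA"),
)


def guess_te_class(subfamily: str) -> str:
    for prefix, cls in _CLASS_PREFIXES:
        if subfamily.startswith(prefix):
            return cls
    return "Other"


def _normalize_class(raw: str) -> str:
    head = raw.split("/")[0]
    return head if head in TE_CLASSES else guess_te_class(head)


def read_te_annotation(path, dialect: str = "bed6+2") -> TEAnnotation:
    """Load TE intervals from BED6(+2) or a RepeatMasker ``.out`` file.

    BED columns: chrom, start, end, name, score, strand[, subfamily, class].
    When the two extra columns are absent the name column is the subfamily
    and the class is guessed from its prefix.  RepeatMasker coordinates
    (1-based inclusive) are converted to 0-based half-open.
    """
    intervals: list[TEInterval] = []
    if dialect == "bed6+2":
        with _open_text(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                cols = line.split("\t") if "\t" in line else line.split()
                if len(cols) < 6:
                    raise ValueError(f"BED line with fewer than 6 columns: {line!r}")
                chrom, start, end, name, _score, strand = cols[:6]
                subfamily = cols[6] if len(cols) > 6 else name
                te_class = _normalize_class(cols[7]) if len(cols) > 7 else guess_te_class(subfamily)
                intervals.append(
                    TEInterval(chrom, int(start), int(end), strand, subfamily, te_class)
                )
    elif dialect == "repeatmasker_out":
        with _open_text(path) as fh:
            for line in fh:
                cols = line.split()
                # skip the three header lines and blanks
                if not cols or not cols[0].isdigit():
                    continue
                chrom = cols[4]
                start = int(cols[5]) - 1  # 1-based inclusive -> 0-based half-open
                end = int(cols[6])
                strand = "+" if cols[8] == "+" else "-"  # RM uses 'C' for complement
                subfamily = cols[9]
                te_class = _normalize_class(cols[10])
                intervals.append(TEInterval(chrom, start, end, strand, subfamily, te_class))
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    return TEAnnotation(intervals=intervals)


# ---------------------------------------------------------------------------
# Expression tables


def read_expression_table(path) -> ExpressionTable:
    """Read a TSV of sample, group, gene columns into an :class:`ExpressionTable`."""
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    if df.columns[0] != "sample" or df.columns[1] != "group":
        raise ValueError("expression table must start with 'sample' and 'group' columns")
    if df["sample"].duplicated().any():
        dupes = df.loc[df["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    df = df.set_index("sample")
    groups = df.pop("group")
    values = df.apply(pd.to_numeric, errors="coerce")
    bad = values.columns[values.isna().any()].tolist()
    if bad:
        raise ValueError(f"non-numeric or missing cells in genes: {bad}")
    return ExpressionTable(data=values, groups=groups)


def write_expression_table(table: ExpressionTable, path) -> None:
    out = table.data.copy()
    out.insert(0, "group", table.groups)
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT, lineterminator="\n")


# ---------------------------------------------------------------------------
# BED / TSV writers


def write_bed(records: Sequence, path) -> None:
    """Write cluster calls (or any objects with chrom/start/end) as BED.

    Cluster calls get four extra columns: weighted_reads, density_p,
    frac_1T_or_10A, main_strand_frac.
    """
    rows = []
    for i, rec in enumerate(records):
        name = getattr(rec, "name", f"cluster{i:04d}")
        strand = getattr(rec, "strand", ".")
        row = [rec.chrom, str(rec.start), str(rec.end), name, "0", strand]
        if hasattr(rec, "weighted_reads"):
            row += [
                FLOAT_FMT % rec.weighted_reads,
                FLOAT_FMT % rec.density_p,
                FLOAT_FMT % rec.frac_1T_or_10A,
                FLOAT_FMT % rec.main_strand_frac,
            ]
        rows.append("\t".join(row))
    with open(path, "w", newline="\n") as fh:
        for row in sorted(rows):
            fh.write(row + "\n")


def read_bed_intervals(path) -> list[tuple[str, int, int]]:
    """Read (chrom, start, end) triples from a BED-like file."""
    out = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            start, end = int(cols[1]), int(cols[2])
            if start >= end:
                raise ValueError(f"interval start >= end in line {line!r}")
            out.append((cols[0], start, end))
    return out


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Write a report DataFrame with deterministic float formatting."""
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index, lineterminator="\n")


def write_collapsed_reads(reads: Sequence[CollapsedRead], path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("id\tsequence\tcount\n")
        for r in reads:
            fh.write(f"{r.id}\t{r.sequence}\t{r.count}\n")


def read_collapsed_reads(path) -> list[CollapsedRead]:
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != "id\tsequence\tcount":
            raise ValueError(f"unexpected collapsed-read header: {header!r}")
        for line in fh:
            rid, seq, count = line.rstrip("\n").split("\t")
            out.append(CollapsedRead(id=rid, sequence=seq, count=int(count)))
    return out
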