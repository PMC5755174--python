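"""Synthetic genomes, small-RNA libraries and expression tables.

The generator produces toy data with the statistical structure the
analysis pipeline assumes, so that every stage can be verified against
known ground truth without any external downloads:

* a random background genome with TE consensus sequences, diverged TE
  copies planted on either strand, reserved piRNA-cluster intervals, and
  fixed miRNA-like / tRF-like donor loci;
* a small-RNA library with piRNA-like reads (25-31 nt genomic span,
  tunable 1U fraction, optional opposite-strand ping-pong partners with
  an exact 10-nt 5'-5' overlap, non-templated 3' tails of 0-5 nt whose
  bases are guaranteed to mismatch the genome), 22-nt miRNA-like and
  32-nt tRF-like contaminant bands, and uniform background reads;
* expression tables in which a latent germ-cell-content variable drives
  the piRNA-pathway genes plus DDX4/DAZL while an independent latent
  GCNIS/TGCT-content variable drives NANOG/POU5F1 and the miR-302/371
  marker rows, with ACTB as a near-constant housekeeping reference.

A single seed determines everything; each stage draws from its own
derived substream so stages can be regenerated independently.

Note on the 1U/10A constraints: reads are genome-templated (so they
align exactly), which means the biases are imposed by site selection,
not by editing read bases.  With an exact 10-nt 5'-5' overlap the
partner's 10th base is the complement-of-complement of the primary
read's first base — the same genomic letter — so partner 10A and
primary 1U cannot be controlled independently.  Mirroring the biology
(uridine bias marks primary piRNAs, adenine-10 marks ping-pong
partners), unpaired reads are placed with a 5'-T probability ``p_1U``
and pair anchors with probability ``p_10A``; the partner's 10th base is
then A with probability ``p_10A`` and its own first base is left
unconstrained.  Applying a 10A constraint to unpaired reads would
anchor plus-strand 5' ends and minus-strand 10th bases on the same
genomic T positions and manufacture a spurious 10-nt overlap excess in
libraries with no ping-pong at all.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io_formats import CollapsedRead, TEAnnotation, TEInterval, ExpressionTable
from .trim_align import revcomp
from .marker_correlation import DEFAULT_GENE_SETS

__all__ = [
    "TEFamilyConfig",
    "LibraryConfig",
    "PiRNAModel",
    "ExpressionModel",
    "SimConfig",
    "SimTruth",
    "ReadTruth",
    "SyntheticGenome",
    "build_genome",
    "simulate_library",
    "simulate_expression",
    "germline_preset",
    "somatic_preset",
    "write_fastq",
    "config_from_yaml",
]

_BASES = "ACGT"
_STAGES = {"genome": 11, "library": 23, "expression": 37}


def _rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng([seed, _STAGES[stage]])


def _random_seq(rng: np.random.Generator, n: int) -> str:
    arr = np.frombuffer(b"ACGT", dtype=np.uint8)[rng.integers(0, 4, n)]
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class TEFamilyConfig:
    name: str
    te_class: str
    consensus_len: int
    n_copies: int


@dataclass(frozen=True)
class LibraryConfig:
    n_reads: int = 5000
    frac_pirna: float = 0.6
    frac_mirna: float = 0.15
    frac_trf: float = 0.1
    # remainder of the fractions is uniform background

    def __post_init__(self):
        total = self.frac_pirna + self.frac_mirna + self.frac_trf
        if total > 1.0 + 1e-9:
            raise ValueError(f"library class fractions sum to {total} > 1")

    @property
    def frac_background(self) -> float:
        return max(0.0, 1.0 - self.frac_pirna - self.frac_mirna - self.frac_trf)


def _default_length_probs() -> dict[int, float]:
    # genomic-span law over 25..31, mode 29
    return {25: 0.05, 26: 0.08, 27: 0.12, 28: 0.18, 29: 0.30, 30: 0.17, 31: 0.10}


def _default_tail_probs() -> dict[int, float]:
    return {0: 0.70, 1: 0.15, 2: 0.10, 3: 0.05}


@dataclass(frozen=True)
class PiRNAModel:
    length_probs: dict[int, float] = field(default_factory=_default_length_probs)
    p_1U: float = 0.8  # P(5' base is T) for unpaired piRNA reads
    p_10A: float = 0.7  # P(10th base is A) for ping-pong partners (anchors pairs)
    pingpong_fraction: float = 0.5
    tail_probs: dict[int, float] = field(default_factory=_default_tail_probs)
    te_read_fraction: float = 0.3  # piRNA reads drawn from TE copies instead of clusters

    def __post_init__(self):
        for name, probs in (("length_probs", self.length_probs), ("tail_probs", self.tail_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")
        for p in (self.p_1U, self.p_10A, self.pingpong_fraction, self.te_read_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(t < 0 or t > 5 for t in self.tail_probs):
            raise ValueError("tail lengths must be in 0..5")


@dataclass(frozen=True)
class ExpressionModel:
    n_samples_per_group: int = 10
    germ_latent_loading: float = 0.95
    tgct_latent_loading: float = 0.9
    noise_sd: float = 0.1  # in latent units, per gene

    def __post_init__(self):
        if self.n_samples_per_group < 3:
            raise ValueError("need >= 3 samples per group")
        if self.germ_latent_loading <= 0 or self.tgct_latent_loading <= 0:
            raise ValueError("latent loadings must be positive")


def _default_te_families() -> tuple[TEFamilyConfig, ...]:
    return (
        TEFamilyConfig("L1toy", "LINE", 3000, 4),
        TEFamilyConfig("AluToy", "SINE", 300, 10),
    )


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    genome_len: int = 200_000
    chrom_name: str = "chr1"
    te_families: tuple[TEFamilyConfig, ...] = field(default_factory=_default_te_families)
    te_divergence: float = 0.05
    n_clusters: int = 3
    cluster_len: int = 5000
    n_mirna_loci: int = 6
    n_trf_loci: int = 4
    library: LibraryConfig = field(default_factory=LibraryConfig)
    pirna: PiRNAModel = field(default_factory=PiRNAModel)
    expression: ExpressionModel = field(default_factory=ExpressionModel)


def germline_preset(seed: int = 1, **overrides) -> SimConfig:
    """A germline-like testis library: strong piRNA class with ping-pong."""
    return replace(SimConfig(seed=seed), **overrides)


def somatic_preset(seed: int = 1, **overrides) -> SimConfig:
    """A somatic-like library: no piRNA class, only miRNA/tRF/background."""
    cfg = SimConfig(
        seed=seed,
        library=LibraryConfig(frac_pirna=0.0, frac_mirna=0.45, frac_trf=0.2),
    )
    return replace(cfg, **overrides)


def config_from_yaml(path) -> SimConfig:
    """Build a SimConfig from a YAML file of (nested) field overrides."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "te_families" in kwargs:
        kwargs["te_families"] = tuple(TEFamilyConfig(**f) for f in kwargs["te_families"])
    for key, cls in (("library", LibraryConfig), ("pirna", PiRNAModel), ("expression", ExpressionModel)):
        if key in kwargs:
            sub = dict(kwargs[key])
            for probs_key in ("length_probs", "tail_probs"):
                if probs_key in sub:
                    sub[probs_key] = {int(k): float(v) for k, v in sub[probs_key].items()}
            kwargs[key] = cls(**sub)
    return SimConfig(**kwargs)


# ---------------------------------------------------------------------------
# Ground truth containers


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    provenance: str  # cluster | te | mirna | trf | background
    source: str  # cluster/TE/donor name, or "genome" for background
    chrom: str
    strand: str
    five_prime: int
    genomic_len: int
    tail_len: int
    partner_id: str  # "" when unpaired
    pair_role: str = ""  # primary | secondary | "" when unpaired


@dataclass
class SimTruth:
    clusters: list[tuple[str, int, int]] = field(default_factory=list)
    mirna_loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    trf_loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    reads: list[ReadTruth] = field(default_factory=list)


@dataclass
class SyntheticGenome:
    sequences: dict[str, str]
    annotation: TEAnnotation
    truth: SimTruth


# ---------------------------------------------------------------------------
# Genome construction

_EDGE_MARGIN = 100
_PAD = 50  # clearance between planted features


class _Placer:
    """Samples non-overlapping intervals on one chromosome."""

    def __init__(self, rng: np.random.Generator, genome_len: int):
        self.rng = rng
        self.genome_len = genome_len
        self.occupied: list[tuple[int, int]] = []

    def place(self, length: int, tries: int = 2000) -> int:
        lo, hi = _EDGE_MARGIN, self.genome_len - length - _EDGE_MARGIN
        if hi <= lo:
            raise ValueError("requested insertions exceed genome capacity")
        for _ in range(tries):
            start = int(self.rng.integers(lo, hi))
            if all(start >= e + _PAD or start + length + _PAD <= s for s, e in self.occupied):
                self.occupied.append((start, start + length))
                return start
        raise ValueError("requested insertions exceed genome capacity")


def _diverge(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    mask = rng.random(len(arr)) < rate
    for i in np.nonzero(mask)[0]:
        alternatives = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = alternatives[int(rng.integers(0, 3))]
    return arr.tobytes().decode("ascii")


def build_genome(config: SimConfig) -> SyntheticGenome:
    """Random genome with planted TE copies, reserved clusters and donor loci.

    TE copies are the family consensus mutated at ``te_divergence`` per
    base and inserted on a random strand; cluster intervals are reserved
    disjoint from TE copies (their sequence stays background).  Fully
    deterministic for a fixed config.
    """
    rng = _rng(config.seed, "genome")
    chrom = config.chrom_name
    genome = bytearray(_random_seq(rng, config.genome_len), "ascii")
    placer = _Placer(rng, config.genome_len)

    consensi: dict[str, str] = {}
    intervals: list[TEInterval] = []
    for fam in config.te_families:
        consensi[fam.name] = _random_seq(rng, fam.consensus_len)
        for _ in range(fam.n_copies):
            start = placer.place(fam.consensus_len)
            strand = "+" if rng.random() < 0.5 else "-"
            copy = _diverge(rng, consensi[fam.name], config.te_divergence)
            if strand == "-":
                copy = revcomp(copy)
            genome[start : start + fam.consensus_len] = copy.encode("ascii")
            intervals.append(
                TEInterval(chrom, start, start + fam.consensus_len, strand, fam.name, fam.te_class)
            )

    truth = SimTruth()
    for _ in range(config.n_clusters):
        start = placer.place(config.cluster_len)
        truth.clusters.append((chrom, start, start + config.cluster_len))
    for _ in range(config.n_mirna_loci):
        start = placer.place(22)
        truth.mirna_loci.append((chrom, start, start + 22, "+" if rng.random() < 0.5 else "-"))
    for _ in range(config.n_trf_loci):
        start = placer.place(32)
        truth.trf_loci.append((chrom, start, start + 32, "+" if rng.random() < 0.5 else "-"))

    intervals.sort(key=lambda iv: (iv.chrom, iv.start))
    truth.clusters.sort()
    annotation = TEAnnotation(intervals=intervals, consensi=consensi)
    return SyntheticGenome({chrom: genome.decode("ascii")}, annotation, truth)


# ---------------------------------------------------------------------------
# Library simulation


def _sample_from_probs(rng: np.random.Generator, probs: dict[int, float]) -> int:
    keys = sorted(probs)
    return int(rng.choice(keys, p=[probs[k] for k in keys]))


def _tail_bases(rng: np.random.Generator, seq: str, chrom_seq: str, strand: str,
                start: int, end: int, tail_len: int) -> str:
    """Append ``tail_len`` bases each guaranteed to mismatch the genome.

    The mismatch is evaluated in read space at the position the next
    templated base would occupy, so the trim loop is exercised exactly
    ``tail_len`` times.
    """
    tail = []
    for i in range(tail_len):
        if strand == "+":
            genomic = chrom_seq[end + i]
        else:
            genomic = revcomp(chrom_seq[start - 1 - i])
        choices = [b for b in _BASES if b != genomic]
        tail.append(choices[int(rng.integers(0, 3))])
    return seq + "".join(tail)


def _read_at(chrom_seq: str, strand: str, five_prime: int, length: int) -> tuple[str, int, int]:
    """Genome-templated read sequence and its forward-coordinate interval."""
    if strand == "+":
        start, end = five_prime, five_prime + length
        return chrom_seq[start:end], start, end
    start, end = five_prime - length + 1, five_prime + 1
    return revcomp(chrom_seq[start:end]), start, end


def _pick_site(
    rng: np.random.Generator,
    chrom_seq: str,
    lo: int,
    hi: int,
    strand: str,
    length: int,
    want_1u: bool | None,
    want_10a: bool | None = None,
    tries: int = 500,
) -> int:
    """Rejection-sample a 5' coordinate matching the base constraints.

    ``lo``/``hi`` bound the forward-strand start of the read interval;
    a constraint of None is not enforced.  Falls back to the last draw
    if the constraints cannot be met locally.
    """
    five_prime = lo
    for _ in range(tries):
        start = int(rng.integers(lo, hi))
        five_prime = start if strand == "+" else start + length - 1
        read, _, _ = _read_at(chrom_seq, strand, five_prime, length)
        if want_1u is not None and (read[0] == "T") != want_1u:
            continue
        if want_10a is not None and (read[9] == "A") != want_10a:
            continue
        return five_prime
    return five_prime


def simulate_library(
    genome: SyntheticGenome,
    config: SimConfig,
) -> tuple[list[tuple[str, str]], SimTruth]:
    """Simulate a collapsed-free raw read list (id, sequence) plus truth.

    piRNA reads are sampled from cluster or TE loci with the configured
    genomic-span law; a ``pingpong_fraction`` of them come in pairs with a
    10-nt 5'-5' overlap on opposite strands; non-templated tails are
    appended with guaranteed-mismatching bases.  miRNA-like (22 nt) and
    tRF-like (32 nt) reads re-use fixed donor loci; background reads are
    uniform.  Deterministic for a fixed config.
    """
    rng = _rng(config.seed, "library")
    lib = config.library
    model = config.pirna
    chrom = config.chrom_name
    chrom_seq = genome.sequences[chrom]
    truth = SimTruth(
        clusters=list(genome.truth.clusters),
        mirna_loci=list(genome.truth.mirna_loci),
        trf_loci=list(genome.truth.trf_loci),
    )

    n_pi = round(lib.n_reads * lib.frac_pirna)
    n_mi = round(lib.n_reads * lib.frac_mirna)
    n_trf = round(lib.n_reads * lib.frac_trf)
    n_bg = lib.n_reads - n_pi - n_mi - n_trf
    if n_pi > 0 and not truth.clusters and model.te_read_fraction < 1.0:
        raise ValueError("frac_pirna > 0 but the genome has no planted clusters")
    te_loci = [
        (iv.start, iv.end)
        for iv in genome.annotation.intervals
        if iv.end - iv.start >= 60
    ]

    n_paired = int(rng.binomial(n_pi, model.pingpong_fraction))
    if n_paired % 2:
        n_paired -= 1
    n_pairs = n_paired // 2
    n_single = n_pi - n_paired

    reads: list[tuple[str, str]] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        rid = f"r{counter:06d}"
        counter += 1
        return rid

    def pirna_site(length: int) -> tuple[str, int, int, str]:
        """Choose a source locus and admissible read-start bounds.

        Loci are planted >= 100 bp from genome ends, which covers the
        largest possible partner overhang (21 bp) and tail (5 bp), so the
        read start may range over the whole locus.
        """
        use_te = te_loci and rng.random() < model.te_read_fraction
        if use_te:
            s, e = te_loci[int(rng.integers(0, len(te_loci)))]
            source = "te"
        else:
            _, s, e = truth.clusters[int(rng.integers(0, len(truth.clusters)))]
            source = "cluster"
        lo, hi = s, e - length
        if hi <= lo:  # degenerate locus; fall back to its start
            lo, hi = s, s + 1
        return source, lo, hi, ("+" if rng.random() < 0.5 else "-")

    def emit_pirna(paired: bool) -> None:
        length = _sample_from_probs(rng, model.length_probs)
        source, lo, hi, strand = pirna_site(length)
        provenance = "te" if source == "te" else "cluster"
        tail = _sample_from_probs(rng, model.tail_probs)
        if not paired:
            want_1u = rng.random() < model.p_1U
            fp = _pick_site(rng, chrom_seq, lo, hi, strand, length, want_1u)
            seq, start, end = _read_at(chrom_seq, strand, fp, length)
            full = _tail_bases(rng, seq, chrom_seq, strand, start, end, tail)
            rid = next_id()
            reads.append((rid, full))
            truth.reads.append(
                ReadTruth(rid, provenance, source, chrom, strand, fp, length, tail, "", "")
            )
            return
        # pair anchor: the primary's 5' base is the partner's 10th base
        # (complemented twice), so one draw sets primary 1U = partner 10A
        want_anchor_t = rng.random() < model.p_10A
        fp = _pick_site(rng, chrom_seq, lo, hi, strand, length, want_anchor_t)
        seq, start, end = _read_at(chrom_seq, strand, fp, length)
        full = _tail_bases(rng, seq, chrom_seq, strand, start, end, tail)
        rid = next_id()
        # partner on the opposite strand, exact 10-nt 5'-5' overlap
        p_len = _sample_from_probs(rng, model.length_probs)
        if strand == "+":
            p_strand, p_fp = "-", fp + 9
        else:
            p_strand, p_fp = "+", fp - 9
        p_seq, p_start, p_end = _read_at(chrom_seq, p_strand, p_fp, p_len)
        p_tail = _sample_from_probs(rng, model.tail_probs)
        p_full = _tail_bases(rng, p_seq, chrom_seq, p_strand, p_start, p_end, p_tail)
        p_rid = next_id()
        reads.append((rid, full))
        reads.append((p_rid, p_full))
        truth.reads.append(
            ReadTruth(rid, provenance, source, chrom, strand, fp, length, tail, p_rid, "primary")
        )
        truth.reads.append(
            ReadTruth(p_rid, provenance, source, chrom, p_strand, p_fp, p_len, p_tail, rid, "secondary")
        )

    for _ in range(n_pairs):
        emit_pirna(paired=True)
    for _ in range(n_single):
        emit_pirna(paired=False)

    def emit_donor(loci, provenance: str, label: str) -> None:
        # skewed donor usage: a few dominant species, like real miRNA libraries
        weights = np.array([2.0 ** -i for i in range(len(loci))])
        weights /= weights.sum()
        idx = int(rng.choice(len(loci), p=weights))
        c, s, e, strand = loci[idx]
        seq = chrom_seq[s:e] if strand == "+" else revcomp(chrom_seq[s:e])
        rid = next_id()
        reads.append((rid, seq))
        fp = s if strand == "+" else e - 1
        truth.reads.append(
            ReadTruth(rid, provenance, f"{label}{idx}", c, strand, fp, e - s, 0, "")
        )

    for _ in range(n_mi):
        emit_donor(truth.mirna_loci, "mirna", "mir")
    for _ in range(n_trf):
        emit_donor(truth.trf_loci, "trf", "trf")

    for _ in range(n_bg):
        length = int(rng.integers(18, 36))
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(_EDGE_MARGIN, len(chrom_seq) - length - _EDGE_MARGIN))
        fp = start if strand == "+" else start + length - 1
        seq, _, _ = _read_at(chrom_seq, strand, fp, length)
        rid = next_id()
        reads.append((rid, seq))
        truth.reads.append(
            ReadTruth(rid, "background", "genome", chrom, strand, fp, length, 0, "")
        )

    return reads, truth


def write_fastq(reads: Iterable[tuple[str, str]], path) -> None:
    """Write (id, sequence) records as FASTQ with a constant quality string."""
    with open(path, "w", newline="\n") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_truth_reads(truth: SimTruth, path) -> None:
    import pandas as pd

    df = pd.DataFrame([vars(r) for r in truth.reads])
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# Expression simulation

GERM_DRIVEN = DEFAULT_GENE_SETS.pathway + DEFAULT_GENE_SETS.germline
TGCT_DRIVEN = DEFAULT_GENE_SETS.tgct + ("MIR302A", "MIR371A")
_GROUPS = ("normal", "adjacent_SE", "adjacent_NS", "tumor_SE", "tumor_NS")
_ACTB_SCALE = 100.0


def simulate_expression(config: SimConfig):
    """Latent-factor expression table mimicking mixed-tissue testis samples.

    Each sample carries a germ-cell-content latent g and an independent
    GCNIS/TGCT-content latent t, set by group: normal testis has high g
    and ~0 t, adjacent tissues intermediate mixtures, tumors ~0 g and
    high t.  Germ-driven genes are ``scale x (loading x g + noise)``,
    TGCT-driven genes likewise from t; ACTB is a constant-scale
    housekeeping gene whose relative noise is 1% of ``noise_sd``.
    Returns the table and a per-sample latent DataFrame.
    """
    import pandas as pd

    rng = _rng(config.seed, "expression")
    model = config.expression
    n = model.n_samples_per_group

    samples, groups, g_lat, t_lat = [], [], [], []
    for group in _GROUPS:
        for i in range(n):
            samples.append(f"{group}_{i:02d}")
            groups.append(group)
            if group == "normal":
                # lognormal spread: bulk-testis pathway expression varies with
                # germ-cell content, giving per-gene relative SD near 90%
                g = rng.lognormal(0.0, 0.75)
                t = abs(rng.normal(0.0, 0.02))
            elif group.startswith("adjacent"):
                g = rng.uniform(0.4, 1.0) if group.endswith("NS") else rng.uniform(0.05, 0.6)
                t = max(0.0, rng.normal(0.45, 0.15))
            else:  # tumors
                g = abs(rng.normal(0.0, 0.02))
                t = max(0.1, rng.normal(1.0, 0.25))
            g_lat.append(g)
            t_lat.append(t)
    g_arr = np.array(g_lat)
    t_arr = np.array(t_lat)

    genes = list(GERM_DRIVEN) + list(TGCT_DRIVEN) + ["ACTB"]
    scales = {gene: float(rng.lognormal(1.0, 0.8)) for gene in genes if gene != "ACTB"}
    values = {}
    for gene in GERM_DRIVEN:
        noise = rng.normal(0.0, model.noise_sd, len(samples))
        values[gene] = np.clip(scales[gene] * (model.germ_latent_loading * g_arr + noise), 0.0, None)
    for gene in TGCT_DRIVEN:
        noise = rng.normal(0.0, model.noise_sd, len(samples))
        values[gene] = np.clip(scales[gene] * (model.tgct_latent_loading * t_arr + noise), 0.0, None)
    actb_noise = rng.normal(0.0, 0.01 * model.noise_sd, len(samples))
    values["ACTB"] = _ACTB_SCALE * (1.0 + actb_noise)

    data = pd.DataFrame(values, index=pd.Index(samples, name="sample"))
    table = ExpressionTable(data=data, groups=pd.Series(groups, index=data.index, name="group"))
    latents = pd.DataFrame({"g": g_arr, "t": t_arr}, index=data.index)
    return table, latents
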