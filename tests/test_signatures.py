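"""pirna_signatures: length bands, 1U/10A, TE coverage, consensus, ping-pong."""
import math
from fractions import Fraction

import numpy as np
import pytest

from pirnakit import pirna_signatures as sig
from pirnakit import trim_align as ta
from pirnakit.io_formats import TEAnnotation, TEInterval

from conftest import make_reads, random_genome
from _oracles import naive_consensus_scan, naive_find_all, naive_subfamily_totals, rc


def _random_seqs(rng, n, length):
    return ["".join(np.array(list("ACGT"))[rng.integers(0, 4, length)]) for _ in range(n)]


class TestLengthDistribution:
    def test_band_examples(self, rng):
        hist = sig.length_distribution(make_reads(_random_seqs(rng, 5, 22)))
        assert hist.frac_mirna_band == 1.0 and hist.frac_pirna_band == 0.0

        reads = make_reads([("T" * 26, 3), ("A" * 30, 1)])
        hist = sig.length_distribution(reads)
        assert hist.frac_pirna_band == 1.0
        assert hist.counts[26] == 3 and hist.n == 4

    def test_empty_input(self):
        hist = sig.length_distribution([])
        assert hist.n == 0 and hist.counts == {}
        assert hist.frac_pirna_band == 0.0

    def test_band_fraction_binomial_recovery(self, rng):
        # 60% of copy mass at 26 nt (piRNA band), rest at 22 nt
        n = 10_000
        in_band = rng.random(n) < 0.6
        seqs = [("ACGT" * 7)[: 26 if b else 22] for b in in_band]
        hist = sig.length_distribution(make_reads(seqs))
        se = math.sqrt(0.6 * 0.4 / n)
        assert abs(hist.frac_pirna_band - 0.6) < 3 * se


class TestNtBias:
    def test_examples(self):
        reads = make_reads([("T" + "A" * 25, 1), ("G" + "A" * 25, 1)])
        stats = sig.nt_bias(reads)
        assert stats.frac_1U == 0.5
        assert stats.frac_10A == 1.0  # both have A at position 10

        single = make_reads([("TGGGGGGGGAG" + "C" * 15, 1)])  # 10th base A
        stats = sig.nt_bias(single)
        assert stats.frac_10A == 1.0 and stats.frac_1U == 1.0

    def test_degenerate_when_no_reads_in_range(self):
        stats = sig.nt_bias(make_reads(["ACGT" * 5]))  # 20 nt, outside 25-31
        assert stats.degenerate and stats.frac_1U is None

    def test_binomial_recovery(self, rng):
        n = 5000
        seqs = [
            ("T" if rng.random() < 0.8 else "G") + "".join(np.array(list("ACG"))[rng.integers(0, 3, 27)])
            for _ in range(n)
        ]
        stats = sig.nt_bias(make_reads(seqs))
        se = math.sqrt(0.8 * 0.2 / n)
        assert abs(stats.frac_1U - 0.8) < 3 * se

    def test_uniform_first_base_quarter(self, rng):
        n = 4000
        seqs = ["".join(np.array(list("ACGT"))[rng.integers(0, 4, 28)]) for _ in range(n)]
        stats = sig.nt_bias(make_reads(seqs))
        se = math.sqrt(0.25 * 0.75 / n)
        assert abs(stats.frac_1U - 0.25) < 3 * se


def _hit(read_id, chrom, start, end, strand="+", n_hits=1, trim=0):
    return ta.AlignmentHit(read_id, chrom, start, end, strand, trim, n_hits)


class TestTECoverage:
    def test_unique_read_in_l1(self):
        reads = {r.id: r for r in make_reads([("T" * 26, 2)])}
        ann = TEAnnotation(intervals=[TEInterval("chr1", 100, 3000, "+", "L1HS", "LINE")])
        cov = sig.te_weighted_coverage([_hit("u000000", "chr1", 500, 526)], reads, ann)
        assert cov.per_subfamily["L1HS"] == 2
        assert cov.te_fraction == 1.0

    def test_one_of_four_hits_in_alu(self):
        count = 4
        reads = {r.id: r for r in make_reads([("T" * 26, count)])}
        ann = TEAnnotation(intervals=[TEInterval("chr1", 100, 400, "+", "AluYa5", "SINE")])
        hits = [
            _hit("u000000", "chr1", 150, 176, n_hits=4),
            _hit("u000000", "chr1", 5000, 5026, n_hits=4),
            _hit("u000000", "chr1", 6000, 6026, n_hits=4),
            _hit("u000000", "chr2", 100, 126, n_hits=4),
        ]
        cov = sig.te_weighted_coverage(hits, reads, ann)
        assert cov.per_subfamily["AluYa5"] == Fraction(1, 4) * count

    def test_double_count_at_subfamily_level_once_globally(self):
        reads = {r.id: r for r in make_reads([("T" * 26, 1)])}
        ann = TEAnnotation(
            intervals=[
                TEInterval("chr1", 100, 200, "+", "L1HS", "LINE"),
                TEInterval("chr1", 150, 300, "-", "AluYa5", "SINE"),
            ]
        )
        cov = sig.te_weighted_coverage([_hit("u000000", "chr1", 140, 166)], reads, ann)
        assert cov.per_subfamily["L1HS"] == 1 and cov.per_subfamily["AluYa5"] == 1
        assert cov.te_total == 1  # counted once in the global fraction

    def test_matches_naive_intersection_oracle(self, rng):
        reads = {r.id: r for r in make_reads([(s, int(rng.integers(1, 4))) for s in _random_seqs(rng, 60, 26)])}
        intervals = []
        for i in range(30):
            start = int(rng.integers(0, 20_000))
            sub = ["L1HS", "AluYa5", "MER1"][i % 3]
            cls = {"L1HS": "LINE", "AluYa5": "SINE", "MER1": "DNA"}[sub]
            intervals.append(TEInterval("chr1", start, start + int(rng.integers(100, 800)), "+", sub, cls))
        hits = []
        for rid in reads:
            n = int(rng.integers(1, 4))
            for _ in range(n):
                start = int(rng.integers(0, 21_000))
                hits.append(_hit(rid, "chr1", start, start + 26, n_hits=n))
        cov = sig.te_weighted_coverage(hits, reads, TEAnnotation(intervals=intervals))
        oracle_sub, oracle_te, oracle_non = naive_subfamily_totals(
            hits, reads, [(iv.chrom, iv.start, iv.end, iv.subfamily) for iv in intervals]
        )
        assert cov.per_subfamily == oracle_sub
        assert cov.te_total == oracle_te and cov.non_te_total == oracle_non

    def test_mass_conservation_exact(self, rng):
        reads = {r.id: r for r in make_reads([(s, int(rng.integers(1, 5))) for s in _random_seqs(rng, 40, 26)])}
        hits = []
        for rid, r in reads.items():
            n = int(rng.integers(1, 6))
            for _ in range(n):
                start = int(rng.integers(0, 10_000))
                hits.append(_hit(rid, "chr1", start, start + 26, n_hits=n))
        ann = TEAnnotation(intervals=[TEInterval("chr1", 2000, 6000, "+", "L1HS", "LINE")])
        cov = sig.te_weighted_coverage(hits, reads, ann)
        assert cov.te_total + cov.non_te_total == sum(r.count for r in reads.values())

    def test_empty_annotation(self):
        reads = {r.id: r for r in make_reads(["T" * 26])}
        cov = sig.te_weighted_coverage([_hit("u000000", "chr1", 0, 26)], reads, TEAnnotation())
        assert cov.te_fraction == 0.0


class TestConsensusAlignment:
    def test_exact_window(self, rng):
        cons = {"L1toy": random_genome(rng, 500)}
        read = make_reads([cons["L1toy"][100:126]])
        hits, _ = sig.align_to_consensus(read, cons)
        exact = [h for h in hits if h.mismatches == 0 and h.strand == "+"]
        assert any(h.position == 100 for h in exact)

    def test_mismatch_threshold(self, rng):
        cons = {"L1toy": random_genome(rng, 500)}
        window = list(cons["L1toy"][100:126])
        for i in (3, 10):  # two substitutions
            window[i] = next(b for b in "ACGT" if b != window[i])
        two = make_reads(["".join(window)])
        hits, _ = sig.align_to_consensus(two, cons)
        assert any(h.position == 100 and h.mismatches == 2 for h in hits)
        for i in (20,):  # third substitution
            window[i] = next(b for b in "ACGT" if b != window[i])
        three = make_reads(["".join(window)])
        hits, _ = sig.align_to_consensus(three, cons)
        assert not any(h.position == 100 and h.strand == "+" for h in hits)

    def test_minus_strand(self, rng):
        cons = {"L1toy": random_genome(rng, 500)}
        read = make_reads([rc(cons["L1toy"][200:228])])
        hits, _ = sig.align_to_consensus(read, cons)
        assert any(h.position == 200 and h.strand == "-" for h in hits)
        # minus-strand 5' end is the rightmost matched base
        h = next(h for h in hits if h.position == 200 and h.strand == "-")
        assert h.five_prime == 227

    def test_read_longer_than_consensus_skipped(self, rng):
        cons = {"short": random_genome(rng, 20)}
        hits, skipped = sig.align_to_consensus(make_reads(["A" * 30]), cons)
        assert hits == [] and skipped == {"short": 1}

    def test_matches_double_loop_oracle(self, rng):
        consensi = {"A": random_genome(rng, 300), "B": random_genome(rng, 200)}
        # half planted (with 0-2 substitutions), half random
        seqs = []
        for _ in range(50):
            src = consensi["A" if rng.random() < 0.5 else "B"]
            start = int(rng.integers(0, len(src) - 26))
            s = list(src[start : start + 26])
            for _ in range(int(rng.integers(0, 3))):
                i = int(rng.integers(0, 26))
                s[i] = "ACGT"[int(rng.integers(0, 4))]
            seqs.append("".join(s))
        seqs += _random_seqs(rng, 50, 26)
        reads = make_reads(seqs)
        hits, _ = sig.align_to_consensus(reads, consensi)
        by_read: dict[str, dict] = {}
        for h in hits:
            by_read.setdefault(h.read_id, {})[(h.subfamily, h.position, h.strand)] = h.mismatches
        for r in reads:
            assert by_read.get(r.id, {}) == naive_consensus_scan(r.sequence, consensi, 2)

    def test_zero_mismatch_equals_find_exact(self, rng):
        cons = {"A": random_genome(rng, 400)}
        seqs = [cons["A"][i : i + 26] for i in range(0, 300, 41)] + _random_seqs(rng, 10, 26)
        reads = make_reads(seqs)
        hits, _ = sig.align_to_consensus(reads, cons, max_mismatch=0)
        index = ta.build_index({"A": cons["A"]})
        for r in reads:
            got = sorted((h.position, h.strand) for h in hits if h.read_id == r.id)
            expected = sorted((pos, strand) for _, pos, strand in index.find_exact(r.sequence).hits)
            assert got == expected


class TestConsensusProfile:
    def test_coverage_examples(self):
        reads = {r.id: r for r in make_reads(["T" * 26, "A" * 26])}
        hits = [
            sig.ConsensusHit("u000000", "A", 0, "+", 0, 26, 1),
            sig.ConsensusHit("u000001", "A", 10, "+", 1, 26, 1),
        ]
        prof = sig.consensus_profile(hits, "A", 100, reads)
        assert prof["+"][0] == 1 and prof["+"][15] == 2 and prof["+"][40] == 0

    def test_conservation(self, rng):
        reads = {r.id: r for r in make_reads([(s, int(rng.integers(1, 4))) for s in _random_seqs(rng, 20, 26)])}
        hits = []
        for rid, r in reads.items():
            n = int(rng.integers(1, 3))
            for _ in range(n):
                hits.append(sig.ConsensusHit(rid, "A", int(rng.integers(0, 70)), "+", 0, 26, n))
        prof = sig.consensus_profile(hits, "A", 100, reads)
        total = prof["+"].sum() + prof["-"].sum()
        expected = sum(float(h.weight) * reads[h.read_id].count * h.length for h in hits)
        assert total == pytest.approx(expected, abs=1e-9)

    def test_unknown_subfamily_errors(self):
        with pytest.raises(ValueError, match="no consensus hits"):
            sig.consensus_profile([], "missing", 100, {})


class TestPingPong:
    def test_stated_arithmetic(self):
        # background: mean 2, sample sd 2 over the 19 off-signal overlaps
        background = [0.0] * 9 + [4.0] * 9 + [2.0]
        counts = {d: background[i] for i, d in enumerate(b for b in range(1, 21) if b != 10)}
        counts[10] = 12.0
        prof = sig.zscore_from_counts(counts)
        assert prof.z10 == pytest.approx(5.0)

    def test_no_pairs_degenerate(self):
        prof = sig.pingpong_zscore([(100, "+", 1.0), (500, "+", 1.0)])
        assert prof.degenerate and prof.z10 is None
        assert all(v == 0 for v in prof.overlap_counts.values())

    def test_overlap_convention(self):
        # plus 5' at 100, minus 5' at 109 -> overlap exactly 10
        prof = sig.pingpong_zscore([(100, "+", 1.0), (109, "-", 1.0)])
        assert prof.overlap_counts[10] == 1.0
        assert sum(prof.overlap_counts.values()) == 1.0

    def test_product_weights(self):
        prof = sig.pingpong_zscore([(100, "+", 0.5), (109, "-", 0.25)])
        assert prof.overlap_counts[10] == pytest.approx(0.125)

    def test_rescaling_invariance(self, rng):
        records = [
            (int(rng.integers(0, 1000)), "+" if rng.random() < 0.5 else "-", float(rng.random()))
            for _ in range(300)
        ]
        z1 = sig.pingpong_zscore(records).z10
        z2 = sig.pingpong_zscore([(p, s, w * 3.7) for p, s, w in records]).z10
        assert z1 == pytest.approx(z2, rel=1e-9)

    def test_planted_pairs_give_strong_z10(self, rng):
        records = []
        for _ in range(2000):
            p = int(rng.integers(0, 50_000))
            records.append((p, "+", 1.0))
            if rng.random() < 0.5:
                records.append((p + 9, "-", 1.0))
            else:
                records.append((int(rng.integers(0, 50_000)), "-", 1.0))
        assert sig.pingpong_zscore(records).z10 > 10
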