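import numpy as np
import pytest

from rtscan.io import Genome, GenomicInterval, Read, ReadSet, TranscriptAnnotation
from rtscan.profiles import (
    assign_read_class,
    class_tally,
    detect_oligoA,
    length_normalized_profile,
    metagene_endpoint_profile,
    oligoA_fraction,
    pileup,
    polii_3prime_group_profile,
    snoRNA_flank_ratio,
    tally_snoRNA_readthrough,
)
from rtscan.simulate import SimConfig, simulate_crac_reads, simulate_genome

from conftest import make_transcripts


def read(chrom, start, end, strand, tail3="", name="."):
    return Read(GenomicInterval(chrom, start, end, strand), name=name, tail3=tail3)


class TestClassAssignment:
    def test_snoRNA_beats_mRNA(self):
        ts = make_transcripts(
            [
                ("m1", "chr1", 0, 2000, "+", "mRNA"),
                ("s1", "chr1", 500, 700, "+", "snoRNA"),
            ]
        )
        assert assign_read_class(read("chr1", 550, 580, "+"), ts) == "snoRNA"

    def test_antisense(self):
        ts = make_transcripts([("m1", "chr1", 0, 2000, "+", "mRNA")])
        assert assign_read_class(read("chr1", 100, 130, "-"), ts) == "antisense"

    def test_intergenic(self):
        ts = make_transcripts([("m1", "chr1", 0, 200, "+", "mRNA")])
        assert assign_read_class(read("chr1", 5000, 5030, "+"), ts) == "intergenic"

    def test_half_overlap_rule(self):
        ts = make_transcripts([("m1", "chr1", 100, 200, "+", "mRNA")])
        # 15 of 30 nt inside: exactly 50% -> counted
        assert assign_read_class(read("chr1", 185, 215, "+"), ts) == "mRNA"
        # 14 of 30 inside -> intergenic
        assert assign_read_class(read("chr1", 186, 216, "+"), ts) == "intergenic"

    def test_intron_label(self):
        intron = GenomicInterval("chr1", 300, 600, "+")
        t = TranscriptAnnotation(
            interval=GenomicInterval("chr1", 0, 2000, "+"),
            id="m1",
            rna_class="mRNA",
            introns=(intron,),
        )
        ts = make_transcripts([])
        ts.transcripts.append(t)
        assert assign_read_class(read("chr1", 400, 430, "+"), ts) == "intron"
        assert assign_read_class(read("chr1", 1000, 1030, "+"), ts) == "mRNA"

    def test_tally_matches_bruteforce_and_sums_to_one(self):
        cfg = SimConfig(n_genes=30, reads_per_sample=200, seed=12)
        ts, truth = simulate_genome(cfg)
        reads = simulate_crac_reads(ts, truth, cfg)
        tally = class_tally(reads, ts)
        assert tally["fraction"].sum() == pytest.approx(1.0)
        brute = {}
        for r in reads:
            label = assign_read_class(r, ts)
            brute[label] = brute.get(label, 0) + 1
        assert dict(tally["count"]) == brute


class TestOligoA:
    def test_non_templated_detected(self):
        genome = Genome({"chr1": "A" * 100 + "CT" + "G" * 100})
        r = read("chr1", 70, 100, "+", tail3="AA")
        assert detect_oligoA(r, genome)

    def test_single_A_rejected(self):
        genome = Genome({"chr1": "C" * 200})
        assert not detect_oligoA(read("chr1", 70, 100, "+", tail3="A"), genome)

    def test_templated_rejected(self):
        genome = Genome({"chr1": "C" * 100 + "AA" + "G" * 100})
        assert not detect_oligoA(read("chr1", 70, 100, "+", tail3="AA"), genome)

    def test_minus_strand_templating(self):
        # - strand read ending at genomic position 100; downstream (sense)
        # bases are the reverse complement of genome[98:100]
        genome = Genome({"chr1": "C" * 98 + "TT" + "G" * 100})
        r = read("chr1", 100, 130, "-", tail3="AA")
        assert not detect_oligoA(r, genome)  # revcomp(TT) = AA -> templated
        genome2 = Genome({"chr1": "C" * 98 + "AG" + "G" * 100})
        assert detect_oligoA(read("chr1", 100, 130, "-", tail3="AA"), genome2)

    def test_off_contig_counts_as_non_templated(self):
        genome = Genome({"chr1": "C" * 100})
        assert detect_oligoA(read("chr1", 70, 99, "+", tail3="AAA"), genome)

    def test_fraction_no_tails(self, toy_genome):
        rs = ReadSet([read("chr1", 0, 30, "+") for _ in range(5)])
        assert oligoA_fraction(rs, toy_genome) == 0.0

    def test_fraction_empty_set_missing(self, toy_genome):
        assert oligoA_fraction(ReadSet([]), toy_genome) is None

    def test_weighted_mean_identity(self):
        ts = make_transcripts(
            [
                ("m1", "chr1", 0, 100, "+", "mRNA"),
                ("s1", "chr1", 200, 300, "+", "snoRNA"),
            ]
        )
        genome = Genome({"chr1": "C" * 400})
        reads = ReadSet(
            [read("chr1", 10, 40, "+", tail3="AA")]
            + [read("chr1", 10, 40, "+")] * 3
            + [read("chr1", 210, 240, "+", tail3="AA")] * 2
            + [read("chr1", 210, 240, "+")] * 2
        )
        total = oligoA_fraction(reads, genome)
        f_m = oligoA_fraction(reads, genome, ts, "mRNA")
        f_s = oligoA_fraction(reads, genome, ts, "snoRNA")
        assert total == pytest.approx((4 * f_m + 4 * f_s) / 8)


class TestMetagene:
    def test_single_read_at_anchor(self):
        ts = make_transcripts([("m1", "chr1", 1000, 2000, "+", "mRNA")])
        rs = ReadSet([read("chr1", 998, 1003, "+")], total_mapped=100)
        prof = metagene_endpoint_profile(
            rs, ts, anchor="TSS", flank_out=10, flank_in=10, normalization="raw"
        )
        nz = prof.offsets[prof.values > 0]
        assert list(nz) == [-2, -1, 0, 1, 2]

    def test_minus_strand_orientation(self):
        ts = make_transcripts([("m1", "chr1", 1000, 2000, "-", "mRNA")])
        # TSS of a minus gene is at 1999; genomic 2001 is offset -2
        rs = ReadSet([read("chr1", 2001, 2003, "-")], total_mapped=100)
        prof = metagene_endpoint_profile(
            rs, ts, anchor="TSS", flank_out=10, flank_in=10, normalization="raw"
        )
        nz = prof.offsets[prof.values > 0]
        assert list(nz) == [-3, -2]

    def test_sum_to_one(self):
        ts = make_transcripts([("m1", "chr1", 1000, 2000, "+", "mRNA")])
        rs = ReadSet([read("chr1", 990, 1050, "+"), read("chr1", 1010, 1080, "+")])
        prof = metagene_endpoint_profile(rs, ts, anchor="TSS", flank_out=50, flank_in=100)
        assert prof.values.sum() == pytest.approx(1.0)

    def test_per_million(self):
        ts = make_transcripts([("m1", "chr1", 1000, 2000, "+", "mRNA")])
        rs = ReadSet([read("chr1", 1000, 1001, "+")], total_mapped=2 * 10**6)
        prof = metagene_endpoint_profile(
            rs, ts, anchor="TSS", flank_out=5, flank_in=5, normalization="per_million"
        )
        assert prof.values.max() == pytest.approx(0.5)

    def test_empty_gene_set_rejected(self):
        rs = ReadSet([])
        with pytest.raises(ValueError):
            metagene_endpoint_profile(rs, [], anchor="TSS")

    def test_min_len_filter(self):
        ts = make_transcripts(
            [
                ("short", "chr1", 0, 120, "+", "CUT"),
                ("long", "chr1", 1000, 1400, "+", "CUT"),
            ]
        )
        rs = ReadSet([read("chr1", 1000, 1030, "+")])
        prof = metagene_endpoint_profile(rs, ts, anchor="TSS", min_len=150)
        assert prof.gene_set_size == 1

    def test_uniform_coverage_flat_interior(self):
        # uniform reads: interior of the profile stays within Poisson bands
        rng = np.random.default_rng(0)
        ts = make_transcripts([("m1", "chr1", 1000, 3000, "+", "mRNA")])
        reads = []
        for s in rng.integers(900, 2970, size=3000):
            reads.append(read("chr1", int(s), int(s) + 30, "+"))
        rs = ReadSet(reads)
        prof = metagene_endpoint_profile(
            rs, ts, anchor="TSS", flank_out=0, flank_in=500, normalization="raw"
        )
        interior = prof.values[50:450]
        lam = interior.mean()
        assert np.all(np.abs(interior - lam) < 3.5 * np.sqrt(lam))


class TestLengthNormalized:
    def test_full_coverage_equal_bins(self):
        ts = make_transcripts([("m1", "chr1", 0, 100, "+", "mRNA")])
        rs = ReadSet([read("chr1", 0, 100, "+")])
        prof = length_normalized_profile(rs, ts, n_bins=10)
        assert np.allclose(prof, 10.0)

    def test_first_half_coverage(self):
        ts = make_transcripts([("m1", "chr1", 0, 100, "+", "mRNA")])
        rs = ReadSet([read("chr1", 0, 50, "+")])
        prof = length_normalized_profile(rs, ts, n_bins=10)
        assert np.allclose(prof[:5], 10.0) and np.allclose(prof[5:], 0.0)

    def test_minus_strand_reversed(self):
        ts = make_transcripts([("m1", "chr1", 0, 100, "-", "mRNA")])
        rs = ReadSet([read("chr1", 50, 100, "-")])  # 5' half of a minus gene
        prof = length_normalized_profile(rs, ts, n_bins=10)
        assert np.allclose(prof[:5], 10.0) and np.allclose(prof[5:], 0.0)

    def test_mass_conservation(self):
        rng = np.random.default_rng(1)
        ts = make_transcripts([("m1", "chr1", 0, 97, "+", "mRNA")])
        reads = [read("chr1", int(s), int(s) + 20, "+") for s in rng.integers(0, 77, 40)]
        rs = ReadSet(reads)
        prof = length_normalized_profile(rs, ts, n_bins=13)
        assert prof.sum() == pytest.approx(40 * 20)

    def test_transcript_shorter_than_bins(self):
        ts = make_transcripts([("m1", "chr1", 0, 5, "+", "mRNA")])
        rs = ReadSet([read("chr1", 0, 5, "+")])
        prof = length_normalized_profile(rs, ts, n_bins=10)
        assert prof.sum() == pytest.approx(5.0)
        assert np.allclose(prof, 0.5)


class TestPileup:
    def test_two_overlapping_reads(self):
        region = GenomicInterval("chr1", 100, 150, "+")
        rs = ReadSet(
            [read("chr1", 100, 130, "+"), read("chr1", 110, 140, "+")],
            total_mapped=10**6,
        )
        vals = pileup(rs, region)
        assert vals[15] == pytest.approx(2.0)
        assert vals[5] == pytest.approx(1.0)
        assert vals[45] == pytest.approx(0.0)

    def test_empty_region(self):
        rs = ReadSet([read("chr1", 0, 30, "+")], total_mapped=100)
        vals = pileup(rs, GenomicInterval("chr2", 0, 50, "+"))
        assert np.allclose(vals, 0.0)

    def test_zero_total_rejected(self):
        rs = ReadSet([], total_mapped=0)
        with pytest.raises(ValueError):
            pileup(rs, GenomicInterval("chr1", 0, 10, "+"))

    def test_matches_naive_counting(self):
        rng = np.random.default_rng(2)
        reads = [
            read("chr1", int(s), int(s) + int(l), "+")
            for s, l in zip(rng.integers(0, 400, 100), rng.integers(10, 40, 100))
        ]
        rs = ReadSet(reads, total_mapped=10**6)
        region = GenomicInterval("chr1", 50, 350, "+")
        vals = pileup(rs, region)
        for i in range(0, 300, 17):
            p = region.start + i
            naive = sum(1 for r in reads if r.interval.start <= p < r.interval.end)
            assert vals[i] == pytest.approx(naive)


class TestGroupProfile:
    def test_single_gene_max_one(self):
        ts = make_transcripts([("m1", "chr1", 1000, 2000, "+", "mRNA")])
        rs = ReadSet([read("chr1", 1900, 1950, "+"), read("chr1", 1910, 1960, "+")])
        prof = polii_3prime_group_profile(rs, ts, window_up=200, window_down=200)
        assert prof.values.max() == pytest.approx(1.0)

    def test_linearity_over_identical_genes(self):
        specs = [(f"m{i}", "chr1", 1000, 2000, "+", "mRNA") for i in range(3)]
        # identical coordinates are fine for the profile; ids must differ
        ts = make_transcripts(specs)
        rs = ReadSet([read("chr1", 1900, 1950, "+")])
        single = polii_3prime_group_profile(rs, [ts.transcripts[0]], 100, 100)
        triple = polii_3prime_group_profile(rs, ts.transcripts, 100, 100)
        assert np.allclose(triple.values, 3 * single.values)

    def test_bounded_by_group_size(self):
        cfg = SimConfig(n_genes=20, crac_bias="three_prime", reads_per_sample=5000, seed=3)
        ts, truth = simulate_genome(cfg)
        rs = simulate_crac_reads(ts, truth, cfg)
        prof = polii_3prime_group_profile(rs, ts.transcripts, 300, 300)
        assert np.all(prof.values <= prof.gene_set_size + 1e-9)

    def test_geneless_hits_dropped_with_warning(self):
        ts = make_transcripts(
            [
                ("hit", "chr1", 1000, 2000, "+", "mRNA"),
                ("cold", "chr1", 5000, 6000, "+", "mRNA"),
            ]
        )
        rs = ReadSet([read("chr1", 1950, 1980, "+")])
        with pytest.warns(UserWarning, match="cold"):
            prof = polii_3prime_group_profile(rs, ts.transcripts, 100, 100)
        assert prof.gene_set_size == 1

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            polii_3prime_group_profile(ReadSet([]), [], 100, 100)


class TestFlankRatio:
    def _sno(self):
        return make_transcripts([("sno1", "chr1", 1000, 1200, "+", "snoRNA")])["sno1"]

    def test_identical_readsets_fold_one(self):
        reads = ReadSet([read("chr1", 1050, 1080, "+"), read("chr1", 1250, 1280, "+")])
        fr = snoRNA_flank_ratio(reads, reads, self._sno())
        assert fr.fold == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        body = [read("chr1", 1050, 1080, "+", name=f"b{i}") for i in range(100)]
        flank_wt = [read("chr1", 1250, 1280, "+", name=f"f{i}") for i in range(10)]
        flank_mut = [read("chr1", 1250, 1280, "+", name=f"g{i}") for i in range(20)]
        fr = snoRNA_flank_ratio(
            ReadSet(body + flank_wt), ReadSet(body + flank_mut), self._sno()
        )
        assert fr.fold == pytest.approx(2.0)

    def test_fold_symmetry(self):
        a = ReadSet([read("chr1", 1050, 1080, "+")] * 3 + [read("chr1", 1300, 1330, "+")])
        b = ReadSet([read("chr1", 1050, 1080, "+")] * 2 + [read("chr1", 1300, 1330, "+")] * 3)
        f_ab = snoRNA_flank_ratio(a, b, self._sno()).fold
        f_ba = snoRNA_flank_ratio(b, a, self._sno()).fold
        assert f_ab == pytest.approx(1.0 / f_ba)

    def test_zero_body_undefined(self):
        empty = ReadSet([read("chr1", 1250, 1280, "+")])
        fr = snoRNA_flank_ratio(empty, empty, self._sno())
        assert fr.fold is None


class TestSnoTally:
    def _snos(self):
        specs = []
        for i in range(5):
            specs.append((f"mono{i}", "chr1", 1000 * i + 10, 1000 * i + 200, "+", "snoRNA"))
        ts = make_transcripts(specs)
        out = []
        for i, t in enumerate(ts):
            out.append(
                TranscriptAnnotation(
                    interval=t.interval,
                    id=t.id,
                    rna_class="snoRNA",
                    sno_transcript_class="monocistronic" if i < 4 else "intronic",
                )
            )
        return out

    def test_counts(self):
        snos = self._snos()
        calls = {"mono0": True, "mono1": True, "mono2": True, "mono3": False, "mono4": True}
        tally = tally_snoRNA_readthrough(calls, snos)
        assert tally["monocistronic"] == (3, 4)

    def test_intronic_never_in_denominator(self):
        snos = self._snos()
        calls = {t.id: True for t in snos}
        tally = tally_snoRNA_readthrough(calls, snos)
        assert tally["all"][1] == 4  # the intronic entry is excluded

    def test_matches_bruteforce(self):
        snos = self._snos()
        calls = {"mono0": True, "mono2": True}
        tally = tally_snoRNA_readthrough(calls, snos)
        brute_num = sum(
            1
            for t in snos
            if t.sno_transcript_class == "monocistronic" and calls.get(t.id)
        )
        brute_den = sum(
            1
            for t in snos
            if t.sno_transcript_class == "monocistronic" and t.id in calls
        )
        assert tally["monocistronic"] == (brute_num, brute_den)
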