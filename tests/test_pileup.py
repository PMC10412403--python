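"""SNP pileup: VCF site filtering, per-read classification, oracle
equivalence, depth-cap semantics, thread invariance."""

import gzip
import logging
import math
import random

import pytest

from scatterbam.bam import BamHeader, BamRecord, FlagBits
from scatterbam.errors import ConfigError
from scatterbam.pileup import (
    DEFAULT_EXCLUDE_FLAGS,
    PileupConfig,
    SiteCounts,
    SnpSite,
    format_csv,
    parse_csv,
    pileup_site,
    pileup_sites,
    read_sites,
    snp_pileup,
    write_csv,
)
from scatterbam.reader import BamFile

F = FlagBits


# ---------------------------------------------------------------------------
# VCF site reading
# ---------------------------------------------------------------------------

VCF_HEADER = "##fileformat=VCFv4.2\n#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def _vcf(tmp_path, rows, name="sites.vcf", gz=False):
    text = VCF_HEADER + "".join(
        "\t".join(map(str, r)) + "\n" for r in rows)
    p = tmp_path / name
    if gz:
        p.write_bytes(gzip.compress(text.encode()))
    else:
        p.write_text(text)
    return p


class TestReadSites:
    def test_simple_snp(self, tmp_path):
        p = _vcf(tmp_path, [("chr1", 100, ".", "A", "C", ".", "PASS", ".")])
        assert read_sites(p) == [SnpSite("chr1", 100, "A", "C")]

    @pytest.mark.parametrize("ref,alt", [
        ("A", "AT"),      # insertion
        ("AT", "A"),      # deletion
        ("A", "<DEL>"),   # symbolic
        ("A", "C,G"),     # multi-allelic
        ("N", "C"),       # non-ACGT ref
        ("A", "A"),       # ref == alt
    ])
    def test_non_snp_rows_skipped(self, tmp_path, ref, alt):
        p = _vcf(tmp_path, [("chr1", 100, ".", ref, alt, ".", "PASS", "."),
                            ("chr1", 200, ".", "G", "T", ".", "PASS", ".")])
        assert read_sites(p) == [SnpSite("chr1", 200, "G", "T")]

    def test_duplicate_coordinate_with_non_biallelic_first_occurrence(self, tmp_path):
        # the later bi-allelic duplicate must still be emitted
        p = _vcf(tmp_path, [("chr1", 100, ".", "A", "<DEL>", ".", "PASS", "."),
                            ("chr1", 100, ".", "A", "G", ".", "PASS", ".")])
        assert read_sites(p) == [SnpSite("chr1", 100, "A", "G")]

    def test_duplicate_snp_rows_all_retained(self, tmp_path):
        p = _vcf(tmp_path, [("chr1", 100, ".", "A", "C", ".", "PASS", "."),
                            ("chr1", 100, ".", "A", "G", ".", "PASS", ".")])
        assert len(read_sites(p)) == 2

    def test_gzip_input(self, tmp_path):
        p = _vcf(tmp_path, [("chr1", 5, ".", "T", "G", ".", "PASS", ".")], gz=True)
        assert read_sites(p) == [SnpSite("chr1", 5, "T", "G")]

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "bad.vcf"
        p.write_text("chr1\t100\t.\tA\n")
        with pytest.raises(ConfigError):
            read_sites(p)

    def test_no_data_lines(self, tmp_path):
        p = tmp_path / "empty.vcf"
        p.write_text(VCF_HEADER)
        with pytest.raises(ConfigError):
            read_sites(p)


# ---------------------------------------------------------------------------
# per-site classification
# ---------------------------------------------------------------------------

def read_at(pos, cigar, seq, qual=None, flag=0, mapq=60, name="r"):
    return BamRecord(read_name=name, flag=int(flag), ref_id=0, pos=pos, mapq=mapq,
                     cigar=cigar, seq=seq,
                     qual=qual if qual is not None else (35,) * len(seq))


SITE = SnpSite("chr1", 101, "A", "C")  # pos0 = 100


class TestPileupSite:
    def test_ref_base(self):
        r = read_at(95, (("M", 10),), "GGGGGAGGGG")
        assert pileup_site([r], SITE) == SiteCounts(1, 0, 0, 0)

    def test_alt_and_error(self):
        alt = read_at(100, (("M", 5),), "CGGGG")
        err = read_at(100, (("M", 5),), "TGGGG")
        assert pileup_site([alt, err], SITE) == SiteCounts(0, 1, 1, 0)

    def test_deletion_spanning_site(self):
        r = read_at(95, (("M", 3), ("D", 5), ("M", 3)), "GGGGGG")
        assert pileup_site([r], SITE) == SiteCounts(0, 0, 0, 1)

    def test_refskip_and_noncovering_contribute_nothing(self):
        n = read_at(95, (("M", 3), ("N", 5), ("M", 3)), "GGGGGG")
        away = read_at(200, (("M", 5),), "AAAAA")
        assert pileup_site([n, away], SITE) == SiteCounts(0, 0, 0, 0)

    def test_softclip_does_not_consume_reference(self):
        # 5S shifts query but not reference: aligned base at site is seq[5+(100-98)]
        r = read_at(98, (("S", 5), ("M", 5)), "GGGGGGGAGG")
        assert pileup_site([r], SITE) == SiteCounts(1, 0, 0, 0)

    def test_insertion_shifts_query_coordinates(self):
        # 3M 2I 4M starting at 98: site 100 is the 4th M base → seq index 5
        r = read_at(98, (("M", 3), ("I", 2), ("M", 4)), "GGGTTAGGG"[:9])
        assert pileup_site([r], SITE) == SiteCounts(0, 0, 1, 0)

    def test_base_quality_threshold(self):
        r = read_at(100, (("M", 3),), "AGG", qual=(10, 35, 35))
        cfg = PileupConfig(min_base_quality=20)
        assert pileup_site([r], SITE, cfg) == SiteCounts(0, 0, 0, 0)
        assert pileup_site([r], SITE) == SiteCounts(1, 0, 0, 0)

    def test_missing_quality_passes_any_threshold(self):
        r = read_at(100, (("M", 3),), "AGG")
        r.qual = None
        cfg = PileupConfig(min_base_quality=90)
        assert pileup_site([r], SITE, cfg) == SiteCounts(1, 0, 0, 0)

    def test_map_quality_and_flag_exclusions(self):
        lowmq = read_at(100, (("M", 3),), "AGG", mapq=5)
        dup = read_at(100, (("M", 3),), "AGG", flag=F.DUP)
        sec = read_at(100, (("M", 3),), "AGG", flag=F.SECONDARY)
        qc = read_at(100, (("M", 3),), "AGG", flag=F.QCFAIL)
        cfg = PileupConfig(min_map_quality=20)
        assert pileup_site([lowmq, dup, sec, qc], SITE, cfg) == SiteCounts(0, 0, 0, 0)

    def test_max_depth_admits_in_file_order(self):
        reads = [read_at(100, (("M", 3),), b + "GG", name=f"r{i}")
                 for i, b in enumerate("ACA")]
        cfg = PileupConfig(max_depth=2)
        got = pileup_site(reads, SITE, cfg)
        assert got == SiteCounts(1, 1, 0, 0)  # first two in file order
        assert got.R + got.A + got.E + got.D == 2


# ---------------------------------------------------------------------------
# whole-pipeline equivalence
# ---------------------------------------------------------------------------

def oracle_counts(records, site, rid):
    """Independent brute-force CIGAR walk over every record (test-local)."""
    pos = site.pos1 - 1
    R = A = E = D = 0
    for rec in records:
        if rec.ref_id != rid or rec.flag & DEFAULT_EXCLUDE_FLAGS:
            continue
        rpos, q = rec.pos, 0
        hit = None
        for op, n in rec.cigar:
            if op in "M=X":
                if rpos <= pos < rpos + n:
                    hit = rec.seq[q + pos - rpos]
                rpos += n
                q += n
            elif op == "D":
                if rpos <= pos < rpos + n:
                    hit = "-"
                rpos += n
            elif op == "N":
                rpos += n
            elif op in "IS":
                q += n
        if hit is None:
            continue
        if hit == "-":
            D += 1
        elif hit == site.ref_base:
            R += 1
        elif hit == site.alt_base:
            A += 1
        else:
            E += 1
    return SiteCounts(R, A, E, D)


class TestOracleEquivalence:
    def test_counts_equal_truth_and_brute_force(self, big_sim, big_bamfile, big_sites):
        sites = sorted((SnpSite(c, p, r, a) for c, p, r, a, _ in big_sites),
                       key=lambda s: (big_bamfile.header.ref_id(s.chrom), s.pos1))
        assert len(sites) >= 100
        table = pileup_sites(sites, [big_bamfile], PileupConfig(), n_threads=4)
        records = list(big_bamfile)
        assert len(table) == len(sites)
        for site, per_sample in table:
            got = per_sample[0]
            truth = big_sim.truth.site_allele_counts[(site.chrom, site.pos1)]
            assert list(got) == truth, site
            assert got == oracle_counts(records, site,
                                        big_bamfile.header.ref_id(site.chrom)), site

    def test_pysam_pileup_cross_check(self, big_bam_path, big_bamfile, big_sites):
        pysam = pytest.importorskip("pysam")
        sites = [SnpSite(c, p, r, a) for c, p, r, a, _ in big_sites][:25]
        table = dict((s, c[0]) for s, c in
                     pileup_sites(sites, [big_bamfile], PileupConfig(), 1))
        af = pysam.AlignmentFile(str(big_bam_path), "rb")
        for site in sites:
            R = A = E = D = 0
            for col in af.pileup(site.chrom, site.pos1 - 1, site.pos1,
                                 truncate=True, min_base_quality=0,
                                 max_depth=1_000_000, ignore_overlaps=False,
                                 ignore_orphans=False):
                for pr in col.pileups:
                    if pr.is_refskip:
                        continue
                    if pr.is_del:
                        D += 1
                        continue
                    b = pr.alignment.query_sequence[pr.query_position]
                    if b == site.ref_base:
                        R += 1
                    elif b == site.alt_base:
                        A += 1
                    else:
                        E += 1
            assert table[site] == SiteCounts(R, A, E, D), site

    def test_thread_invariance_byte_identical_csv(self, big_bamfile, big_sites):
        sites = sorted((SnpSite(c, p, r, a) for c, p, r, a, _ in big_sites),
                       key=lambda s: (big_bamfile.header.ref_id(s.chrom), s.pos1))
        outs = {format_csv(pileup_sites(sites, [big_bamfile], PileupConfig(), n), 1)
                for n in (1, 2, 8)}
        assert len(outs) == 1

    def test_monotone_in_thresholds_and_depth_cap(self, small_bamfile, small_sites):
        sites = [SnpSite(c, p, r, a) for c, p, r, a, _ in small_sites]
        base = pileup_sites(sites, [small_bamfile], PileupConfig(), 1)
        strict = pileup_sites(sites, [small_bamfile],
                              PileupConfig(min_base_quality=20, min_map_quality=30), 1)
        capped = pileup_sites(sites, [small_bamfile], PileupConfig(max_depth=2), 1)
        for (s0, a), (s1, b), (s2, c) in zip(base, strict, capped):
            for x, y in zip(a[0], b[0]):
                assert y <= x
            assert sum(c[0]) == min(2, sum(a[0]))


class TestMultiSampleAndOutput:
    def test_two_samples_csv_layout(self, tmp_path, small_bamfile, small_bam_path):
        sites = [SnpSite("chr1", 10001, "A", "C")]
        table = pileup_sites(sites, [small_bamfile, small_bamfile], PileupConfig(), 1)
        text = format_csv(table, 2)
        header = text.splitlines()[0].split(",")
        assert len(header) == 4 + 8
        assert header[:6] == ["Chromosome", "Position", "Ref", "Alt", "File1R", "File1A"]

    def test_csv_round_trip(self, tmp_path, small_bamfile, small_sites):
        sites = [SnpSite(c, p, r, a) for c, p, r, a, _ in small_sites[:10]]
        table = pileup_sites(sites, [small_bamfile], PileupConfig(), 1)
        p = tmp_path / "out.csv"
        write_csv(table, p, 1)
        assert parse_csv(p) == table

    def test_empty_table_is_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        write_csv([], p, 2)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 and lines[0].count(",") == 11

    def test_unknown_chrom_yields_zero_row_and_warning(self, small_bamfile, caplog):
        sites = [SnpSite("chrMT", 5, "A", "C")]
        with caplog.at_level(logging.WARNING, logger="scatterbam.pileup"):
            table = pileup_sites(sites, [small_bamfile], PileupConfig(), 1)
        assert table == [(sites[0], [SiteCounts(0, 0, 0, 0)])]
        assert any("chrMT" in r.message for r in caplog.records)

    def test_min_total_depth_filters_rows(self, small_bamfile):
        sites = [SnpSite("chr1", 10001, "A", "C")]
        allrows = pileup_sites(sites, [small_bamfile], PileupConfig(), 1)
        total = sum(allrows[0][1][0])
        kept = pileup_sites(sites, [small_bamfile],
                            PileupConfig(min_total_depth=total + 1), 1)
        assert kept == []

    def test_snp_pileup_end_to_end(self, tmp_path, small_sim, small_bam_path):
        vcf = tmp_path / "s.vcf"
        vcf.write_text(small_sim.vcf)
        table = snp_pileup(vcf, [str(small_bam_path)], PileupConfig(), 2)
        assert len(table) == len(small_sim.truth.site_allele_counts)


class TestParameterRecovery:
    def test_injected_fractions_within_binomial_intervals(self, deep_sim, deep_bam_path):
        """Injected VAFs recovered within 99% binomial intervals at ~550x."""
        f = BamFile(str(deep_bam_path))
        sites = [SnpSite(c, p, r, a) for c, p, r, a, _ in (
            ("chr1", 2001, "A", "C", 0.0), ("chr1", 3501, "G", "T", 0.25),
            ("chr1", 5001, "C", "A", 0.5), ("chr1", 6501, "T", "G", 1.0))]
        fracs = [0.0, 0.25, 0.5, 1.0]
        table = pileup_sites(sites, [f], PileupConfig(), 2)
        for (site, per_sample), p_true in zip(table, fracs):
            c = per_sample[0]
            n = c.R + c.A
            assert n >= 500
            vaf = c.A / n
            half = 2.576 * math.sqrt(p_true * (1 - p_true) / n)
            # base errors perturb counts slightly even at p ∈ {0, 1}
            assert abs(vaf - p_true) <= half + 0.01, (site, vaf, p_true)
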