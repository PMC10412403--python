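"""Deterministic synthetic BAM/BAI/VCF fixtures with exhaustive ground truth.

The generator emulates a small paired-end resequencing experiment: fragments
drawn around a mean insert size, reads of fixed length, occasional soft
clips/insertions/deletions, sequencing errors, duplicate/QC-fail/secondary/
unmapped reads at configurable rates, and alternate alleles injected at
listed SNP sites with stated fractions.  Everything downstream needs to be
testable without downloads, so the generator records truth *while emitting*
— block boundaries, per-record virtual offsets, flag tallies, per-site
allele counts — rather than re-deriving it with the code under test.

Same seed ⇒ byte-identical output.  Genomic placement, flags, alleles and
qualities come from integer/uniform draws of one ``random.Random``; fragment
lengths use its Gaussian (deterministic in CPython).
"""

from __future__ import annotations

import io
import random
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

from .bam import BamHeader, BamRecord, FlagBits
from .bgzf import VirtualOffset
from .errors import ConfigError
from .flagstat import FlagCounts, _Side
from .index import BaiIndex
from .writer import BamWriteInfo, index_from_write, write_bam_bytes

_ACGT = "ACGT"
_EXCLUDE = int(FlagBits.UNMAP | FlagBits.SECONDARY | FlagBits.QCFAIL | FlagBits.DUP)
#: two-level quality alphabet: exact deltas for threshold-monotonicity tests
QUAL_HIGH, QUAL_LOW = 35, 12


@dataclass(frozen=True)
class SimConfig:
    seed: int = 1
    references: tuple[tuple[str, int], ...] = (
        ("chr1", 120000), ("chr2", 90000), ("chr3", 60000))
    n_read_pairs: int = 2000
    read_len: int = 100
    fragment_mean: float = 300.0
    fragment_sd: float = 40.0
    base_error_rate: float = 0.001
    dup_fraction: float = 0.02
    unmapped_fraction: float = 0.01
    secondary_fraction: float = 0.01
    qcfail_fraction: float = 0.01
    #: fraction of mapped reads carrying a soft clip, insertion or deletion
    indel_fraction: float = 0.08
    #: (chrom, pos1, ref_base, alt_base, alt_fraction)
    variant_sites: tuple[tuple[str, int, str, str, float], ...] = ()
    #: emit coordinate-sorted BAM + BAI; False gives generation order, no index
    coordinate_sort: bool = True


@dataclass
class Truth:
    """Ground truth recorded during generation."""

    block_boundaries: list[int]
    record_voffsets: list[int]  # packed, file order
    flag_tallies: FlagCounts
    #: (chrom, pos1) -> [R, A, E, D] under zero quality thresholds and the
    #: default exclusion mask (UNMAP|SECONDARY|QCFAIL|DUP)
    site_allele_counts: dict[tuple[str, int], list[int]]

    def to_dict(self) -> dict:
        return {
            "block_boundaries": self.block_boundaries,
            "record_voffsets": self.record_voffsets,
            "flag_tallies": asdict(self.flag_tallies),
            "site_allele_counts": {f"{c}:{p}": v for (c, p), v in
                                   self.site_allele_counts.items()},
        }


@dataclass
class SimResult:
    bam: bytes
    bai: Optional[BaiIndex]
    vcf: str
    truth: Truth
    header: BamHeader
    write_info: BamWriteInfo


def reference_base(rid: int, pos: int) -> str:
    """Implicit deterministic reference genome (no FASTA is emitted)."""
    return _ACGT[(pos * 7 + rid * 11 + 3) % 4]


def _validate(cfg: SimConfig) -> None:
    for name in ("base_error_rate", "dup_fraction", "unmapped_fraction",
                 "secondary_fraction", "qcfail_fraction", "indel_fraction"):
        v = getattr(cfg, name)
        if not 0.0 <= v <= 1.0:
            raise ConfigError(f"{name}={v} outside [0, 1]")
    names = {n: l for n, l in cfg.references}
    for chrom, pos1, ref, alt, frac in cfg.variant_sites:
        if chrom not in names or not (1 <= pos1 <= names[chrom]):
            raise ConfigError(f"variant site {chrom}:{pos1} outside references")
        if ref not in _ACGT or alt not in _ACGT or ref == alt:
            raise ConfigError(f"variant site {chrom}:{pos1}: bad alleles {ref}>{alt}")
        if not 0.0 <= frac <= 1.0:
            raise ConfigError(f"variant site {chrom}:{pos1}: fraction {frac}")


def _draw_cigar(rng: random.Random, read_len: int, indel_fraction: float):
    if rng.random() >= indel_fraction:
        return (("M", read_len),)
    kind = rng.randrange(3)
    if kind == 0:  # leading soft clip
        s = rng.randrange(3, 9)
        return (("S", s), ("M", read_len - s))
    k = rng.randrange(20, read_len - 20)
    if kind == 1:  # insertion
        ilen = rng.randrange(1, 4)
        return (("M", k), ("I", ilen), ("M", read_len - k - ilen))
    dlen = rng.randrange(1, 4)  # deletion
    return (("M", k), ("D", dlen), ("M", read_len - k))


def _draw_mapq(rng: random.Random) -> int:
    u = rng.random()
    return 60 if u < 0.80 else (20 if u < 0.95 else 0)


def simulate(cfg: SimConfig) -> SimResult:
    """Generate (BAM bytes, BAI, VCF text, Truth) from *cfg*."""
    _validate(cfg)
    rng = random.Random(cfg.seed)
    ref_lens = [l for _, l in cfg.references]
    total_len = sum(ref_lens)
    # per-reference site map: pos0 -> (ref_base, alt_base, fraction, key)
    site_map: list[dict[int, tuple[str, str, float, tuple[str, int]]]] = [
        {} for _ in cfg.references]
    name_to_rid = {n: i for i, (n, _) in enumerate(cfg.references)}
    site_counts: dict[tuple[str, int], list[int]] = {}
    for chrom, pos1, ref, alt, frac in cfg.variant_sites:
        rid = name_to_rid[chrom]
        site_map[rid][pos1 - 1] = (ref, alt, frac, (chrom, pos1))
        site_counts.setdefault((chrom, pos1), [0, 0, 0, 0])

    def allele_at(rid: int, pos: int) -> str:
        s = site_map[rid].get(pos)
        return s[0] if s is not None else reference_base(rid, pos)

    records: list[BamRecord] = []

    def build_read(rid: int, start: int, cigar, flag: int, mapq: int,
                   name: str) -> BamRecord:
        """Emit bases along the CIGAR; draw alt alleles and errors; record
        site contributions (for non-excluded reads) as we go."""
        seq, qual = [], []
        contrib: list[tuple[tuple[str, int], int]] = []  # (site key, class)
        rpos = start
        for op, n in cigar:
            if op == "M":
                for j in range(n):
                    p = rpos + j
                    site = site_map[rid].get(p)
                    if site is not None:
                        ref_b, alt_b, frac, key = site
                        base = alt_b if rng.random() < frac else ref_b
                    else:
                        base = reference_base(rid, p)
                    if rng.random() < cfg.base_error_rate:
                        base = _ACGT[(_ACGT.index(base) + rng.randrange(1, 4)) % 4]
                    if site is not None:
                        ref_b, alt_b, frac, key = site
                        cls = 0 if base == ref_b else (1 if base == alt_b else 2)
                        contrib.append((key, cls))
                    seq.append(base)
                    qual.append(QUAL_HIGH if rng.random() < 0.9 else QUAL_LOW)
                rpos += n
            elif op == "D":
                for j in range(n):
                    site = site_map[rid].get(rpos + j)
                    if site is not None:
                        contrib.append((site[3], 3))
                rpos += n
            elif op in "IS":
                for _ in range(n):
                    seq.append(_ACGT[rng.randrange(4)])
                    qual.append(QUAL_HIGH if rng.random() < 0.9 else QUAL_LOW)
        rec = BamRecord(read_name=name, flag=flag, ref_id=rid, pos=start, mapq=mapq,
                        cigar=cigar, seq="".join(seq), qual=tuple(qual))
        if not flag & _EXCLUDE:
            for key, cls in contrib:
                site_counts[key][cls] += 1
        return rec

    def random_seq(n: int) -> tuple[str, tuple[int, ...]]:
        s = "".join(_ACGT[rng.randrange(4)] for _ in range(n))
        q = tuple(QUAL_HIGH if rng.random() < 0.9 else QUAL_LOW for _ in range(n))
        return s, q

    for i in range(cfg.n_read_pairs):
        name = f"sim{i:07d}"
        # weighted reference choice by length (integer path)
        x = rng.randrange(total_len)
        rid = 0
        while x >= ref_lens[rid]:
            x -= ref_lens[rid]
            rid += 1
        rlen = ref_lens[rid]
        frag = max(cfg.read_len, int(round(rng.gauss(cfg.fragment_mean, cfg.fragment_sd))))
        frag = min(frag, rlen)
        start1 = rng.randrange(0, max(1, rlen - frag + 1))
        start2 = start1 + frag - cfg.read_len
        un1 = rng.random() < cfg.unmapped_fraction
        un2 = rng.random() < cfg.unmapped_fraction
        dup = rng.random() < cfg.dup_fraction
        qc1 = rng.random() < cfg.qcfail_fraction
        qc2 = rng.random() < cfg.qcfail_fraction
        sec = rng.random() < cfg.secondary_fraction
        base1 = int(FlagBits.PAIRED | FlagBits.READ1)
        base2 = int(FlagBits.PAIRED | FlagBits.READ2)
        if dup:
            base1 |= FlagBits.DUP
            base2 |= FlagBits.DUP
        if qc1:
            base1 |= FlagBits.QCFAIL
        if qc2:
            base2 |= FlagBits.QCFAIL
        proper = (not un1 and not un2
                  and abs(frag - cfg.fragment_mean) <= 4 * cfg.fragment_sd)
        if proper:
            base1 |= FlagBits.PROPER_PAIR
            base2 |= FlagBits.PROPER_PAIR
        if un1 and un2:
            for fl, nm in ((base1, name), (base2, name)):
                s, q = random_seq(cfg.read_len)
                records.append(BamRecord(
                    read_name=nm, flag=int(fl | FlagBits.UNMAP | FlagBits.MUNMAP),
                    ref_id=-1, pos=-1, mapq=0, cigar=(), seq=s, qual=q))
            continue
        cig1 = _draw_cigar(rng, cfg.read_len, cfg.indel_fraction)
        cig2 = _draw_cigar(rng, cfg.read_len, cfg.indel_fraction)
        mq1, mq2 = _draw_mapq(rng), _draw_mapq(rng)
        f1, f2 = base1, base2
        f2 |= FlagBits.REVERSE
        f1 |= FlagBits.MREVERSE
        if un1:
            f1 |= FlagBits.UNMAP
            f2 |= FlagBits.MUNMAP
            f1 &= ~int(FlagBits.MREVERSE)
        if un2:
            f2 |= FlagBits.UNMAP
            f1 |= FlagBits.MUNMAP
            f2 &= ~int(FlagBits.REVERSE)
        # mapped-or-placed coordinates: an unmapped read sits at its mate's position
        p1 = start1 if not un1 else start2
        p2 = start2 if not un2 else start1
        if un1:
            s, q = random_seq(cfg.read_len)
            r1 = BamRecord(read_name=name, flag=int(f1), ref_id=rid, pos=p1, mapq=0,
                           cigar=(), seq=s, qual=q)
        else:
            r1 = build_read(rid, p1, cig1, int(f1), mq1, name)
        if un2:
            s, q = random_seq(cfg.read_len)
            r2 = BamRecord(read_name=name, flag=int(f2), ref_id=rid, pos=p2, mapq=0,
                           cigar=(), seq=s, qual=q)
        else:
            r2 = build_read(rid, p2, cig2, int(f2), mq2, name)
        tlen = frag if not (un1 or un2) else 0
        r1.next_ref_id, r1.next_pos, r1.tlen = rid, p2, tlen
        r2.next_ref_id, r2.next_pos, r2.tlen = rid, p1, -tlen
        records.append(r1)
        records.append(r2)
        if sec and not un1:
            alt_start = rng.randrange(0, max(1, rlen - cfg.read_len + 1))
            sflag = int(f1 | FlagBits.SECONDARY)
            r3 = build_read(rid, alt_start, (("M", cfg.read_len),), sflag, 0, name)
            r3.next_ref_id, r3.next_pos = rid, p2
            records.append(r3)

    if cfg.coordinate_sort:
        placed = sorted((r for r in records if r.ref_id >= 0),
                        key=lambda r: (r.ref_id, r.pos))
        tail = [r for r in records if r.ref_id < 0]
        records = placed + tail

    header = BamHeader(text="@HD\tVN:1.6\tSO:coordinate\n" if cfg.coordinate_sort else
                       "@HD\tVN:1.6\tSO:unsorted\n",
                       references=tuple(cfg.references))
    bam_bytes, info = write_bam_bytes(header, records)
    bai = index_from_write(header, records, info) if cfg.coordinate_sort else None

    tallies = FlagCounts()
    for r in records:
        _tally(tallies, r)

    truth = Truth(
        block_boundaries=list(info.block_boundaries),
        record_voffsets=[v0.packed for v0, _ in info.record_voffsets],
        flag_tallies=tallies,
        site_allele_counts=site_counts,
    )
    vcf = make_vcf(cfg)
    return SimResult(bam=bam_bytes, bai=bai, vcf=vcf, truth=truth, header=header,
                     write_info=info)


def _tally(c: FlagCounts, r: BamRecord) -> None:
    """The generator's own category tally (kept separate from the counting
    code under test; same samtools category definitions)."""
    f = r.flag
    s: _Side = c.failed if f & 0x200 else c.passed
    s.total += 1
    s.secondary += 1 if f & 0x100 else 0
    s.supplementary += 1 if f & 0x800 else 0
    s.duplicates += 1 if f & 0x400 else 0
    s.mapped += 0 if f & 0x4 else 1
    if not f & 0x900 and f & 0x1:
        s.paired_in_sequencing += 1
        s.read1 += 1 if f & 0x40 else 0
        s.read2 += 1 if f & 0x80 else 0
        s.properly_paired += 1 if (f & 0x2 and not f & 0x4) else 0
        if not f & 0x4:
            if f & 0x8:
                s.singletons += 1
            else:
                s.with_mate_mapped += 1
                if r.next_ref_id >= 0 and r.next_ref_id != r.ref_id:
                    s.mate_diff_ref += 1
                    s.mate_diff_ref_mapq_ge5 += 1 if r.mapq >= 5 else 0


def make_vcf(cfg: SimConfig) -> str:
    lines = ["##fileformat=VCFv4.2",
             "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"]
    order = {n: i for i, (n, _) in enumerate(cfg.references)}
    for chrom, pos1, ref, alt, _frac in sorted(
            cfg.variant_sites, key=lambda s: (order[s[0]], s[1])):
        lines.append(f"{chrom}\t{pos1}\t.\t{ref}\t{alt}\t.\tPASS\t.")
    return "\n".join(lines) + "\n"


def corrupt(bam: bytes, n_corruptions: int, seed: int) -> tuple[bytes, list[int]]:
    """Overwrite *n_corruptions* random bytes outside the header block and the
    EOF marker; returns (corrupted copy, corrupted offsets)."""
    if n_corruptions < 0:
        raise ConfigError("n_corruptions must be >= 0")
    data = bytearray(bam)
    rng = random.Random(seed)
    from .bgzf import _block_size_at

    header_block_end = _block_size_at(bam, 0)
    lo, hi = header_block_end, max(header_block_end + 1, len(bam) - 28)
    offsets = []
    for _ in range(n_corruptions):
        o = rng.randrange(lo, hi)
        data[o] ^= 0x55
        offsets.append(o)
    return bytes(data), sorted(set(offsets))
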