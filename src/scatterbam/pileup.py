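"""Multi-sample pileup at VCF-listed SNP sites (a snp-pileup port).

For every bi-allelic SNP site in a VCF, and every input BAM, counts the
reads whose aligned base at the site supports the reference allele (R), the
alternate allele (A), some other substitution (E), or whose alignment
deletes the site (D).  ``A/(R+A)`` is the variant allele fraction.  The CSV
output is the table FACETS consumes.

Depth-limit semantics: every read overlapping a site is considered in file
order and the cap lives in the per-site count structure itself — once
R+A+E+D reaches ``max_depth`` further reads contribute nothing.  This is an
intentional divergence from HTSLIB's pileup-iterator admission scheme (which
stops admitting reads while the iterator is full) and generally yields more
even coverage in extreme-depth regions.

Duplicate VCF coordinates are all retained and processed independently; in
particular a bi-allelic row at a position whose first occurrence was not a
valid SNP is still emitted (the stock tool skipped it).
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

from .bam import BamRecord, FlagBits
from .engine import Job, partition_sites, run_scatter_gather
from .errors import ConfigError, ScatterbamError
from .reader import BamFile

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")

#: reads with any of these flags never contribute to counts
DEFAULT_EXCLUDE_FLAGS = int(FlagBits.UNMAP | FlagBits.SECONDARY | FlagBits.QCFAIL | FlagBits.DUP)


class SnpSite(NamedTuple):
    """One candidate bi-allelic SNP: chromosome, 1-based position, alleles."""

    chrom: str
    pos1: int
    ref_base: str
    alt_base: str


class SiteCounts(NamedTuple):
    """Per-sample counts at one site."""

    R: int  # reads supporting ref_base
    A: int  # reads supporting alt_base
    E: int  # other substitutions ("errors")
    D: int  # deletions spanning the site


@dataclass(frozen=True)
class PileupConfig:
    """Filtering and limit parameters.

    ``max_depth = 0`` means unlimited; a missing base quality (stored 0xff)
    passes any ``min_base_quality`` threshold — missing is not low.
    """

    min_map_quality: int = 0
    min_base_quality: int = 0
    max_depth: int = 0
    exclude_flag_mask: int = DEFAULT_EXCLUDE_FLAGS
    min_total_depth: int = 0


def read_sites(vcf_path) -> list[SnpSite]:
    """Parse CHROM/POS/REF/ALT rows of a VCF (plain or gzip) into SNP sites.

    Rows whose REF or ALT is not one single base A/C/G/T (indels, symbolic
    and multi-allelic ALTs) are skipped with a logged count.  Duplicate
    coordinates are all retained, each judged on its own row.
    """
    opener = gzip.open if _is_gzip(vcf_path) else open
    sites: list[SnpSite] = []
    skipped = 0
    n_lines = 0
    with opener(vcf_path, "rt") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 8:
                raise ConfigError(f"VCF data line with {len(cols)} < 8 columns")
            n_lines += 1
            chrom, pos_s, _id, ref, alt = cols[0], cols[1], cols[2], cols[3], cols[4]
            if (len(ref) == 1 and ref in _BASES and len(alt) == 1 and alt in _BASES
                    and ref != alt):
                sites.append(SnpSite(chrom, int(pos_s), ref, alt))
            else:
                skipped += 1
    if n_lines == 0:
        raise ConfigError(f"no data lines in {vcf_path}")
    if skipped:
        log.info("skipped %d non-SNP VCF rows", skipped)
    return sites


def _is_gzip(path) -> bool:
    try:
        with open(path, "rb") as fh:
            return fh.read(2) == b"\x1f\x8b"
    except OSError:
        return False


def base_at(rec: BamRecord, pos: int) -> tuple[Optional[str], Optional[int]]:
    """Walk the CIGAR and classify what *rec* places at reference position
    *pos* (0-based): the aligned base character, ``"-"`` for a deletion
    spanning the site, or None (not covered / reference skip / clip).
    Returns ``(what, base_quality_or_None)``."""
    rpos, q = rec.pos, 0
    for op, n in rec.cigar:
        if op in "M=X":
            if rpos <= pos < rpos + n:
                i = q + (pos - rpos)
                qual = None if rec.qual is None else rec.qual[i]
                return rec.seq[i], qual
            rpos += n
            q += n
        elif op == "D":
            if rpos <= pos < rpos + n:
                return "-", None
            rpos += n
        elif op == "N":
            if rpos <= pos < rpos + n:
                return None, None
            rpos += n
        elif op in "IS":
            q += n
        # H and P consume nothing
        if rpos > pos:
            return None, None
    return None, None


def pileup_site(records: Sequence[BamRecord], site: SnpSite,
                config: PileupConfig = PileupConfig()) -> SiteCounts:
    """Count one sample's reads at one site, in file order.

    Each passing read contributes exactly one of R/A/E/D; excluded flags,
    low mapping quality, and low base quality contribute nothing.  With
    ``max_depth > 0`` contributions stop once the count sum reaches the cap.
    """
    pos = site.pos1 - 1
    r = a = e = d = 0
    for rec in records:
        if config.max_depth > 0 and r + a + e + d >= config.max_depth:
            break
        if rec.flag & config.exclude_flag_mask:
            continue
        if rec.mapq < config.min_map_quality:
            continue
        what, qual = base_at(rec, pos)
        if what is None:
            continue
        if what == "-":
            d += 1
            continue
        # missing quality (None) passes any threshold
        if qual is not None and qual != 0xFF and qual < config.min_base_quality:
            continue
        if what == site.ref_base:
            r += 1
        elif what == site.alt_base:
            a += 1
        else:
            e += 1
    return SiteCounts(r, a, e, d)


def snp_pileup(vcf_path, bam_sources: Sequence, config: PileupConfig = PileupConfig(),
               n_threads: int = 1) -> list[tuple[SnpSite, list[SiteCounts]]]:
    """Pileup every VCF site across all samples.

    BAMs must be coordinate-sorted and indexed.  Work is partitioned over
    groups of consecutive sites sized by the compressed data they span in
    the first sample's index; output row order follows site order and is
    invariant to ``n_threads``.  A VCF chromosome absent from a BAM header
    yields zero counts for that sample with a logged warning.
    """
    sites = read_sites(vcf_path)
    return pileup_sites(sites, bam_sources, config, n_threads)


def pileup_sites(sites: Sequence[SnpSite], bam_sources: Sequence,
                 config: PileupConfig = PileupConfig(),
                 n_threads: int = 1) -> list[tuple[SnpSite, list[SiteCounts]]]:
    bams = [b if isinstance(b, BamFile) else BamFile(b) for b in bam_sources]
    for b in bams:
        if b.index is None:
            raise ScatterbamError("snp_pileup requires indexed BAMs")
    warned: set[str] = set()
    jobs = partition_sites(sites, bams[0].index, bams[0].header, max(1, n_threads) * 4)

    def worker(job: Job) -> list[tuple[SnpSite, list[SiteCounts]]]:
        rows = []
        for site in job.payload:
            per_sample = []
            for b in bams:
                rid = b.header.ref_id(site.chrom)
                if rid is None:
                    if site.chrom not in warned:
                        warned.add(site.chrom)
                        log.warning("chromosome %s not in BAM header; zero counts", site.chrom)
                    per_sample.append(SiteCounts(0, 0, 0, 0))
                    continue
                recs = b.fetch(rid, site.pos1 - 1, site.pos1)
                per_sample.append(pileup_site(list(recs), site, config))
            total = sum(c.R + c.A + c.E + c.D for c in per_sample)
            if total >= config.min_total_depth:
                rows.append((site, per_sample))
        return rows

    return run_scatter_gather(jobs, worker, lambda x, y: x + y, [], n_threads)


def format_csv(table: Sequence[tuple[SnpSite, list[SiteCounts]]],
               sample_count: int) -> str:
    """FACETS-style CSV: Chromosome,Position,Ref,Alt then R/A/E/D per sample."""
    cols = ["Chromosome", "Position", "Ref", "Alt"]
    for i in range(sample_count):
        cols += [f"File{i + 1}R", f"File{i + 1}A", f"File{i + 1}E", f"File{i + 1}D"]
    lines = [",".join(cols)]
    for site, per_sample in table:
        row = [site.chrom, str(site.pos1), site.ref_base, site.alt_base]
        for c in per_sample:
            row += [str(c.R), str(c.A), str(c.E), str(c.D)]
        lines.append(",".join(row))
    return "\n".join(lines) + "\n"


def write_csv(table, out_path, sample_count: int) -> None:
    try:
        with open(out_path, "w") as fh:
            fh.write(format_csv(table, sample_count))
    except OSError as e:
        raise ScatterbamError(f"cannot write {out_path}: {e}") from e


def parse_csv(path) -> list[tuple[SnpSite, list[SiteCounts]]]:
    """Inverse of :func:`write_csv` (round-trip helper)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(",")
        n_samples = (len(header) - 4) // 4
        out = []
        for line in fh:
            c = line.rstrip("\n").split(",")
            site = SnpSite(c[0], int(c[1]), c[2], c[3])
            counts = [SiteCounts(*map(int, c[4 + 4 * i : 8 + 4 * i]))
                      for i in range(n_samples)]
            out.append((site, counts))
    return out
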