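"""Windowed, mergeable flag statistics (a samtools-flagstat port).

Per 16-kb window a worker tallies the flag categories of every record whose
alignment starts in the window; the gather stage is componentwise addition,
so the parallel result equals a single sequential pass exactly.  Records
with no reference (refID −1) live past the indexed region and are reached by
scanner-partitioned segments instead of windows.

Category semantics mirror samtools flagstat: secondary/supplementary records
are excluded from the pairing counters; ``mapped`` excludes UNMAP;
``properly paired`` requires PAIRED ∧ PROPER_PAIR ∧ ¬UNMAP.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

from .bam import BamRecord, FlagBits
from .bgzf import BgzfFile
from .engine import Job, group_windows, make_windows, records_in_window, run_scatter_gather
from .errors import ScatterbamError
from .reader import BamFile, iter_records_from
from .bgzf import VirtualReader
from .scanner import scan_start_points


@dataclass
class _Side:
    """Counters for one QC side (pass or fail)."""

    total: int = 0
    secondary: int = 0
    supplementary: int = 0
    duplicates: int = 0
    mapped: int = 0
    paired_in_sequencing: int = 0
    read1: int = 0
    read2: int = 0
    properly_paired: int = 0
    with_mate_mapped: int = 0
    singletons: int = 0
    mate_diff_ref: int = 0
    mate_diff_ref_mapq_ge5: int = 0

    def __add__(self, other: "_Side") -> "_Side":
        return _Side(**{f.name: getattr(self, f.name) + getattr(other, f.name)
                        for f in fields(self)})


@dataclass
class FlagCounts:
    """Mergeable flagstat result: one counter set per QC side.

    Merging is componentwise addition — commutative, associative, with the
    all-zero value as identity — which is what lets per-window results gather
    into the whole-file answer by simple summation.
    """

    passed: _Side = field(default_factory=_Side)
    failed: _Side = field(default_factory=_Side)

    def __add__(self, other: "FlagCounts") -> "FlagCounts":
        return FlagCounts(self.passed + other.passed, self.failed + other.failed)


def count_record(c: FlagCounts, r: BamRecord) -> FlagCounts:
    """Update *c* with one record's flag categories (mutates and returns *c*)."""
    flag = r.flag
    s = c.failed if flag & FlagBits.QCFAIL else c.passed
    s.total += 1
    if flag & FlagBits.SECONDARY:
        s.secondary += 1
    if flag & FlagBits.SUPPLEMENTARY:
        s.supplementary += 1
    if flag & FlagBits.DUP:
        s.duplicates += 1
    if not flag & FlagBits.UNMAP:
        s.mapped += 1
    if not flag & (FlagBits.SECONDARY | FlagBits.SUPPLEMENTARY):
        if flag & FlagBits.PAIRED:
            s.paired_in_sequencing += 1
            if flag & FlagBits.READ1:
                s.read1 += 1
            if flag & FlagBits.READ2:
                s.read2 += 1
            if flag & FlagBits.PROPER_PAIR and not flag & FlagBits.UNMAP:
                s.properly_paired += 1
            if not flag & FlagBits.UNMAP:
                if flag & FlagBits.MUNMAP:
                    s.singletons += 1
                else:
                    s.with_mate_mapped += 1
                    if r.next_ref_id >= 0 and r.next_ref_id != r.ref_id:
                        s.mate_diff_ref += 1
                        if r.mapq >= 5:
                            s.mate_diff_ref_mapq_ge5 += 1
    return c


def merge_counts(a: FlagCounts, b: FlagCounts) -> FlagCounts:
    """Componentwise sum (the gather operation)."""
    return a + b


def flagstat_sequential(bam: BamFile) -> FlagCounts:
    """Single-pass sequential count over every record (the parity oracle)."""
    c = FlagCounts()
    for rec in bam:
        count_record(c, rec)
    return c


def flagstat(bam_source, n_threads: int = 1, use_index: bool = True,
             jobs_per_worker: int = 4) -> FlagCounts:
    """Whole-file flag statistics, scattered over 16-kb windows.

    With an index: one job per group of contiguous windows (≈ ``4 ×
    n_threads`` jobs), plus scanner-partitioned segments for the unplaced
    tail.  Without one (or ``use_index=False``): scanner-partitioned
    segments over the whole file.  Every record is counted exactly once and
    the result equals the sequential count for any thread count.
    """
    bam = bam_source if isinstance(bam_source, BamFile) else BamFile(bam_source)
    jobs: list[Job] = []
    if use_index and bam.index is not None:
        windows = make_windows(bam.header)
        jobs = list(group_windows(windows, bam.index, jobs_per_worker * max(1, n_threads)))

        def window_worker(job: Job) -> FlagCounts:
            c = FlagCounts()
            for w in job.payload:
                for rec in records_in_window(bam, w):
                    count_record(c, rec)
            return c

        placed = run_scatter_gather(jobs, window_worker, merge_counts, FlagCounts(),
                                    n_threads)
        tail = _count_segments(bam, bam.tail_start(), n_threads)
        return placed + tail
    # no index: scanner partitioning over the whole file
    return _count_segments(bam, bam.header_end, n_threads)


def _count_segments(bam: BamFile, region_start, n_threads: int) -> FlagCounts:
    hits = scan_start_points(bam.bgzf, max(1, n_threads * 4), bam.header,
                             region_start=region_start)
    if not hits:
        return FlagCounts()
    bounds = [h.voffset for h in hits] + [None]
    jobs = [Job(i, (bounds[i], bounds[i + 1])) for i in range(len(hits))]

    def seg_worker(job: Job) -> FlagCounts:
        v_beg, v_end = job.payload
        c = FlagCounts()
        rdr = VirtualReader(bam.bgzf, v_beg, v_end)
        for _, rec, _ in iter_records_from(rdr, bam.header):
            count_record(c, rec)
        return c

    return run_scatter_gather(jobs, seg_worker, merge_counts, FlagCounts(), n_threads)


def _pct(num: int, den: int) -> str:
    return "N/A" if den == 0 else f"{100.0 * num / den:.2f}%"


def format_flagstat(c: FlagCounts) -> str:
    """samtools-flagstat-style report: ``N1 + N2 <category>`` per line."""
    p, f = c.passed, c.failed
    lines = [
        f"{p.total} + {f.total} in total (QC-passed reads + QC-failed reads)",
        f"{p.secondary} + {f.secondary} secondary",
        f"{p.supplementary} + {f.supplementary} supplementary",
        f"{p.duplicates} + {f.duplicates} duplicates",
        f"{p.mapped} + {f.mapped} mapped ({_pct(p.mapped, p.total)} : {_pct(f.mapped, f.total)})",
        f"{p.paired_in_sequencing} + {f.paired_in_sequencing} paired in sequencing",
        f"{p.read1} + {f.read1} read1",
        f"{p.read2} + {f.read2} read2",
        f"{p.properly_paired} + {f.properly_paired} properly paired "
        f"({_pct(p.properly_paired, p.paired_in_sequencing)} : "
        f"{_pct(f.properly_paired, f.paired_in_sequencing)})",
        f"{p.with_mate_mapped} + {f.with_mate_mapped} with itself and mate mapped",
        f"{p.singletons} + {f.singletons} singletons "
        f"({_pct(p.singletons, p.paired_in_sequencing)} : "
        f"{_pct(f.singletons, f.paired_in_sequencing)})",
        f"{p.mate_diff_ref} + {f.mate_diff_ref} with mate mapped to a different chr",
        f"{p.mate_diff_ref_mapq_ge5} + {f.mate_diff_ref_mapq_ge5} "
        f"with mate mapped to a different chr (mapQ>=5)",
    ]
    return "\n".join(lines) + "\n"
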