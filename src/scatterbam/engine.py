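"""Deterministic scatter/gather execution over genomic windows or site groups.

The engine's contract is what makes every pipeline built on it reproducible:
workers are pure functions of their job, and results are merged in job
*ordinal* order regardless of completion order, so output is bit-identical
for any worker count.

Windows are 16 kb by default because that is exactly the granularity of the
BAI linear index — every window start maps to a virtual offset that a worker
can seek to directly.  Site-group jobs are sized by the compressed data they
span (estimated from the index) so workers receive comparable work.
"""

from __future__ import annotations

import os
from concurrent.futures import FIRST_EXCEPTION, ThreadPoolExecutor, wait
from dataclasses import dataclass
from typing import Any, Callable, Iterable, NamedTuple, Optional, Sequence, TypeVar

from .bam import BamHeader
from .errors import JobError
from .index import LINEAR_WINDOW, BaiIndex, span_compressed_bytes

T = TypeVar("T")
R = TypeVar("R")


class Window(NamedTuple):
    """One tile of a reference: [beg, end), beg a multiple of the window size."""

    ref: int
    beg: int
    end: int


@dataclass(frozen=True)
class Job:
    """A unit of scattered work: merge position, payload, and a size estimate
    (compressed bytes spanned, from the index) used for load balancing."""

    ordinal: int
    payload: Any
    data_estimate: int = 0


def make_windows(header: BamHeader, window_size: int = LINEAR_WINDOW) -> list[Window]:
    """Tile every reference with half-open windows in genome order."""
    if window_size < 1:
        raise ValueError("window_size must be >= 1")
    out = []
    for rid, (_, length) in enumerate(header.references):
        beg = 0
        while beg < length:
            out.append(Window(rid, beg, min(beg + window_size, length)))
            beg += window_size
    return out


def records_in_window(bam, w: Window):
    """Records assigned to *w*: exactly those whose alignment start lies in
    [w.beg, w.end).  Start-based assignment is the dedup rule for reads that
    overlap window boundaries — each belongs only to the earlier window, the
    one containing its start."""
    yield from bam.fetch_starting_in(w.ref, w.beg, w.end)


def group_windows(windows: Sequence[Window], index: Optional[BaiIndex],
                  n_jobs: int) -> list[Job]:
    """Group contiguous windows into ~n_jobs jobs balanced by spanned data."""
    if not windows:
        return []
    n_jobs = max(1, n_jobs)
    if index is None:
        per = max(1, len(windows) // n_jobs)
        slices = [windows[i : i + per] for i in range(0, len(windows), per)]
        return [Job(i, tuple(s), 0) for i, s in enumerate(slices)]
    est = [span_compressed_bytes(index, w.ref, w.beg, w.end) for w in windows]
    total = sum(est)
    target = max(1, total // n_jobs)
    jobs: list[Job] = []
    cur: list[Window] = []
    acc = 0
    for w, e in zip(windows, est):
        cur.append(w)
        acc += e
        if acc >= target and len(jobs) < n_jobs - 1:
            jobs.append(Job(len(jobs), tuple(cur), acc))
            cur, acc = [], 0
    if cur:
        jobs.append(Job(len(jobs), tuple(cur), acc))
    return jobs


def partition_sites(sites: Sequence[T], index: Optional[BaiIndex],
                    header: Optional[BamHeader], n_jobs: int) -> list[Job]:
    """Split a sorted site list into consecutive slices of comparable spanned
    data size (greedy accumulation toward total/n_jobs), in genome order.

    Sites are (chrom, pos1, ...) tuples or objects with ``chrom``/``pos1``;
    without an index, slices are equal-count.
    """
    if not sites:
        return []
    n_jobs = max(1, n_jobs)

    def site_key(s):
        chrom = getattr(s, "chrom", None) or s[0]
        pos1 = getattr(s, "pos1", None) or s[1]
        return chrom, pos1

    if index is None or header is None:
        per = max(1, -(-len(sites) // n_jobs))
        slices = [sites[i : i + per] for i in range(0, len(sites), per)]
        return [Job(i, tuple(s), 0) for i, s in enumerate(slices)]
    est = []
    for s in sites:
        chrom, pos1 = site_key(s)
        rid = header.ref_id(chrom)
        if rid is None:
            est.append(0)
        else:
            est.append(span_compressed_bytes(index, rid, pos1 - 1, pos1))
    total = sum(est)
    target = max(1, total // n_jobs)
    jobs: list[Job] = []
    cur: list[T] = []
    acc = 0
    for s, e in zip(sites, est):
        cur.append(s)
        acc += e
        if acc >= target and len(jobs) < n_jobs - 1:
            jobs.append(Job(len(jobs), tuple(cur), acc))
            cur, acc = [], 0
    if cur:
        jobs.append(Job(len(jobs), tuple(cur), acc))
    return jobs


def default_workers() -> int:
    return os.cpu_count() or 1


def run_scatter_gather(jobs: Sequence[Job], worker: Callable[[Job], R],
                       merge: Callable[[R, R], R], identity: R,
                       n_workers: int = 1) -> R:
    """Run *worker* over *jobs* with *n_workers* threads and fold *merge*
    over the results in job-ordinal order.

    The result equals the sequential fold for every worker count (the
    bit-identical output contract).  A worker exception is re-raised as
    :class:`JobError` carrying the failing ordinal; remaining jobs are
    cancelled.
    """
    if not jobs:
        return identity
    n_workers = max(1, min(n_workers, len(jobs)))
    if n_workers == 1:
        acc = identity
        for job in jobs:
            try:
                acc = merge(acc, worker(job))
            except JobError:
                raise
            except Exception as e:
                raise JobError(job.ordinal, str(e)) from e
        return acc
    results: dict[int, R] = {}
    with ThreadPoolExecutor(max_workers=n_workers) as ex:
        futs = {ex.submit(worker, job): job for job in jobs}
        done, pending = wait(futs, return_when=FIRST_EXCEPTION)
        failed = None
        for fut in done:
            job = futs[fut]
            exc = fut.exception()
            if exc is not None:
                if failed is None or job.ordinal < failed[0].ordinal:
                    failed = (job, exc)
            else:
                results[job.ordinal] = fut.result()
        if failed is not None:
            for fut in pending:
                fut.cancel()
            job, exc = failed
            raise JobError(job.ordinal, str(exc)) from exc
    acc = identity
    for job in jobs:
        acc = merge(acc, results[job.ordinal])
    return acc
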