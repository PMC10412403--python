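"""High-level BAM reading: header + index + record iteration + region fetch."""

from __future__ import annotations

import os
import struct
from typing import Iterator, Optional

from . import bam
from .bam import BamHeader, BamRecord, parse_record, read_header, reference_span
from .bgzf import BgzfFile, VirtualOffset, VirtualReader
from .errors import InvalidRecordError, TruncationError
from .index import BaiIndex, query_chunks, read_bai


def iter_records_from(reader: VirtualReader, header: BamHeader,
                      ) -> Iterator[tuple[VirtualOffset, BamRecord, VirtualOffset]]:
    """Yield (start voffset, record, end voffset) from a positioned reader."""
    while True:
        v0 = reader.tell()
        head = reader.read(4)
        if not head:
            return
        if len(head) < 4:
            raise TruncationError(f"dangling {len(head)} bytes at {v0}")
        (block_size,) = struct.unpack("<i", head)
        body = reader.read(block_size)
        if len(body) != block_size:
            raise TruncationError(f"record at {v0} truncated")
        rec, _ = parse_record(head + body, 0, header)
        yield v0, rec, reader.tell()


class BamFile:
    """A BAM file opened for reading.

    Accepts a path or raw bytes; the index is loaded from ``<path>.bai`` when
    present, or may be supplied directly.  All readers created from one
    BamFile share the immutable compressed buffer, so region fetches from
    many threads are independent.
    """

    def __init__(self, source, index: Optional[BaiIndex] = None):
        self.bgzf = source if isinstance(source, BgzfFile) else BgzfFile(source)
        rdr = VirtualReader(self.bgzf, VirtualOffset(0, 0))
        self.header, _ = read_header(rdr)
        #: virtual offset of the first alignment record
        self.header_end: VirtualOffset = rdr.tell()
        self.index = index
        if index is None and isinstance(source, (str, os.PathLike)):
            bai = str(source) + ".bai"
            if os.path.exists(bai):
                self.index = read_bai(bai)

    # -- sequential access -------------------------------------------------
    def __iter__(self) -> Iterator[BamRecord]:
        for _, rec, _ in self.iter_with_offsets():
            yield rec

    def iter_with_offsets(self, v_beg: Optional[VirtualOffset] = None,
                          v_end: Optional[VirtualOffset] = None,
                          ) -> Iterator[tuple[VirtualOffset, BamRecord, VirtualOffset]]:
        rdr = VirtualReader(self.bgzf, v_beg or self.header_end, v_end)
        yield from iter_records_from(rdr, self.header)

    # -- indexed access ----------------------------------------------------
    def fetch(self, ref, beg: int, end: int) -> Iterator[BamRecord]:
        """Records overlapping [beg, end) on *ref* (name or id), in file order.

        Requires a coordinate-sorted, indexed file.  A placed record's extent
        is ``[pos, pos + max(1, reference span))`` — zero-span records count
        as one base so they cannot fall through window/overlap tests.
        """
        if self.index is None:
            raise InvalidRecordError("fetch requires an index")
        rid = self.header.ref_id(ref) if isinstance(ref, str) else ref
        if rid is None or rid < 0 or rid >= self.header.n_references:
            return
        for chunk in query_chunks(self.index, rid, beg, end):
            for _, rec, _ in self.iter_with_offsets(chunk.v_beg, chunk.v_end):
                if rec.ref_id != rid:
                    if rec.ref_id > rid:
                        return
                    continue
                if rec.pos >= end:
                    return
                if rec.pos + max(1, reference_span(rec.cigar)) > beg:
                    yield rec

    def fetch_starting_in(self, ref, beg: int, end: int) -> Iterator[BamRecord]:
        """Records whose alignment *start* lies in [beg, end): start-based
        window assignment, so a boundary-overlapping read belongs only to the
        window containing its start."""
        for rec in self.fetch(ref, beg, end):
            if beg <= rec.pos < end:
                yield rec

    def tail_start(self) -> VirtualOffset:
        """Virtual offset where the unplaced (refID −1) tail begins: past the
        last indexed chunk, or the first record if nothing is indexed."""
        if self.index is None:
            return self.header_end
        v = self.header_end
        for ri in self.index.references:
            if ri.off_end is not None and ri.off_end > v:
                v = ri.off_end
            for chunks in ri.bins.values():
                for c in chunks:
                    if c.v_end > v:
                        v = c.v_end
        return v
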