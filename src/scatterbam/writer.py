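"""Whole-file BAM writing with ground-truth offset capture."""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import BinaryIO, Optional, Sequence

from .bam import BamHeader, BamRecord, reference_span, write_header, write_record
from .bgzf import BgzfWriter, VirtualOffset
from .index import BaiIndex, build_bai


@dataclass
class BamWriteInfo:
    """Where everything landed: the writer's own record of truth."""

    header_end: VirtualOffset
    block_boundaries: list[int]
    #: (v_beg, v_end) per record, in file order
    record_voffsets: list[tuple[VirtualOffset, VirtualOffset]]


def write_bam(header: BamHeader, records: Sequence[BamRecord],
              out: BinaryIO) -> BamWriteInfo:
    """Serialize header + records as BGZF-compressed BAM.

    The header is flushed into its own block(s) so the first record starts a
    fresh block.  Records are written in the given order; no sorting is done
    here.
    """
    w = BgzfWriter(out)
    w.write(write_header(header))
    w.flush_block()
    header_end = w.tell()
    voffs = []
    for r in records:
        v0 = w.tell()
        w.write(write_record(r, header))
        voffs.append((v0, None))
        voffs[-1] = (v0, w.tell())
    w.close()
    return BamWriteInfo(header_end=header_end, block_boundaries=list(w.block_offsets),
                        record_voffsets=voffs)


def write_bam_bytes(header: BamHeader, records: Sequence[BamRecord],
                    ) -> tuple[bytes, BamWriteInfo]:
    buf = io.BytesIO()
    info = write_bam(header, records, buf)
    return buf.getvalue(), info


def index_from_write(header: BamHeader, records: Sequence[BamRecord],
                     info: BamWriteInfo) -> BaiIndex:
    """Build a BAI from a written, coordinate-sorted record list."""
    placed = []
    n_no_coor = 0
    for r, (v0, v1) in zip(records, info.record_voffsets):
        if r.ref_id < 0:
            n_no_coor += 1
            continue
        end = r.pos + max(1, reference_span(r.cigar))
        placed.append((r.ref_id, r.pos, end, v0, v1))
    return build_bai(placed, header, n_no_coor=n_no_coor)
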