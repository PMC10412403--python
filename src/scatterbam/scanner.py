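"""Heuristic recovery of parse start points in BAMs without an index.

Two layers.  The block layer scans raw bytes for BGZF framing and accepts an
offset only after a full test-inflate with CRC check — magic bytes alone
occur by chance inside compressed payloads.  The record layer scans a
decompressed buffer for a byte offset from which ``k_confirm`` consecutive
candidate records all pass a cheap structural validation predicate, each
chained candidate starting exactly where the previous one's declared size
ends; the chained conjunction makes the false-positive probability on
arbitrary bytes negligible, and truth-set tests enforce soundness
empirically.

This is what makes unsorted/unindexed files — and the unplaced-record tail
of indexed files — parallelizable: pick N raw offsets, resolve each to a
validated record start, and parse the segments between consecutive starts
independently.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from typing import Optional

from .bam import BamHeader, read_header
from .bgzf import BGZF_MAGIC, BgzfFile, VirtualOffset, VirtualReader, read_block
from .errors import NotABamError, ScatterbamError

#: consecutive records that must validate before a start point is accepted
DEFAULT_K_CONFIRM = 4

_FIXED = struct.Struct("<iiiBBHHHiiii")


@dataclass(frozen=True)
class ScanHit:
    """A validated record start: where, and how many records confirmed it."""

    voffset: VirtualOffset
    confirmed: int


def find_block_start(data: bytes, from_offset: int) -> Optional[int]:
    """Smallest offset ≥ *from_offset* where a BGZF block fully validates
    (framing, test-inflate, CRC); None if there is none."""
    o = from_offset
    while True:
        o = data.find(BGZF_MAGIC, o)
        if o < 0:
            return None
        try:
            read_block(data, o)
            return o
        except ScatterbamError:
            o += 1


def _validate_candidate(buf: bytes, o: int, header: BamHeader) -> Optional[int]:
    """Structural validation of one candidate record at buffer offset *o*.

    Checks: plausible block_size; refID and mate refID in range; positions
    within the named reference; read-name length in [1, 255] with a NUL at
    its declared end; all cigar op codes ≤ 8; plausible l_seq; computed
    fixed+variable sizes fit block_size.  Returns bytes consumed, or None.
    """
    if o + 36 > len(buf):
        return None
    (block_size, ref_id, pos, l_read_name, _mapq, _bin, n_cigar, _flag, l_seq,
     next_ref_id, next_pos, _tlen) = _FIXED.unpack_from(buf, o)
    if not (32 <= block_size <= 1 << 25):
        return None
    n_ref = header.n_references
    if not (-1 <= ref_id < n_ref) or not (-1 <= next_ref_id < n_ref):
        return None
    if ref_id >= 0:
        if not (-1 <= pos < header.ref_length(ref_id)):
            return None
    elif pos != -1:
        return None
    if next_ref_id >= 0:
        if not (-1 <= next_pos < header.ref_length(next_ref_id)):
            return None
    elif next_pos != -1:
        return None
    if not (1 <= l_read_name <= 255):
        return None
    if not (0 <= l_seq <= 1 << 28):
        return None
    var = l_read_name + 4 * n_cigar + (l_seq + 1) // 2 + l_seq
    if 32 + var > block_size + 4:
        return None
    name_end = o + 36 + l_read_name - 1
    if name_end >= len(buf):
        return None
    if buf[name_end] != 0:
        return None
    cig = o + 36 + l_read_name
    if cig + 4 * n_cigar > len(buf):
        return None
    for i in range(n_cigar):
        (word,) = struct.unpack_from("<I", buf, cig + 4 * i)
        if word & 0xF > 8:
            return None
    return block_size + 4


def find_record_start(buf: bytes, header: BamHeader,
                      k_confirm: int = DEFAULT_K_CONFIRM,
                      start: int = 0,
                      buffer_is_tail: bool = False) -> Optional[int]:
    """Smallest buffer offset ≥ *start* from which *k_confirm* chained
    candidates all validate; None if no offset qualifies.

    With ``buffer_is_tail`` the chain may be cut short by the true end of
    data: a chain of ≥ 1 records that ends exactly at the buffer end is
    accepted.  Earliest validating offset wins (left-to-right scan).
    """
    n = len(buf)
    for o in range(start, n):
        ok = _chain_length(buf, o, header, k_confirm)
        if ok >= k_confirm:
            return o
        if ok >= 1 and buffer_is_tail and _chain_end(buf, o, header, ok) == n:
            return o
    return None


def _chain_length(buf: bytes, o: int, header: BamHeader, k_cap: int) -> int:
    """How many consecutive candidates validate from *o* (capped at k_cap)."""
    ok, p = 0, o
    while ok < k_cap:
        used = _validate_candidate(buf, p, header)
        if used is None or p + used > len(buf):
            break
        p += used
        ok += 1
    return ok


def _chain_end(buf: bytes, o: int, header: BamHeader, k: int) -> int:
    p = o
    for _ in range(k):
        p += _validate_candidate(buf, p, header)
    return p


def resolve_probe(f: BgzfFile, raw_offset: int, header: BamHeader,
                  k_confirm: int = DEFAULT_K_CONFIRM,
                  min_voffset: Optional[VirtualOffset] = None) -> Optional[ScanHit]:
    """Resolve one raw file offset to the first validated record start at or
    after it (and at or after *min_voffset*, typically the header end)."""
    coffset = find_block_start(f.data, raw_offset)
    while coffset is not None:
        # inflate a window of blocks big enough to hold the confirm chain
        payloads: list[bytes] = []
        offsets: list[int] = []
        sizes: list[int] = []
        o, budget = coffset, 0
        while o < len(f) and budget < (k_confirm + 2) * 65536:
            try:
                blk = f.block_at(o)
            except ScatterbamError:
                break
            payloads.append(blk.payload)
            offsets.append(o)
            sizes.append(len(blk.payload))
            budget += len(blk.payload)
            o += blk.csize
        if not payloads:
            coffset = find_block_start(f.data, coffset + 4)
            continue
        at_eof = o >= len(f)
        start = 0
        if min_voffset is not None and VirtualOffset(coffset, 0) < min_voffset:
            if min_voffset.coffset >= o and not at_eof:
                coffset = find_block_start(f.data, min_voffset.coffset)
                continue
            acc, start = 0, None
            for off_i, sz in zip(offsets, sizes):
                if off_i == min_voffset.coffset:
                    start = acc + min_voffset.uoffset
                    break
                acc += sz
            if start is None:
                start = acc + min_voffset.uoffset if min_voffset.coffset >= o else 0
                if min_voffset.coffset >= o:
                    return None
        buf = b"".join(payloads)
        r = find_record_start(buf, header, k_confirm, start=start, buffer_is_tail=at_eof)
        if r is not None:
            k, acc = 0, 0
            while k < len(sizes) and r >= acc + sizes[k]:
                acc += sizes[k]
                k += 1
            if k == len(sizes):
                return None
            conf = _chain_length(buf, r, header, k_confirm)
            return ScanHit(VirtualOffset(offsets[k], r - acc), max(conf, 1))
        if at_eof:
            return None
        # no start validated inside this window: continue from its end
        coffset = find_block_start(f.data, o)
    return None


def scan_start_points(source, n_points: int, header: Optional[BamHeader] = None,
                      k_confirm: int = DEFAULT_K_CONFIRM,
                      region_start: Optional[VirtualOffset] = None) -> list[ScanHit]:
    """Resolve ~*n_points* evenly spaced raw offsets to validated record
    starts; deduplicated and sorted by virtual offset.

    The start of the scanned region (the first record after the header, or
    *region_start* when scanning e.g. the unplaced tail) is always included
    when records exist there, so the returned hits partition the data:
    parsing each ``[hit_i, hit_{i+1})`` segment (last segment to end of
    data) and concatenating reproduces a sequential parse exactly.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    f = source if isinstance(source, BgzfFile) else BgzfFile(source)
    if len(f) == 0 or find_block_start(f.data, 0) is None:
        raise NotABamError("no valid BGZF block found")
    if header is None:
        rdr = VirtualReader(f, VirtualOffset(0, 0))
        header, _ = read_header(rdr)
        begin = rdr.tell()
    else:
        rdr = VirtualReader(f, VirtualOffset(0, 0))
        _, _ = read_header(rdr)
        begin = rdr.tell()
    if region_start is not None and region_start > begin:
        begin = region_start
    hits: dict[int, ScanHit] = {}
    first = resolve_probe(f, begin.coffset, header, k_confirm, min_voffset=begin)
    if first is not None:
        hits[first.voffset.packed] = first
    lo, hi = begin.coffset, len(f)
    step = max(1, (hi - lo) // n_points)
    for i in range(n_points):
        hit = resolve_probe(f, lo + i * step, header, k_confirm, min_voffset=begin)
        if hit is not None:
            hits[hit.voffset.packed] = hit
    return [hits[k] for k in sorted(hits)]
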