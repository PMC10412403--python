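"""BAI index: build, read, write, and query.

The BAI format pairs a hierarchical binning index (bins of chunk intervals)
with a *linear index*: per 16-kb genomic window, the smallest virtual offset
of any record overlapping that window.  The linear index is what drives
parallel partitioning here — window start offsets give every worker an entry
point, and chunk extents give a cheap estimate of how much compressed data a
genomic interval spans, which is how jobs are sized.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field as dc_field
from typing import Iterable, NamedTuple, Optional

from .bgzf import VirtualOffset
from .errors import NotABaiError, RangeError, TruncationError, UnsortedInputError

#: window width of the linear index; fixed by the BAI format.
LINEAR_WINDOW = 16384
#: pseudo-bin carrying per-reference mapped/unmapped counts.
PSEUDO_BIN = 37450
MAX_POS = 1 << 29


class Chunk(NamedTuple):
    """A [v_beg, v_end) extent of the compressed file."""

    v_beg: VirtualOffset
    v_end: VirtualOffset


@dataclass
class RefIndex:
    """Index data for one reference."""

    bins: dict[int, list[Chunk]] = dc_field(default_factory=dict)
    #: entry i = smallest start voffset of any record overlapping window i;
    #: None where no record overlaps the window (gap entries are filled with
    #: the next non-empty window's offset only at serialization time).
    linear: list[Optional[VirtualOffset]] = dc_field(default_factory=list)
    n_mapped: int = 0
    n_unmapped: int = 0
    off_beg: Optional[VirtualOffset] = None
    off_end: Optional[VirtualOffset] = None


@dataclass
class BaiIndex:
    references: list[RefIndex]
    n_no_coor: Optional[int] = None


def reg2bin(beg: int, end: int) -> int:
    """Smallest bin fully containing the 0-based half-open interval [beg, end)."""
    if not (0 <= beg < end <= MAX_POS):
        raise RangeError(f"interval [{beg}, {end}) outside [0, 2^29]")
    end -= 1
    if beg >> 14 == end >> 14:
        return ((1 << 15) - 1) // 7 + (beg >> 14)
    if beg >> 17 == end >> 17:
        return ((1 << 12) - 1) // 7 + (beg >> 17)
    if beg >> 20 == end >> 20:
        return ((1 << 9) - 1) // 7 + (beg >> 20)
    if beg >> 23 == end >> 23:
        return ((1 << 6) - 1) // 7 + (beg >> 23)
    if beg >> 26 == end >> 26:
        return ((1 << 3) - 1) // 7 + (beg >> 26)
    return 0


def reg2bins(beg: int, end: int) -> list[int]:
    """All bins that may hold records overlapping [beg, end)."""
    if not (0 <= beg < end <= MAX_POS):
        raise RangeError(f"interval [{beg}, {end}) outside [0, 2^29]")
    end -= 1
    bins = [0]
    for shift, base in ((26, 1), (23, 9), (20, 73), (17, 585), (14, 4681)):
        bins.extend(range(base + (beg >> shift), base + (end >> shift) + 1))
    return bins


def build_bai(placed: Iterable[tuple[int, int, int, VirtualOffset, VirtualOffset]],
              header, n_no_coor: int = 0) -> BaiIndex:
    """Build an index from records in file order.

    *placed* yields ``(ref_id, pos, end, v_beg, v_end)`` per placed record
    (``end`` half-open; unmapped-but-placed records use span 1).  Records must
    be coordinate-sorted: non-decreasing (ref_id, pos).
    """
    refs = [RefIndex() for _ in header.references]
    last = (-1, -1)
    for ref_id, pos, end, v_beg, v_end in placed:
        if ref_id < 0:
            raise UnsortedInputError("unplaced record (refID -1) passed to build_bai")
        if (ref_id, pos) < last:
            raise UnsortedInputError(
                f"record at ref {ref_id} pos {pos} out of order after {last}"
            )
        last = (ref_id, pos)
        ri = refs[ref_id]
        b = reg2bin(pos, end)
        chunks = ri.bins.setdefault(b, [])
        if chunks and chunks[-1].v_end == v_beg:
            chunks[-1] = Chunk(chunks[-1].v_beg, v_end)
        else:
            chunks.append(Chunk(v_beg, v_end))
        w_lo, w_hi = pos // LINEAR_WINDOW, (end - 1) // LINEAR_WINDOW
        if len(ri.linear) <= w_hi:
            ri.linear.extend([None] * (w_hi + 1 - len(ri.linear)))
        for w in range(w_lo, w_hi + 1):
            if ri.linear[w] is None or v_beg < ri.linear[w]:
                ri.linear[w] = v_beg
        ri.n_mapped += 1
        ri.off_beg = v_beg if ri.off_beg is None else min(ri.off_beg, v_beg)
        ri.off_end = v_end if ri.off_end is None else max(ri.off_end, v_end)
    return BaiIndex(references=refs, n_no_coor=n_no_coor)


def _filled_linear(ri: RefIndex) -> list[VirtualOffset]:
    """Gap-fill: empty windows take the next non-empty window's offset;
    trailing gaps take the last non-empty offset."""
    out: list[VirtualOffset] = []
    nxt: Optional[VirtualOffset] = None
    filled: list[Optional[VirtualOffset]] = [None] * len(ri.linear)
    for i in range(len(ri.linear) - 1, -1, -1):
        if ri.linear[i] is not None:
            nxt = ri.linear[i]
        filled[i] = nxt
    last = VirtualOffset(0, 0)
    for v in filled:
        if v is None:
            v = last
        out.append(v)
        last = v
    return out


def write_bai(index: BaiIndex, path) -> None:
    parts = [b"BAI\x01", struct.pack("<i", len(index.references))]
    for ri in index.references:
        bins = dict(ri.bins)
        n_bin = len(bins) + (1 if ri.off_beg is not None else 0)
        parts.append(struct.pack("<i", n_bin))
        for b in sorted(bins):
            chunks = bins[b]
            parts.append(struct.pack("<Ii", b, len(chunks)))
            for c in chunks:
                parts.append(struct.pack("<QQ", c.v_beg.packed, c.v_end.packed))
        if ri.off_beg is not None:
            parts.append(struct.pack("<Ii", PSEUDO_BIN, 2))
            parts.append(struct.pack("<QQ", ri.off_beg.packed, ri.off_end.packed))
            parts.append(struct.pack("<QQ", ri.n_mapped, ri.n_unmapped))
        lin = _filled_linear(ri)
        parts.append(struct.pack("<i", len(lin)))
        for v in lin:
            parts.append(struct.pack("<Q", v.packed))
    if index.n_no_coor is not None:
        parts.append(struct.pack("<Q", index.n_no_coor))
    with open(path, "wb") as fh:
        fh.write(b"".join(parts))


def read_bai(path) -> BaiIndex:
    with open(path, "rb") as fh:
        data = fh.read()
    if data[:4] != b"BAI\x01":
        raise NotABaiError(f"bad magic {data[:4]!r}")
    off = 4

    def take(fmt: str):
        nonlocal off
        size = struct.calcsize(fmt)
        if off + size > len(data):
            raise TruncationError("BAI structure truncated")
        vals = struct.unpack_from(fmt, data, off)
        off += size
        return vals

    (n_ref,) = take("<i")
    refs = []
    for _ in range(n_ref):
        ri = RefIndex()
        (n_bin,) = take("<i")
        for _ in range(n_bin):
            b, n_chunk = take("<Ii")
            chunks = []
            for _ in range(n_chunk):
                vb, ve = take("<QQ")
                chunks.append(Chunk(VirtualOffset.from_packed(vb), VirtualOffset.from_packed(ve)))
            if b == PSEUDO_BIN:
                if len(chunks) >= 2:
                    ri.off_beg, ri.off_end = chunks[0]
                    ri.n_mapped = chunks[1].v_beg.packed
                    ri.n_unmapped = chunks[1].v_end.packed
            else:
                ri.bins[b] = chunks
        (n_intv,) = take("<i")
        for _ in range(n_intv):
            (v,) = take("<Q")
            ri.linear.append(VirtualOffset.from_packed(v))
        refs.append(ri)
    n_no_coor = None
    if off + 8 <= len(data):
        (n_no_coor,) = struct.unpack_from("<Q", data, off)
    return BaiIndex(references=refs, n_no_coor=n_no_coor)


def window_start_offsets(index: BaiIndex, ref: int) -> list[tuple[int, VirtualOffset]]:
    """(window index, start virtual offset) per non-empty 16-kb window.

    On an index read back from disk, gap-filled entries are indistinguishable
    from genuinely occupied ones, so every serialized entry is reported.
    """
    ri = index.references[ref]
    return [(i, v) for i, v in enumerate(ri.linear) if v is not None]


def _linear_bound(ri: RefIndex, beg: int) -> Optional[VirtualOffset]:
    w = beg // LINEAR_WINDOW
    for i in range(w, len(ri.linear)):
        if ri.linear[i] is not None:
            return ri.linear[i]
    return None


def query_chunks(index: BaiIndex, ref: int, beg: int, end: int) -> list[Chunk]:
    """Merged, sorted chunk list covering all records overlapping [beg, end).

    Chunks ending before the linear-index lower bound for *beg* are pruned;
    overlapping or abutting chunks are merged.
    """
    if not (0 <= beg < end):
        raise RangeError(f"bad interval [{beg}, {end})")
    ri = index.references[ref]
    bound = _linear_bound(ri, beg)
    raw: list[Chunk] = []
    for b in reg2bins(beg, min(end, MAX_POS)):
        for c in ri.bins.get(b, ()):
            if bound is not None and c.v_end <= bound:
                continue
            raw.append(c)
    raw.sort()
    merged: list[Chunk] = []
    for c in raw:
        if merged and c.v_beg <= merged[-1].v_end:
            if c.v_end > merged[-1].v_end:
                merged[-1] = Chunk(merged[-1].v_beg, c.v_end)
        else:
            merged.append(c)
    return merged


def span_compressed_bytes(index: BaiIndex, ref: int, beg: int, end: int) -> int:
    """Compressed bytes spanned by [beg, end): sum of merged-chunk coffset
    extents.  Monotone in the interval; sub-additive over adjacent regions."""
    return sum(c.v_end.coffset - c.v_beg.coffset for c in query_chunks(index, ref, beg, end))
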