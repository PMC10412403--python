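"""BGZF block codec and virtual file offsets.

BGZF is the blocked-gzip framing BAM uses: a file is a series of independent
gzip members, each at most 64 KiB compressed, carrying a ``BC`` extra subfield
with the member's total size.  Because every block inflates independently, any
number of readers can decompress disjoint block ranges of one file
concurrently — the property the rest of this package builds on.

A position inside the decompressed stream is addressed by a *virtual offset*:
the compressed-file offset of the containing block (48 bits) packed above the
offset within that block's inflated payload (16 bits).  Packed virtual offsets
order exactly like file layout order.
"""

from __future__ import annotations

import os
import struct
import zlib
from dataclasses import dataclass
from typing import BinaryIO, Iterator, NamedTuple, Union

from .errors import (
    BlockCorruptionError,
    BlockSizeError,
    MalformedBlockError,
    RangeError,
    TruncatedBlockError,
)

#: gzip member magic with FLG.FEXTRA set, as BGZF requires.
BGZF_MAGIC = b"\x1f\x8b\x08\x04"

#: The canonical 28-byte BGZF end-of-file marker: an empty-payload block.
BGZF_EOF = bytes.fromhex("1f8b08040000000000ff0600424302001b0003000000000000000000")

#: Fixed DEFLATE level for all written blocks; byte-determinism at a fixed
#: level is part of the writer contract.
COMPRESSION_LEVEL = 6

#: Largest payload accepted by write_block (BSIZE-1 must fit 16 bits).
MAX_BLOCK_PAYLOAD = 65535

#: The streaming writer flushes at this payload size, leaving headroom so the
#: compressed member always fits the 16-bit BSIZE field even when the payload
#: is incompressible (htslib uses the same 0xff00 threshold).
WRITER_FLUSH_SIZE = 0xFF00

_HEADER = struct.Struct("<4sIBBHBBHH")  # magic, mtime, xfl, os, xlen, SI1, SI2, SLEN, BSIZE-1
_TRAILER = struct.Struct("<II")  # crc32, isize


class VirtualOffset(NamedTuple):
    """Two-part coordinate into a BGZF file.

    ``coffset`` is the compressed-file offset of the containing block;
    ``uoffset`` the offset within the block's decompressed payload.  Tuple
    ordering is lexicographic, which coincides with packed-integer ordering.
    """

    coffset: int
    uoffset: int

    @property
    def packed(self) -> int:
        return pack_voffset(self.coffset, self.uoffset)

    @classmethod
    def from_packed(cls, v: int) -> "VirtualOffset":
        return cls(*unpack_voffset(v))

    def __repr__(self) -> str:  # compact, log-friendly
        return f"voff({self.coffset},{self.uoffset})"


def pack_voffset(coffset: int, uoffset: int) -> int:
    """Pack (coffset, uoffset) into the 64-bit virtual offset used by BAI."""
    if not (0 <= coffset < 1 << 48):
        raise RangeError(f"coffset {coffset} outside [0, 2^48)")
    if not (0 <= uoffset < 1 << 16):
        raise RangeError(f"uoffset {uoffset} outside [0, 2^16)")
    return (coffset << 16) | uoffset


def unpack_voffset(v: int) -> tuple[int, int]:
    if not (0 <= v < 1 << 64):
        raise RangeError(f"virtual offset {v} outside [0, 2^64)")
    return v >> 16, v & 0xFFFF


@dataclass(frozen=True)
class BgzfBlock:
    """One decoded BGZF block: where it sat, how big it was, what it held."""

    coffset: int
    csize: int
    payload: bytes


def write_block(payload: bytes) -> bytes:
    """Serialize *payload* as one complete BGZF block.

    Deterministic for a fixed payload (fixed DEFLATE level, zeroed MTIME/XFL,
    OS byte 0xff).  ``write_block(b"")`` is byte-identical to the standard
    BGZF end-of-file marker.
    """
    if len(payload) > MAX_BLOCK_PAYLOAD:
        raise BlockSizeError(f"payload of {len(payload)} bytes exceeds {MAX_BLOCK_PAYLOAD}")
    co = zlib.compressobj(COMPRESSION_LEVEL, zlib.DEFLATED, -15)
    cdata = co.compress(payload) + co.flush()
    bsize = len(cdata) + 26  # 18-byte header + 8-byte trailer
    if bsize > 65536:
        raise BlockSizeError(
            f"compressed block of {bsize} bytes does not fit the 16-bit BSIZE field"
        )
    header = _HEADER.pack(BGZF_MAGIC, 0, 0, 0xFF, 6, 66, 67, 2, bsize - 1)
    trailer = _TRAILER.pack(zlib.crc32(payload), len(payload))
    return header + cdata + trailer


def _block_size_at(data: bytes, offset: int) -> int:
    """Parse the framing at *offset* and return the declared total block size."""
    if data[offset : offset + 4] != BGZF_MAGIC:
        raise MalformedBlockError(f"no BGZF magic at offset {offset}")
    if offset + 12 > len(data):
        raise TruncatedBlockError(f"block header at {offset} truncated")
    xlen = struct.unpack_from("<H", data, offset + 10)[0]
    extra_end = offset + 12 + xlen
    if extra_end > len(data):
        raise TruncatedBlockError(f"block extra field at {offset} truncated")
    # walk extra subfields looking for BC
    p = offset + 12
    bsize = None
    while p + 4 <= extra_end:
        si1, si2, slen = struct.unpack_from("<BBH", data, p)
        if si1 == 66 and si2 == 67 and slen == 2:
            bsize = struct.unpack_from("<H", data, p + 4)[0] + 1
            break
        p += 4 + slen
    if bsize is None:
        raise MalformedBlockError(f"block at {offset} lacks a BC extra subfield")
    return bsize


def read_block(data: bytes, offset: int) -> BgzfBlock:
    """Decode the BGZF block starting at *offset* of *data*.

    Always inflates and verifies CRC32 and ISIZE; a block that frames
    correctly but fails either check raises :class:`BlockCorruptionError`.
    Pure with respect to *data*: concurrent readers never interfere.
    """
    bsize = _block_size_at(data, offset)
    if offset + bsize > len(data):
        raise TruncatedBlockError(
            f"block at {offset} declares {bsize} bytes but only {len(data) - offset} remain"
        )
    xlen = struct.unpack_from("<H", data, offset + 10)[0]
    cdata = data[offset + 12 + xlen : offset + bsize - 8]
    try:
        payload = zlib.decompress(cdata, -15)
    except zlib.error as e:
        raise BlockCorruptionError(f"block at {offset} failed to inflate: {e}") from e
    crc, isize = _TRAILER.unpack_from(data, offset + bsize - 8)
    if len(payload) != isize:
        raise BlockCorruptionError(f"block at {offset}: ISIZE {isize} != payload {len(payload)}")
    if zlib.crc32(payload) != crc:
        raise BlockCorruptionError(f"block at {offset}: CRC32 mismatch")
    return BgzfBlock(coffset=offset, csize=bsize, payload=payload)


def is_eof_block(data: bytes) -> bool:
    """True iff *data* is exactly the 28-byte BGZF end-of-file marker."""
    return data == BGZF_EOF


Source = Union[bytes, bytearray, str, os.PathLike, BinaryIO]


class BgzfFile:
    """Random-access view of a whole BGZF file with a per-block decode cache.

    The compressed bytes are held in memory (files at this package's working
    scale are a few MiB); decoded payloads are cached per block offset so
    overlapping range reads do not re-inflate.
    """

    def __init__(self, source: Source, cache_blocks: int = 512):
        if isinstance(source, (bytes, bytearray)):
            self.data = bytes(source)
        elif isinstance(source, (str, os.PathLike)):
            with open(source, "rb") as fh:
                self.data = fh.read()
        else:
            self.data = source.read()
        self._cache: dict[int, BgzfBlock] = {}
        self._cache_blocks = cache_blocks

    def __len__(self) -> int:
        return len(self.data)

    def block_at(self, coffset: int) -> BgzfBlock:
        blk = self._cache.get(coffset)
        if blk is None:
            blk = read_block(self.data, coffset)
            if len(self._cache) >= self._cache_blocks:
                self._cache.pop(next(iter(self._cache)))
            self._cache[coffset] = blk
        return blk

    def block_offsets(self) -> list[int]:
        """Offsets of every block, by walking the framing sequentially."""
        out, o = [], 0
        while o < len(self.data):
            out.append(o)
            o += _block_size_at(self.data, o)
        return out


class VirtualReader:
    """Sequential byte source over ``[v_beg, v_end)`` of a BGZF file.

    ``v_end=None`` reads to end of file.  ``tell()`` reports the virtual
    offset of the next byte; when a block is exhausted the position rolls to
    ``(next block coffset, 0)``, matching the convention BAM indices use for
    record start offsets.
    """

    def __init__(self, bgzf: BgzfFile, v_beg: VirtualOffset = VirtualOffset(0, 0),
                 v_end: VirtualOffset | None = None):
        if v_end is not None and v_end < v_beg:
            raise RangeError(f"range end {v_end} before start {v_beg}")
        self._f = bgzf
        self._end = v_end
        self._coffset = v_beg.coffset
        if self._coffset >= len(bgzf):
            self._payload = b""
            self._upos = 0
            if v_beg.uoffset:
                raise MalformedBlockError("range start beyond end of file")
        else:
            blk = bgzf.block_at(self._coffset)
            if v_beg.uoffset > len(blk.payload):
                raise MalformedBlockError(
                    f"uoffset {v_beg.uoffset} beyond payload of block at {self._coffset}"
                )
            self._payload = blk.payload
            self._upos = v_beg.uoffset
            self._csize = blk.csize

    def _advance_block(self) -> bool:
        """Load the next block; False at end of range/file."""
        nxt = self._coffset + self._csize
        if nxt >= len(self._f):
            return False
        if self._end is not None and VirtualOffset(nxt, 0) >= self._end:
            # still allowed when v_end lies inside this next block
            if self._end.coffset != nxt or self._end.uoffset == 0:
                return False
        blk = self._f.block_at(nxt)
        self._coffset = nxt
        self._payload = blk.payload
        self._csize = blk.csize
        self._upos = 0
        return True

    def _avail(self) -> int:
        hi = len(self._payload)
        if self._end is not None and self._end.coffset == self._coffset:
            hi = min(hi, self._end.uoffset)
        return hi - self._upos

    def read(self, n: int = -1) -> bytes:
        """Read up to *n* bytes (all remaining if negative)."""
        chunks: list[bytes] = []
        want = n
        while want != 0:
            avail = self._avail()
            if avail <= 0:
                if self._end is not None and VirtualOffset(self._coffset, self._upos) >= self._end:
                    break
                if self._upos >= len(self._payload):
                    if not self._advance_block():
                        break
                    continue
                break
            take = avail if want < 0 else min(avail, want)
            chunks.append(self._payload[self._upos : self._upos + take])
            self._upos += take
            if want > 0:
                want -= take
        return b"".join(chunks)

    def tell(self) -> VirtualOffset:
        if self._upos >= len(self._payload):
            # block exhausted: the next byte sits at the following block's
            # start — adjacency makes that coffset + csize, no decode needed
            nxt = min(self._coffset + getattr(self, "_csize", 0), len(self._f))
            if nxt > self._coffset:
                return VirtualOffset(nxt, 0)
        return VirtualOffset(self._coffset, self._upos)


def open_decompressed_range(source: Source | BgzfFile, v_beg: VirtualOffset,
                            v_end: VirtualOffset | None = None) -> VirtualReader:
    """Open a sequential reader over the decompressed bytes in ``[v_beg, v_end)``.

    Ranges opened concurrently on one :class:`BgzfFile` are independent: each
    reader carries its own cursor and blocks decode purely from the shared
    immutable byte buffer.
    """
    f = source if isinstance(source, BgzfFile) else BgzfFile(source)
    return VirtualReader(f, v_beg, v_end)


def iter_blocks(source: Source | BgzfFile) -> Iterator[BgzfBlock]:
    """Decode every block of a BGZF file in layout order."""
    f = source if isinstance(source, BgzfFile) else BgzfFile(source)
    o = 0
    while o < len(f):
        blk = f.block_at(o)
        yield blk
        o += blk.csize


def decompress_all(source: Source | BgzfFile) -> bytes:
    """Whole-file single-stream decompression (the partition-property oracle)."""
    return b"".join(b.payload for b in iter_blocks(source))


class BgzfWriter:
    """Streaming BGZF writer that remembers where everything landed.

    Buffers written bytes and emits a block whenever the payload reaches
    :data:`WRITER_FLUSH_SIZE`.  ``tell()`` returns the virtual offset the next
    written byte will occupy, which is how callers (the BAM writer, the
    simulator) record record start offsets and block boundaries as ground
    truth.  ``close()`` appends the end-of-file marker exactly once.
    """

    def __init__(self, fileobj: BinaryIO):
        self._out = fileobj
        self._buf = bytearray()
        self._coffset = 0
        self.block_offsets: list[int] = []
        self._closed = False

    def write(self, data: bytes) -> None:
        self._buf += data
        while len(self._buf) >= WRITER_FLUSH_SIZE:
            self._emit(bytes(self._buf[:WRITER_FLUSH_SIZE]))
            del self._buf[:WRITER_FLUSH_SIZE]

    def _emit(self, payload: bytes) -> None:
        blk = write_block(payload)
        self._out.write(blk)
        self.block_offsets.append(self._coffset)
        self._coffset += len(blk)

    def flush_block(self) -> None:
        """Force the current buffer out as a block (used to end the header)."""
        if self._buf:
            self._emit(bytes(self._buf))
            self._buf.clear()

    def tell(self) -> VirtualOffset:
        return VirtualOffset(self._coffset, len(self._buf))

    def close(self) -> None:
        if self._closed:
            return
        self.flush_block()
        self._out.write(BGZF_EOF)
        self.block_offsets.append(self._coffset)
        self._coffset += len(BGZF_EOF)
        self._closed = True

    def __enter__(self) -> "BgzfWriter":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
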