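"""BAM binary header and alignment-record codec.

Implements the BAM v1 layout: magic ``BAM\\1``, little-endian fields, 4-bit
packed sequences, CIGAR op coding ``MIDNSHP=X`` → 0–8.  Coordinates are
0-based half-open everywhere inside this package; 1-based numbers appear only
at VCF/CSV/CLI boundaries.  Optional-field (tag) bytes are carried opaquely
and round-tripped untouched.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from enum import IntFlag
from typing import Iterator, Optional, Protocol

from .errors import (
    InvalidRecordError,
    NotABamError,
    TruncationError,
    UndefinedCoordinateError,
)

BAM_MAGIC = b"BAM\x01"

CIGAR_OPS = "MIDNSHP=X"
_CIGAR_CODE = {op: i for i, op in enumerate(CIGAR_OPS)}
#: ops that consume reference bases
_REF_CONSUMING = frozenset("MDN=X")
#: ops that consume query (read) bases
_QUERY_CONSUMING = frozenset("MIS=X")

SEQ_ALPHABET = "=ACMGRSVTWYHKDBN"
_SEQ_CODE = {b: i for i, b in enumerate(SEQ_ALPHABET)}


class FlagBits(IntFlag):
    """SAM flag bits."""

    PAIRED = 0x1
    PROPER_PAIR = 0x2
    UNMAP = 0x4
    MUNMAP = 0x8
    REVERSE = 0x10
    MREVERSE = 0x20
    READ1 = 0x40
    READ2 = 0x80
    SECONDARY = 0x100
    QCFAIL = 0x200
    DUP = 0x400
    SUPPLEMENTARY = 0x800


@dataclass(frozen=True)
class BamHeader:
    """SAM header text plus the ordered reference dictionary.

    Reference list order defines refID numbering from 0.
    """

    text: str = ""
    references: tuple[tuple[str, int], ...] = ()

    def __post_init__(self):
        names = [n for n, _ in self.references]
        if len(set(names)) != len(names) or any(not n for n in names):
            raise InvalidRecordError("reference names must be unique and non-empty")
        object.__setattr__(self, "_name_to_id", {n: i for i, (n, _) in enumerate(self.references)})

    def ref_id(self, name: str) -> Optional[int]:
        return self._name_to_id.get(name)

    def ref_length(self, rid: int) -> int:
        return self.references[rid][1]

    @property
    def n_references(self) -> int:
        return len(self.references)


@dataclass
class BamRecord:
    """One alignment in (near-)binary layout.

    ``qual`` is None when absent (all 0xff in the file); ``tags`` is the raw
    optional-field byte-string, never decoded.
    """

    read_name: str
    flag: int = 0
    ref_id: int = -1
    pos: int = -1  # 0-based leftmost coordinate
    mapq: int = 0
    cigar: tuple[tuple[str, int], ...] = ()
    seq: str = ""
    qual: Optional[tuple[int, ...]] = None
    next_ref_id: int = -1
    next_pos: int = -1
    tlen: int = 0
    tags: bytes = b""

    # -- flag predicates ---------------------------------------------------
    @property
    def is_unmapped(self) -> bool:
        return bool(self.flag & FlagBits.UNMAP)

    @property
    def is_paired(self) -> bool:
        return bool(self.flag & FlagBits.PAIRED)

    @property
    def is_secondary(self) -> bool:
        return bool(self.flag & FlagBits.SECONDARY)

    @property
    def is_supplementary(self) -> bool:
        return bool(self.flag & FlagBits.SUPPLEMENTARY)

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flag & FlagBits.DUP)

    @property
    def is_qcfail(self) -> bool:
        return bool(self.flag & FlagBits.QCFAIL)


def reference_span(cigar) -> int:
    """Reference bases consumed by a CIGAR (M, D, N, =, X)."""
    return sum(n for op, n in cigar if op in _REF_CONSUMING)


def query_length(cigar) -> int:
    """Query bases consumed by a CIGAR (M, I, S, =, X)."""
    return sum(n for op, n in cigar if op in _QUERY_CONSUMING)


def end_pos(r: BamRecord) -> int:
    """Half-open alignment end.

    A mapped record with a zero-span CIGAR (e.g. no CIGAR at all) is treated
    as spanning one base so it cannot vanish from window assignment or
    overlap tests.
    """
    if r.is_unmapped or r.ref_id < 0 or r.pos < 0:
        raise UndefinedCoordinateError(f"record {r.read_name!r} is unmapped")
    return r.pos + max(1, reference_span(r.cigar))


def decode_seq(packed: bytes, l_seq: int) -> str:
    """Unpack a 4-bit-per-base sequence; the high nibble is the earlier base."""
    out = []
    for i in range(l_seq):
        b = packed[i >> 1]
        out.append(SEQ_ALPHABET[(b >> 4) if i % 2 == 0 else (b & 0xF)])
    return "".join(out)


def encode_seq(seq: str) -> bytes:
    out = bytearray((len(seq) + 1) // 2)
    for i, ch in enumerate(seq):
        try:
            code = _SEQ_CODE[ch]
        except KeyError:
            raise InvalidRecordError(f"base {ch!r} outside the 16-letter alphabet") from None
        if i % 2 == 0:
            out[i >> 1] = code << 4
        else:
            out[i >> 1] |= code
    return bytes(out)


class _Readable(Protocol):
    def read(self, n: int) -> bytes: ...


def read_header(source) -> tuple[BamHeader, int]:
    """Parse the BAM header from a byte source.

    *source* may be bytes or any object with ``read(n)``.  Returns the header
    and the decompressed-stream offset of the first alignment record.
    """
    if isinstance(source, (bytes, bytearray)):
        import io

        source = io.BytesIO(source)

    def take(n: int, what: str) -> bytes:
        b = source.read(n)
        if len(b) != n:
            raise TruncationError(f"header truncated while reading {what}")
        return b

    magic = take(4, "magic")
    if magic != BAM_MAGIC:
        raise NotABamError(f"bad magic {magic!r}")
    consumed = 4
    (l_text,) = struct.unpack("<i", take(4, "l_text"))
    consumed += 4
    text = take(l_text, "header text").decode("ascii", errors="replace").rstrip("\x00")
    consumed += l_text
    (n_ref,) = struct.unpack("<i", take(4, "n_ref"))
    consumed += 4
    refs = []
    for _ in range(n_ref):
        (l_name,) = struct.unpack("<i", take(4, "l_name"))
        name = take(l_name, "reference name")[:-1].decode("ascii")
        (l_ref,) = struct.unpack("<i", take(4, "l_ref"))
        consumed += 8 + l_name
        refs.append((name, l_ref))
    return BamHeader(text=text, references=tuple(refs)), consumed


def write_header(header: BamHeader) -> bytes:
    text = header.text.encode("ascii")
    parts = [BAM_MAGIC, struct.pack("<i", len(text)), text,
             struct.pack("<i", len(header.references))]
    for name, length in header.references:
        nb = name.encode("ascii") + b"\x00"
        parts.append(struct.pack("<i", len(nb)) + nb + struct.pack("<i", length))
    return b"".join(parts)


_FIXED = struct.Struct("<iiiBBHHHiiii")  # block_size..tlen


def parse_record(buffer: bytes, offset: int, header: BamHeader) -> tuple[BamRecord, int]:
    """Decode one alignment record starting at *offset*; returns (record,
    bytes_consumed) where bytes_consumed = block_size + 4."""
    if offset + 4 > len(buffer):
        raise InvalidRecordError(f"truncated record at offset {offset}: no block_size")
    (block_size,) = struct.unpack_from("<i", buffer, offset)
    if block_size < 32:
        raise InvalidRecordError(f"record at {offset}: block_size {block_size} too small")
    if offset + 4 + block_size > len(buffer):
        raise InvalidRecordError(f"record at {offset}: truncated mid-record")
    (_, ref_id, pos, l_read_name, mapq, _bin, n_cigar, flag, l_seq,
     next_ref_id, next_pos, tlen) = _FIXED.unpack_from(buffer, offset)
    if ref_id >= header.n_references or ref_id < -1:
        raise InvalidRecordError(f"record at {offset}: refID {ref_id} out of range")
    if next_ref_id >= header.n_references or next_ref_id < -1:
        raise InvalidRecordError(f"record at {offset}: next_refID {next_ref_id} out of range")
    if l_read_name < 1:
        raise InvalidRecordError(f"record at {offset}: l_read_name {l_read_name} < 1")
    var_len = l_read_name + 4 * n_cigar + (l_seq + 1) // 2 + l_seq
    if 32 + var_len > block_size + 4:
        raise InvalidRecordError(
            f"record at {offset}: computed field lengths exceed block_size"
        )
    p = offset + 36
    name = buffer[p : p + l_read_name - 1].decode("ascii")
    p += l_read_name
    cigar = []
    for i in range(n_cigar):
        (word,) = struct.unpack_from("<I", buffer, p)
        op = word & 0xF
        if op > 8:
            raise InvalidRecordError(f"record at {offset}: cigar op code {op} > 8")
        cigar.append((CIGAR_OPS[op], word >> 4))
        p += 4
    seq = decode_seq(buffer[p : p + (l_seq + 1) // 2], l_seq)
    p += (l_seq + 1) // 2
    qual_raw = buffer[p : p + l_seq]
    p += l_seq
    qual = None if all(q == 0xFF for q in qual_raw) and l_seq > 0 else tuple(qual_raw)
    if l_seq == 0:
        qual = None
    tags = bytes(buffer[p : offset + 4 + block_size])
    rec = BamRecord(read_name=name, flag=flag, ref_id=ref_id, pos=pos, mapq=mapq,
                    cigar=tuple(cigar), seq=seq, qual=qual, next_ref_id=next_ref_id,
                    next_pos=next_pos, tlen=tlen, tags=tags)
    return rec, block_size + 4


def write_record(r: BamRecord, header: BamHeader) -> bytes:
    """Serialize a record; deterministic; the bin field is recomputed from the
    record's coordinates rather than carried as state."""
    from .index import reg2bin  # local: index depends only on bgzf

    if not (1 <= len(r.read_name) <= 254):
        raise InvalidRecordError(f"read name length {len(r.read_name)} outside [1, 254]")
    if r.qual is not None and len(r.qual) != len(r.seq):
        raise InvalidRecordError("seq/qual length mismatch")
    if r.ref_id >= header.n_references:
        raise InvalidRecordError(f"refID {r.ref_id} not in header")
    if r.ref_id >= 0 and r.pos >= 0:
        bin_ = reg2bin(r.pos, r.pos + max(1, reference_span(r.cigar)))
    else:
        bin_ = 4680  # convention for unplaced records
    name_b = r.read_name.encode("ascii") + b"\x00"
    cigar_b = b"".join(
        struct.pack("<I", (n << 4) | _CIGAR_CODE[op]) for op, n in r.cigar
    )
    seq_b = encode_seq(r.seq)
    qual_b = bytes(r.qual) if r.qual is not None else b"\xff" * len(r.seq)
    body = struct.pack("<iiBBHHHiiii", r.ref_id, r.pos, len(name_b), r.mapq, bin_,
                       len(r.cigar), r.flag, len(r.seq), r.next_ref_id, r.next_pos,
                       r.tlen) + name_b + cigar_b + seq_b + qual_b + r.tags
    return struct.pack("<i", len(body)) + body


def iter_records(buffer: bytes, header: BamHeader, offset: int = 0) -> Iterator[tuple[int, BamRecord]]:
    """Yield (offset, record) for a concatenated record stream."""
    while offset < len(buffer):
        rec, used = parse_record(buffer, offset, header)
        yield offset, rec
        offset += used
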