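"""Reference-based read encoding and compression evaluation.

The demonstrator codec stores each read either as a *reference* record —
its position on a reference genome, strand, length, and the list of
differences needed to reconstruct it exactly — or, when no sufficiently
close alignment exists, as a *raw* record carrying the literal sequence.
Records are packed into a compact binary container (varint coordinates,
2-bit packed raw bases) which is then passed through general-purpose entropy
compression (zlib).  The codec covers the sequence stream only; read IDs and
quality strings are carried through to the entropy stage untransformed,
since the choice of reference only affects the sequence stream.

The round trip is lossless by construction: decoding takes the reference
substring ``[pos, pos + length)``, reverse-complements it for '-' strand
records, and applies the stored substitutions.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import shutil
import struct
import subprocess
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from .align import KmerIndex, align_read, reverse_complement, DEFAULT_SEED_LENGTH
from .catalog import Catalog
from .errors import (
    CorruptStreamError,
    ExternalToolNotFoundError,
    InvalidInputError,
    ReferenceChecksumError,
)
from .filters import select_best

MAGIC = b"CRZ1"
VERSION = 1
DEFAULT_MAX_DIFFS = 3

_TAG_REF_FWD = 0
_TAG_REF_REV = 1
_TAG_RAW_PACKED = 2
_TAG_RAW_LITERAL = 3

_BASE2BITS = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T
_BITS2BASE = b"ACGT"


@dataclass(frozen=True)
class EncodedRead:
    """One read in reference-based (REF) or literal (RAW) representation."""

    mode: str  # "REF" or "RAW"
    genome_index: int = 0
    pos: int = 0  # 1-based on the reference genome
    strand: str = "+"
    length: int = 0
    diffs: tuple[tuple[int, str], ...] = ()  # (0-based offset in read, base)
    sequence: str = ""  # RAW only


@dataclass
class CompressionReport:
    """Sizes and ratio for one compression run."""

    method: str
    original_bytes: int
    compressed_bytes: int
    reads_ref_encoded: int = 0
    reads_raw: int = 0
    command: str = ""

    @property
    def ratio(self) -> float:
        return self.original_bytes / self.compressed_bytes

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "original_bytes": self.original_bytes,
            "compressed_bytes": self.compressed_bytes,
            "ratio": self.ratio,
            "reads_ref_encoded": self.reads_ref_encoded,
            "reads_raw": self.reads_raw,
            "command": self.command,
        }


def reference_checksum(reference: Catalog) -> bytes:
    """MD5 over the ordered (genome_id, sequence) pairs of a catalog."""
    h = hashlib.md5()
    for rec in reference:
        h.update(b">" + rec.genome_id.encode() + b"\n")
        h.update(rec.sequence.encode() + b"\n")
    return h.digest()


# ---------------------------------------------------------------- encoding

def encode_read(
    index: KmerIndex,
    sequence: str,
    max_diffs: int = DEFAULT_MAX_DIFFS,
) -> EncodedRead:
    """Encode one read against the reference index; RAW is the fallback."""
    seq = sequence.upper()
    hits = [r for r in align_read(index, "q", seq) if r.is_mapped]
    best = select_best(hits) if hits else None
    if best is None or best.mismatches > max_diffs:
        return EncodedRead(mode="RAW", sequence=seq, length=len(seq))
    gi = index.id_to_index[best.genome_id]
    oriented = index.seqs[gi][best.pos - 1 : best.pos - 1 + len(seq)].decode()
    if best.is_reverse:
        oriented = reverse_complement(oriented)
    diffs = tuple(
        (i, seq[i]) for i in range(len(seq)) if seq[i] != oriented[i]
    )
    return EncodedRead(
        mode="REF",
        genome_index=gi,
        pos=best.pos,
        strand="-" if best.is_reverse else "+",
        length=len(seq),
        diffs=diffs,
    )


def encode_reads(
    reads: Iterable[tuple[str, str]],
    reference: Catalog,
    max_diffs: int = DEFAULT_MAX_DIFFS,
    seed_length: int = DEFAULT_SEED_LENGTH,
    index: KmerIndex | None = None,
) -> Iterator[EncodedRead]:
    """Encode ``(read_id, sequence)`` pairs; order-preserving, streaming."""
    if index is None:
        index = KmerIndex(reference, seed_length)
    for _, seq in reads:
        yield encode_read(index, seq, max_diffs)


def decode_reads(
    stream: Iterable[EncodedRead],
    reference: Catalog,
) -> Iterator[str]:
    """Exact original sequences, in original order (lossless round trip)."""
    seqs = [r.sequence for r in reference]
    for er in stream:
        if er.mode == "RAW":
            yield er.sequence
            continue
        if not 0 <= er.genome_index < len(seqs):
            raise CorruptStreamError(f"genome_index {er.genome_index} out of range")
        ref = seqs[er.genome_index]
        if er.pos < 1 or er.pos - 1 + er.length > len(ref):
            raise CorruptStreamError(
                f"position {er.pos}+{er.length} beyond reference end ({len(ref)})"
            )
        chunk = ref[er.pos - 1 : er.pos - 1 + er.length]
        if er.strand == "-":
            chunk = reverse_complement(chunk)
        if er.diffs:
            buf = bytearray(chunk.encode())
            last = -1
            for off, base in er.diffs:
                if not last < off < er.length:
                    raise CorruptStreamError(f"bad diff offset {off}")
                buf[off] = ord(base)
                last = off
            chunk = buf.decode()
        yield chunk


# ------------------------------------------------------------- container

def _write_varint(buf: bytearray, value: int) -> None:
    if value < 0:
        raise ValueError("varint must be nonnegative")
    while True:
        b = value & 0x7F
        value >>= 7
        if value:
            buf.append(b | 0x80)
        else:
            buf.append(b)
            return


def _read_varint(data: bytes, off: int) -> tuple[int, int]:
    shift = 0
    value = 0
    while True:
        if off >= len(data):
            raise CorruptStreamError("truncated varint")
        b = data[off]
        off += 1
        value |= (b & 0x7F) << shift
        if not b & 0x80:
            return value, off
        shift += 7


def pack_2bit(seq: str) -> bytes | None:
    """2-bit pack a pure-ACGT sequence; None if other characters occur."""
    out = bytearray((len(seq) + 3) // 4)
    for i, c in enumerate(seq.encode()):
        bits = _BASE2BITS.get(c)
        if bits is None:
            return None
        out[i >> 2] |= bits << ((i & 3) << 1)
    return bytes(out)


def unpack_2bit(data: bytes, length: int) -> str:
    return "".join(
        chr(_BITS2BASE[(data[i >> 2] >> ((i & 3) << 1)) & 3]) for i in range(length)
    )


def _encode_body(
    stream: Sequence[EncodedRead],
    ids_blob: bytes = b"",
    qual_blob: bytes = b"",
) -> bytes:
    buf = bytearray()
    _write_varint(buf, len(stream))
    for er in stream:
        if er.mode == "REF":
            buf.append(_TAG_REF_REV if er.strand == "-" else _TAG_REF_FWD)
            _write_varint(buf, er.genome_index)
            _write_varint(buf, er.pos)
            _write_varint(buf, er.length)
            _write_varint(buf, len(er.diffs))
            prev = -1
            for off, base in er.diffs:
                _write_varint(buf, off - prev - 1)
                buf.append(ord(base))
                prev = off
        else:
            packed = pack_2bit(er.sequence)
            if packed is not None:
                buf.append(_TAG_RAW_PACKED)
                _write_varint(buf, len(er.sequence))
                buf.extend(packed)
            else:
                buf.append(_TAG_RAW_LITERAL)
                _write_varint(buf, len(er.sequence))
                buf.extend(er.sequence.encode())
    _write_varint(buf, len(ids_blob))
    buf.extend(ids_blob)
    _write_varint(buf, len(qual_blob))
    buf.extend(qual_blob)
    return bytes(buf)


def _decode_body(data: bytes) -> tuple[list[EncodedRead], bytes, bytes]:
    off = 0
    n, off = _read_varint(data, off)
    stream: list[EncodedRead] = []
    for _ in range(n):
        if off >= len(data):
            raise CorruptStreamError("truncated container body")
        tag = data[off]
        off += 1
        if tag in (_TAG_REF_FWD, _TAG_REF_REV):
            gi, off = _read_varint(data, off)
            pos, off = _read_varint(data, off)
            length, off = _read_varint(data, off)
            nd, off = _read_varint(data, off)
            diffs = []
            prev = -1
            for _ in range(nd):
                delta, off = _read_varint(data, off)
                offset = prev + 1 + delta
                diffs.append((offset, chr(data[off])))
                off += 1
                prev = offset
            stream.append(
                EncodedRead(
                    mode="REF", genome_index=gi, pos=pos,
                    strand="-" if tag == _TAG_REF_REV else "+",
                    length=length, diffs=tuple(diffs),
                )
            )
        elif tag == _TAG_RAW_PACKED:
            length, off = _read_varint(data, off)
            nbytes = (length + 3) // 4
            seq = unpack_2bit(data[off : off + nbytes], length)
            off += nbytes
            stream.append(EncodedRead(mode="RAW", sequence=seq, length=length))
        elif tag == _TAG_RAW_LITERAL:
            length, off = _read_varint(data, off)
            seq = data[off : off + length].decode()
            off += length
            stream.append(EncodedRead(mode="RAW", sequence=seq, length=length))
        else:
            raise CorruptStreamError(f"unknown record tag {tag}")
    nid, off = _read_varint(data, off)
    ids_blob = data[off : off + nid]
    off += nid
    nq, off = _read_varint(data, off)
    qual_blob = data[off : off + nq]
    return stream, ids_blob, qual_blob


def serialize_container(
    stream: Sequence[EncodedRead],
    reference: Catalog,
    out: str | Path,
    ids_blob: bytes = b"",
    qual_blob: bytes = b"",
) -> int:
    """Write the binary container and return its compressed byte size.

    Layout: 4-byte magic, 1-byte version, 16-byte reference MD5, then the
    zlib-compressed body (read records + pass-through id/quality blobs).
    """
    body = _encode_body(list(stream), ids_blob, qual_blob)
    payload = MAGIC + bytes([VERSION]) + reference_checksum(reference) + zlib.compress(body, 9)
    out = Path(out)
    out.write_bytes(payload)
    return len(payload)


def deserialize_container(
    path: str | Path,
    reference: Catalog,
) -> tuple[list[EncodedRead], bytes, bytes]:
    """Read a container back; refuses when the reference checksum mismatches."""
    data = Path(path).read_bytes()
    if data[:4] != MAGIC:
        raise CorruptStreamError("not a cohortref container (bad magic)")
    if data[4] != VERSION:
        raise CorruptStreamError(f"unsupported container version {data[4]}")
    if data[5:21] != reference_checksum(reference):
        raise ReferenceChecksumError(
            "reference checksum mismatch: decoding requires the byte-identical "
            "reference used for encoding"
        )
    try:
        body = zlib.decompress(data[21:])
    except zlib.error as exc:
        raise CorruptStreamError(f"corrupt container body: {exc}") from exc
    return _decode_body(body)


# ------------------------------------------------------------- FASTQ level

def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (id_line, sequence, quality) from a FASTQ file (gzip transparent)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        while True:
            head = fh.readline()
            if not head:
                return
            seq = fh.readline().rstrip("\n")
            fh.readline()  # '+'
            qual = fh.readline().rstrip("\n")
            yield head.rstrip("\n"), seq, qual


def compress_fastq(
    fastq: str | Path,
    reference: Catalog,
    out: str | Path,
    max_diffs: int = DEFAULT_MAX_DIFFS,
    seed_length: int = DEFAULT_SEED_LENGTH,
) -> CompressionReport:
    """Reference-encode a FASTQ file into a native container."""
    index = KmerIndex(reference, seed_length)
    stream: list[EncodedRead] = []
    ids: list[str] = []
    quals: list[str] = []
    for head, seq, qual in read_fastq(fastq):
        ids.append(head)
        quals.append(qual)
        stream.append(encode_read(index, seq, max_diffs))
    size = serialize_container(
        stream, reference, out,
        ids_blob="\n".join(ids).encode(),
        qual_blob="\n".join(quals).encode(),
    )
    n_ref = sum(1 for er in stream if er.mode == "REF")
    return CompressionReport(
        method="native",
        original_bytes=Path(fastq).stat().st_size,
        compressed_bytes=size,
        reads_ref_encoded=n_ref,
        reads_raw=len(stream) - n_ref,
        command=f"cohortref native codec (max_diffs={max_diffs})",
    )


def decompress_fastq(container: str | Path, reference: Catalog,
                     out: str | Path) -> int:
    """Reconstruct the original FASTQ from a native container; returns read count."""
    stream, ids_blob, qual_blob = deserialize_container(container, reference)
    ids = ids_blob.decode().split("\n") if ids_blob else []
    quals = qual_blob.decode().split("\n") if qual_blob else []
    with open(out, "w") as fh:
        for head, seq, qual in zip(ids, decode_reads(stream, reference), quals):
            fh.write(f"{head}\n{seq}\n+\n{qual}\n")
    return len(stream)


# ------------------------------------------------------------- evaluation

def compression_ratio(original: str | Path, compressed: str | Path,
                      method: str = "sizes") -> CompressionReport:
    """Ratio = byte size of the original file / byte size of the compressed file."""
    original, compressed = Path(original), Path(compressed)
    for p in (original, compressed):
        if not p.exists():
            raise FileNotFoundError(p)
    csize = compressed.stat().st_size
    if csize < 1:
        raise InvalidInputError(f"compressed file {compressed} is empty")
    return CompressionReport(
        method=method,
        original_bytes=original.stat().st_size,
        compressed_bytes=csize,
    )


def run_external_compressor(
    tool: str,
    fastq: str | Path,
    reference: str | Path | None = None,
    out: str | Path | None = None,
    mode_flags: Sequence[str] = (),
) -> CompressionReport:
    """Adapter for external compressors (gzip baseline, genozip when installed).

    Raises :class:`ExternalToolNotFoundError` when the binary is absent; the
    exact command line is recorded in the report.
    """
    fastq = Path(fastq)
    if not fastq.exists():
        raise FileNotFoundError(fastq)
    binary = {"gzip": "gzip", "genozip": "genozip"}.get(tool)
    if binary is None:
        raise InvalidInputError(f"unknown compressor adapter {tool!r}")
    if shutil.which(binary) is None:
        raise ExternalToolNotFoundError(
            f"external compressor binary {binary!r} not found on PATH"
        )
    if tool == "gzip":
        out = Path(out) if out else fastq.with_suffix(fastq.suffix + ".gz.eval")
        cmd = ["gzip", "-c", *mode_flags, str(fastq)]
        with open(out, "wb") as fh:
            subprocess.run(cmd, stdout=fh, check=True)
    else:  # genozip
        out = Path(out) if out else fastq.with_suffix(fastq.suffix + ".genozip")
        cmd = [binary, *mode_flags]
        if reference is not None:
            cmd += ["--reference", str(reference)]
        cmd += ["--output", str(out), str(fastq)]
        subprocess.run(cmd, check=True)
    rep = compression_ratio(fastq, out, method=tool)
    rep.command = " ".join(cmd)
    return rep


def write_report(report: CompressionReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")
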