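"""Built-in ungapped seed-and-extend aligner.

A deliberately small aligner so the whole pipeline is testable without
external aligner binaries or genome downloads.  It is NOT a production
aligner (no gapped alignment, no base-quality model):

* the catalog is indexed by every k-mer position (default k = 21);
* each read is seeded with its non-overlapping k-mers, on both strands, so a
  read of length >= (m + 1) * k is guaranteed to be found at every locus with
  at most m substitutions;
* every distinct candidate locus is extended by full-length Hamming
  comparison and reported with ``mismatches`` = Hamming distance, CIGAR
  ``<len>M`` and ``align_score = len - 5 * mismatches``;
* MAPQ is a constant 60 for every mapped record, so the MAPQ filter never
  masks best-alignment selection when exercising the downstream filters.

Reads shorter than the seed length, and candidate loci where the read would
overhang the genome end, are reported unmapped / skipped.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Iterator

import numpy as np

from .catalog import Catalog
from .errors import InvalidInputError
from .filters import AlignmentRecord

DEFAULT_SEED_LENGTH = 21
MISMATCH_PENALTY = 5
BUILTIN_MAPQ = 60

_RC = bytes.maketrans(b"ACGTRYSWKMBDHVN", b"TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.upper().encode()[::-1].translate(_RC).decode()


class KmerIndex:
    """Exact k-mer hash index over a catalog's (N-free) genome sequences."""

    def __init__(self, catalog: Catalog, k: int = DEFAULT_SEED_LENGTH):
        if k < 11:
            raise InvalidInputError(f"seed length {k} too short (minimum 11)")
        self.k = k
        self.genome_ids = catalog.genome_ids
        self.id_to_index = {g: i for i, g in enumerate(self.genome_ids)}
        self.seqs: list[bytes] = [r.sequence.encode() for r in catalog]
        self.arrays: list[np.ndarray] = [
            np.frombuffer(s, dtype=np.uint8) for s in self.seqs
        ]
        index: dict[bytes, list[tuple[int, int]]] = {}
        for gi, s in enumerate(self.seqs):
            for p in range(len(s) - k + 1):
                index.setdefault(s[p : p + k], []).append((gi, p))
        self._index = index

    def seed_hits(self, kmer: bytes) -> list[tuple[int, int]]:
        return self._index.get(kmer, ())


def _hamming(genome: bytes, arr: np.ndarray, start: int, read: bytes,
             read_arr: np.ndarray) -> int:
    if genome[start : start + len(read)] == read:
        return 0
    window = arr[start : start + len(read)]
    return int(np.count_nonzero(window != read_arr))


def _candidate_loci(index: KmerIndex, read: bytes, rl: int) -> set[tuple[int, int]]:
    k = index.k
    loci: set[tuple[int, int]] = set()
    for off in range(0, rl - k + 1, k):
        for gi, p in index.seed_hits(read[off : off + k]):
            start = p - off
            if 0 <= start <= len(index.seqs[gi]) - rl:
                loci.add((gi, start))
    return loci


def align_read(
    index: KmerIndex,
    read_id: str,
    sequence: str,
    mate: int = 0,
) -> list[AlignmentRecord]:
    """Align one read; returns all hit records, or a single unmapped record.

    Among mapped records the best-scoring one (ties: fewest mismatches, then
    smallest (genome_id, pos), forward before reverse) is primary; the rest
    are flagged secondary.
    """
    seq = sequence.upper()
    rl = len(seq)
    fwd = seq.encode()
    if rl < index.k:
        return [AlignmentRecord(read_id=read_id, mate=mate, is_mapped=False)]
    rev = fwd[::-1].translate(_RC)
    fwd_arr = np.frombuffer(fwd, dtype=np.uint8)
    rev_arr = np.frombuffer(rev, dtype=np.uint8)

    hits: list[AlignmentRecord] = []
    for is_rev, rbytes, rarr in ((False, fwd, fwd_arr), (True, rev, rev_arr)):
        for gi, start in _candidate_loci(index, rbytes, rl):
            mm = _hamming(index.seqs[gi], index.arrays[gi], start, rbytes, rarr)
            hits.append(
                AlignmentRecord(
                    read_id=read_id,
                    genome_id=index.genome_ids[gi],
                    pos=start + 1,
                    mapq=BUILTIN_MAPQ,
                    cigar=f"{rl}M",
                    mismatches=mm,
                    align_score=rl - MISMATCH_PENALTY * mm,
                    is_mapped=True,
                    is_reverse=is_rev,
                    mate=mate,
                    sequence=rbytes.decode(),
                )
            )
    if not hits:
        return [AlignmentRecord(read_id=read_id, mate=mate, is_mapped=False,
                                sequence=seq)]
    hits.sort(key=lambda r: (-(r.align_score or 0), r.mismatches,
                             r.genome_id, r.pos, r.is_reverse))
    return [hits[0]] + [
        replace(h, is_secondary_or_supplementary=True) for h in hits[1:]
    ]


def builtin_align(
    reads: Iterable[tuple],
    catalog: Catalog,
    seed_length: int = DEFAULT_SEED_LENGTH,
    index: KmerIndex | None = None,
) -> Iterator[AlignmentRecord]:
    """Align reads (tuples ``(read_id, sequence[, mate])``) against a catalog."""
    if index is None:
        index = KmerIndex(catalog, seed_length)
    for item in reads:
        read_id, sequence = item[0], item[1]
        mate = item[2] if len(item) > 2 else 0
        yield from align_read(index, read_id, sequence, mate)
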