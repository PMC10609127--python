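"""Read QC and post-alignment filtering.

The pipeline discards, in this order:

1. raw reads shorter than 60 bases or containing any N base (read-level QC,
   mirroring fastp's ``--length_required 60`` / ``--n_base_limit 0``);
2. alignment records with MAPQ < 5;
3. alignment records whose CIGAR contains a non-perfect-match operation
   (insertion, deletion, skipped region, soft clip, hard clip);
4. alignment records with more than three mismatches (NM-tag semantics;
   since indel CIGARs are already gone, NM equals the substitution count).

Among a read's surviving records only the single best alignment is kept,
under a fully deterministic ordering (alignment score, then mismatches, then
(genome_id, pos)).  Paired-end mates are counted as independent reads.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import CatalogMismatchError, CigarParseError, ContractViolationError

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class AlignmentRecord:
    """The fields of one SAM alignment line relevant to filtering."""

    read_id: str
    genome_id: str = "*"
    pos: int = 0  # 1-based leftmost reference coordinate; 0 when unmapped
    mapq: int = 0
    cigar: str = "*"
    mismatches: int = 0  # NM-tag semantics
    align_score: Optional[int] = None  # AS-tag semantics
    is_mapped: bool = True
    is_secondary_or_supplementary: bool = False
    is_reverse: bool = False
    mate: int = 0  # 1 or 2 for paired data, 0 otherwise
    sequence: Optional[str] = None  # oriented as aligned; optional

    @property
    def read_key(self) -> tuple[str, int]:
        """Identity of the underlying read; mates are independent reads."""
        return (self.read_id, self.mate)


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds for read QC and post-alignment filtering.

    Defaults reproduce the pipeline's published thresholds: MAPQ >= 5, no
    indel/skip/clip CIGAR operations, at most 3 mismatches, read length >= 60,
    zero N bases.
    """

    mapq_min: int = 5
    max_mismatches: int = 3
    forbidden_cigar_ops: frozenset[str] = frozenset("IDNSH")
    read_min_len: int = 60
    max_n_bases: int = 0


def qc_read(sequence: str, config: FilterConfig = FilterConfig()) -> bool:
    """Read-level QC predicate: keep iff long enough and N count within limit."""
    if len(sequence) < config.read_min_len:
        return False
    return sequence.upper().count("N") <= config.max_n_bases


def parse_cigar(cigar: str) -> list[tuple[int, str]]:
    """Parse a CIGAR string into (length, op) tuples; '*' parses to []."""
    if cigar == "*":
        return []
    ops = _CIGAR_RE.findall(cigar)
    if "".join(f"{n}{op}" for n, op in ops) != cigar:
        raise CigarParseError(f"unparsable CIGAR {cigar!r}")
    return [(int(n), op) for n, op in ops]


def passes_filters(rec: AlignmentRecord, config: FilterConfig = FilterConfig()) -> bool:
    """Post-alignment filter: MAPQ, perfect-match CIGAR, mismatch ceiling."""
    if rec.mapq < config.mapq_min:
        return False
    for _, op in parse_cigar(rec.cigar):
        if op in config.forbidden_cigar_ops:
            return False
    return rec.mismatches <= config.max_mismatches


def _best_key(rec: AlignmentRecord) -> tuple:
    # Higher score first (records without a score rank below any scored one),
    # then fewer mismatches, then lexicographically smallest (genome_id, pos).
    has_score = rec.align_score is not None
    return (
        0 if has_score else 1,
        -(rec.align_score if has_score else 0),
        rec.mismatches,
        rec.genome_id,
        rec.pos,
    )


def select_best(records: list[AlignmentRecord]) -> Optional[AlignmentRecord]:
    """Pick the single best alignment of one read; None for an empty list.

    Raises :class:`ContractViolationError` if records belong to different
    reads (mixed read_id or mate).
    """
    if not records:
        return None
    keys = {r.read_key for r in records}
    if len(keys) > 1:
        raise ContractViolationError(f"select_best got mixed reads: {sorted(keys)}")
    return min(records, key=_best_key)


@dataclass
class CountResult:
    """Per-genome mapped-read counts for one sample (or pooled subset)."""

    per_genome_mapped: dict[str, int]
    total_reads: int
    reads_kept: int = field(default=0)

    def __post_init__(self) -> None:
        kept = sum(self.per_genome_mapped.values())
        if self.reads_kept == 0:
            self.reads_kept = kept
        assert self.reads_kept == kept, "reads_kept inconsistent with counts"


def count_mapped(
    alignment_stream: Iterable[AlignmentRecord],
    catalog_ids: Iterable[str],
    config: FilterConfig = FilterConfig(),
    total_reads: int = 0,
) -> CountResult:
    """Count, per genome, the reads whose surviving best alignment lands on it.

    Every mapped record of a read (primary, secondary, supplementary alike) is
    a candidate mapping position; candidates failing the post-alignment
    filters are dropped, then :func:`select_best` picks at most one winner per
    read, so each read contributes at most once.  ``total_reads`` is the
    number of QC-passed reads that entered alignment (the mapping-rate
    denominator).
    """
    ids = list(catalog_ids)
    id_set = set(ids)
    groups: dict[tuple[str, int], list[AlignmentRecord]] = {}
    n_read_keys = 0
    for rec in alignment_stream:
        if not rec.is_mapped:
            groups.setdefault(rec.read_key, [])
            continue
        if rec.genome_id not in id_set:
            raise CatalogMismatchError(
                f"alignment references genome {rec.genome_id!r} absent from catalog"
            )
        groups.setdefault(rec.read_key, []).append(rec)
    n_read_keys = len(groups)
    if total_reads < n_read_keys:
        total_reads = max(total_reads, n_read_keys)
    counts = {g: 0 for g in ids}
    kept = 0
    for recs in groups.values():
        survivors = [r for r in recs if passes_filters(r, config)]
        best = select_best(survivors)
        if best is not None:
            counts[best.genome_id] += 1
            kept += 1
    return CountResult(per_genome_mapped=counts, total_reads=total_reads, reads_kept=kept)
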