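"""SAM reading and writing via pysam.

Coordinates follow SAM conventions (1-based in text, converted from pysam's
0-based ``reference_start``).  Only the fields the post-alignment filters
need are materialized: FLAG, RNAME, POS, MAPQ, CIGAR and the optional NM
(edit distance) and AS (alignment score) tags.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

import pysam

from .catalog import Catalog
from .filters import AlignmentRecord


def read_sam(path: str | Path) -> Iterator[AlignmentRecord]:
    """Stream AlignmentRecords from a SAM (or BAM) file."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for seg in fh:
            if seg.flag & 0x1:  # paired
                mate = 1 if seg.flag & 0x40 else (2 if seg.flag & 0x80 else 0)
            else:
                mate = 0
            if seg.is_unmapped:
                yield AlignmentRecord(
                    read_id=seg.query_name, mate=mate, is_mapped=False,
                    sequence=seg.query_sequence,
                )
                continue
            tags = dict(seg.get_tags())
            yield AlignmentRecord(
                read_id=seg.query_name,
                genome_id=seg.reference_name,
                pos=seg.reference_start + 1,
                mapq=seg.mapping_quality,
                cigar=seg.cigarstring or "*",
                mismatches=int(tags.get("NM", 0)),
                align_score=int(tags["AS"]) if "AS" in tags else None,
                is_mapped=True,
                is_secondary_or_supplementary=seg.is_secondary or seg.is_supplementary,
                is_reverse=seg.is_reverse,
                mate=mate,
                sequence=seg.query_sequence,
            )


def write_sam(
    records: Iterable[AlignmentRecord],
    catalog: Catalog,
    path: str | Path,
) -> int:
    """Write AlignmentRecords as SAM against a catalog's reference names.

    Returns the number of records written.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": r.genome_id, "LN": r.length} for r in catalog],
        }
    )
    n = 0
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in records:
            seg = pysam.AlignedSegment(header)
            seg.query_name = rec.read_id
            flag = 0
            if rec.mate in (1, 2):
                flag |= 0x1 | (0x40 if rec.mate == 1 else 0x80)
            if not rec.is_mapped:
                flag |= 0x4
            if rec.is_secondary_or_supplementary:
                flag |= 0x100
            if rec.is_reverse:
                flag |= 0x10
            seg.flag = flag
            if rec.is_mapped:
                seg.reference_id = header.get_tid(rec.genome_id)
                seg.reference_start = rec.pos - 1
                seg.mapping_quality = rec.mapq
                seg.cigarstring = rec.cigar
                tags = [("NM", rec.mismatches)]
                if rec.align_score is not None:
                    tags.append(("AS", rec.align_score))
                seg.set_tags(tags)
            if rec.sequence is not None:
                seg.query_sequence = rec.sequence
                seg.query_qualities = pysam.qualitystring_to_array(
                    "I" * len(rec.sequence)
                )
            out.write(seg)
            n += 1
    return n
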