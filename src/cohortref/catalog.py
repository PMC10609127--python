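"""Reference genome catalogs.

A *catalog* is an ordered set of reference genomes, each normalized to a
single gap-free sequence: assembly gaps (runs of ``N``) are removed and all
segments (chromosomes / scaffolds / contigs) are concatenated in input order
into one complete sequence.  Downstream alignment, ranking, and
reference-based encoding all operate on these normalized records, which
guarantees the emitted reference is N-free.

Non-N IUPAC ambiguity codes are retained: unlike assembly gaps they stand for
real (if uncertain) sequence.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO

from .errors import InvalidInputError

# IUPAC nucleotide one-letter codes (N handled separately as a gap character).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")

MANIFEST_COLUMNS = ("genome_id", "label", "length", "segment_count", "source")

FASTA_WRAP = 80


@dataclass(frozen=True)
class GenomeRecord:
    """One normalized reference genome: gap-free, single concatenated sequence."""

    genome_id: str
    label: str
    sequence: str
    segment_count: int = 1
    source: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Catalog:
    """Ordered collection of :class:`GenomeRecord` with deterministic iteration."""

    records: list[GenomeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.genome_id for r in self.records]
        dupes = {g for g in ids if ids.count(g) > 1}
        if dupes:
            raise InvalidInputError(f"duplicate genome_id(s) in catalog: {sorted(dupes)}")
        self._by_id = {r.genome_id: r for r in self.records}

    def __iter__(self) -> Iterator[GenomeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, genome_id: str) -> GenomeRecord:
        return self._by_id[genome_id]

    def __contains__(self, genome_id: str) -> bool:
        return genome_id in self._by_id

    @property
    def genome_ids(self) -> list[str]:
        return [r.genome_id for r in self.records]

    @property
    def total_bases(self) -> int:
        return sum(r.length for r in self.records)

    def subset(self, genome_ids: Sequence[str]) -> "Catalog":
        """Sub-catalog containing ``genome_ids`` in the given order."""
        missing = [g for g in genome_ids if g not in self._by_id]
        if missing:
            raise InvalidInputError(f"genome_id(s) not in catalog: {missing}")
        return Catalog([self._by_id[g] for g in genome_ids])


def normalize_genome(
    segments: Sequence[str],
    genome_id: str,
    label: str = "",
    source: str | None = None,
) -> GenomeRecord:
    """Normalize raw genome segments into a single gap-free record.

    Segments are uppercased and concatenated in order; every ``N`` (the
    assembly gap character) is removed.  Whitespace inside segments is
    ignored.  Non-N IUPAC ambiguity codes are kept.

    Raises
    ------
    InvalidInputError
        If ``segments`` is empty, a segment is empty after whitespace
        stripping, a non-IUPAC character occurs (the error names the
        character and segment index), or the normalized sequence is empty.
    """
    if not segments:
        raise InvalidInputError(f"genome {genome_id!r}: empty segment list")
    parts: list[str] = []
    for i, seg in enumerate(segments):
        cleaned = "".join(seg.split()).upper()
        if not cleaned:
            raise InvalidInputError(f"genome {genome_id!r}: segment {i} is empty")
        bad = set(cleaned) - IUPAC_CODES
        if bad:
            raise InvalidInputError(
                f"genome {genome_id!r}: non-IUPAC character {sorted(bad)[0]!r} "
                f"in segment {i}"
            )
        parts.append(cleaned.replace("N", ""))
    sequence = "".join(parts)
    if not sequence:
        raise InvalidInputError(
            f"genome {genome_id!r}: sequence empty after gap (N) removal"
        )
    return GenomeRecord(
        genome_id=genome_id,
        label=label,
        sequence=sequence,
        segment_count=len(segments),
        source=source,
    )


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _read_manifest_rows(manifest_path: str | Path) -> tuple[list[str], list[list[str]]]:
    with _open_text(manifest_path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise InvalidInputError(f"manifest {manifest_path} is empty")
    header = lines[0].split("\t")
    rows = [ln.split("\t") for ln in lines[1:]]
    return header, rows


def _genome_stem(path: Path) -> str:
    name = path.name
    for ext in (".gz",):
        if name.endswith(ext):
            name = name[: -len(ext)]
    for ext in (".fasta", ".fa", ".fna"):
        if name.endswith(ext):
            name = name[: -len(ext)]
    return name


def load_catalog(
    fasta_paths: Sequence[str | Path],
    manifest_path: str | Path | None = None,
) -> Catalog:
    """Load and normalize genomes from FASTA files.

    Grouping of FASTA records into genomes:

    * no manifest: each FASTA file is one genome; all of its records are that
      genome's segments, in file order, and the genome_id is the file stem;
    * manifest with a ``record_id`` column: records are grouped by the
      manifest's ``genome_id`` column (manifest order defines catalog order);
    * manifest without ``record_id`` (e.g. a manifest written by
      :func:`write_catalog`): each FASTA record id is its own genome_id and
      label/source metadata are joined from the manifest where present.
    """
    raw: dict[str, tuple[list[str], str, str | None]] = {}  # id -> (segments, label, source)
    order: list[str] = []

    def add_segment(gid: str, seq: str, label: str, source: str | None) -> None:
        if gid not in raw:
            raw[gid] = ([], label, source)
            order.append(gid)
        raw[gid][0].append(seq)

    # Parse all FASTA records up front, keyed by record id.
    records: list[tuple[str, str, str]] = []  # (record_id, description, seq)
    for path in fasta_paths:
        path = Path(path)
        try:
            with _open_text(path) as fh:
                file_records = [
                    (rec.id, rec.description, str(rec.seq))
                    for rec in SeqIO.parse(fh, "fasta")
                ]
        except (OSError, UnicodeDecodeError) as exc:
            raise InvalidInputError(f"cannot parse FASTA {path}: {exc}") from exc
        if not file_records:
            raise InvalidInputError(f"FASTA {path} contains no records")
        if manifest_path is None:
            gid = _genome_stem(path)
            if gid in raw:
                raise InvalidInputError(f"duplicate genome_id {gid!r} (one per file)")
            label = file_records[0][1]
            for _, _, seq in file_records:
                add_segment(gid, seq, label, None)
        else:
            records.extend(file_records)

    if manifest_path is not None:
        header, rows = _read_manifest_rows(manifest_path)
        col = {name: i for i, name in enumerate(header)}
        if "genome_id" not in col:
            raise InvalidInputError("manifest must have a genome_id column")
        by_record = {rid: (desc, seq) for rid, desc, seq in records}
        if len(by_record) != len(records):
            raise InvalidInputError("duplicate FASTA record ids with a manifest")

        def cell(row: list[str], name: str, default: str = "") -> str:
            i = col.get(name)
            return row[i] if i is not None and i < len(row) else default

        if "record_id" in col:
            for row in rows:
                rid = cell(row, "record_id")
                gid = cell(row, "genome_id")
                if rid not in by_record:
                    raise InvalidInputError(f"manifest record_id {rid!r} not in FASTA input")
                desc, seq = by_record[rid]
                add_segment(gid, seq, cell(row, "label") or desc, cell(row, "source") or None)
        else:
            meta = {cell(r, "genome_id"): r for r in rows}
            for rid, desc, seq in records:
                row = meta.get(rid)
                label = cell(row, "label") if row else desc
                source = (cell(row, "source") or None) if row else None
                if rid in raw:
                    raise InvalidInputError(f"duplicate genome_id {rid!r}")
                add_segment(rid, seq, label or desc, source)

    normalized = [
        normalize_genome(segs, gid, label=label, source=source)
        for gid, (segs, label, source) in ((g, raw[g]) for g in order)
    ]
    return Catalog(normalized)


def load_reference_fasta(path: str | Path) -> Catalog:
    """Load a multi-FASTA treating each record as its own (normalized) genome.

    This is the convention for emitted cohort references and compression
    references, where every record is already one whole genome.
    """
    with _open_text(path) as fh:
        recs = [
            normalize_genome([str(r.seq)], r.id, label=r.description)
            for r in SeqIO.parse(fh, "fasta")
        ]
    if not recs:
        raise InvalidInputError(f"FASTA {path} contains no records")
    return Catalog(recs)


def wrap_fasta(seq: str, width: int = FASTA_WRAP) -> str:
    return "\n".join(seq[i : i + width] for i in range(0, len(seq), width))


def write_catalog(
    catalog: Catalog,
    out_fasta: str | Path,
    out_manifest: str | Path,
) -> None:
    """Write one FASTA record per genome (80-column wrapped) plus a TSV manifest.

    Round-trips with ``load_catalog([out_fasta], manifest_path=out_manifest)``.
    """
    if len(catalog) == 0:
        raise InvalidInputError("refusing to write an empty catalog")
    with open(out_fasta, "w") as fa:
        for rec in catalog:
            header = f">{rec.genome_id}"
            if rec.label:
                header += f" {rec.label}"
            fa.write(header + "\n")
            fa.write(wrap_fasta(rec.sequence) + "\n")
    with open(out_manifest, "w") as mf:
        mf.write("\t".join(MANIFEST_COLUMNS) + "\n")
        for rec in catalog:
            mf.write(
                f"{rec.genome_id}\t{rec.label}\t{rec.length}\t"
                f"{rec.segment_count}\t{rec.source or ''}\n"
            )


def split_catalog(catalog: Catalog, k: int) -> list[Catalog]:
    """Partition a catalog into ``k`` sub-catalogs balanced by total bases.

    Deterministic greedy bin packing: genomes are taken largest first (ties by
    genome_id) and each is assigned to the currently lightest sub-catalog
    (ties by sub-catalog index).  Memory cost of aligner indexing scales with
    bases, hence balancing on bases rather than genome count.  Record order
    within each sub-catalog follows the input catalog order.
    """
    if not 1 <= k <= len(catalog):
        raise InvalidInputError(
            f"k={k} out of range for a catalog of {len(catalog)} genomes"
        )
    loads = [0] * k
    assignment: dict[str, int] = {}
    for rec in sorted(catalog, key=lambda r: (-r.length, r.genome_id)):
        lightest = min(range(k), key=lambda i: (loads[i], i))
        assignment[rec.genome_id] = lightest
        loads[lightest] += rec.length
    groups: list[list[GenomeRecord]] = [[] for _ in range(k)]
    for rec in catalog:  # preserve catalog order inside each sub-catalog
        groups[assignment[rec.genome_id]].append(rec)
    return [Catalog(g) for g in groups]
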