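"""Mapping-rate ranking and cohort-specific reference construction.

The mapping rate of a genome in a sample is the number of reads whose
surviving best alignment lands on that genome, divided by the total number of
(QC-passed) reads.  Counts from several samples are pooled (summed numerators
over summed denominators — robust to unequal sequencing depth), genomes are
ranked by pooled rate, and the top N are emitted as the cohort-specific
reference, a multi-FASTA used downstream as a compression reference.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .catalog import Catalog, wrap_fasta
from .errors import CatalogMismatchError, InvalidInputError
from .filters import AlignmentRecord, CountResult, FilterConfig, select_best

logger = logging.getLogger(__name__)

DEFAULT_TOP_N = 1000


@dataclass
class MappingRateTable:
    """Per-genome mapped counts and rates, sorted by rate descending.

    Ordering is deterministic: rate descending, ties broken by genome_id
    ascending.  ``sum(rate) <= 1`` since each read contributes to at most one
    genome.
    """

    rows: list[tuple[str, int, float]]  # (genome_id, mapped_reads, mapping_rate)
    total_reads: int
    sample_ids: list[str] = field(default_factory=list)

    @classmethod
    def from_counts(
        cls,
        counts: dict[str, int],
        total_reads: int,
        sample_ids: Sequence[str] = (),
    ) -> "MappingRateTable":
        if total_reads <= 0:
            raise InvalidInputError("total_reads must be positive")
        rows = sorted(
            ((g, c, c / total_reads) for g, c in counts.items()),
            key=lambda r: (-r[2], r[0]),
        )
        return cls(rows=rows, total_reads=total_reads, sample_ids=list(sample_ids))

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\tmapped_reads\tmapping_rate\n")
            for g, c, r in self.rows:
                fh.write(f"{g}\t{c}\t{r:.10g}\n")

    @classmethod
    def read_tsv(cls, path: str | Path, total_reads: int | None = None,
                 sample_ids: Sequence[str] = ()) -> "MappingRateTable":
        counts: dict[str, int] = {}
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            gi, ci = header.index("genome_id"), header.index("mapped_reads")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                counts[parts[gi]] = int(parts[ci])
        if total_reads is None:
            total_reads = max(1, sum(counts.values()))
        return cls.from_counts(counts, total_reads, sample_ids)


@dataclass
class CohortReference:
    """Ordered top-N genome selection with its captured mapping-rate mass."""

    genome_ids: list[str]
    n: int
    cumulative_rate: float
    rows: list[tuple[str, int, float]] = field(default_factory=list)
    fasta_path: Optional[Path] = None


def pool_samples(
    per_sample: Sequence[CountResult],
    sample_ids: Sequence[str] = (),
) -> MappingRateTable:
    """Pool per-sample counts: sum numerators, sum denominators, re-rank.

    All CountResults must be keyed against the same catalog; inconsistent key
    sets raise an error listing the symmetric difference.
    """
    if not per_sample:
        raise InvalidInputError("no samples to pool")
    keys = set(per_sample[0].per_genome_mapped)
    for cr in per_sample[1:]:
        other = set(cr.per_genome_mapped)
        if other != keys:
            raise CatalogMismatchError(
                f"inconsistent genome key sets across samples: "
                f"{sorted(keys ^ other)}"
            )
    pooled = {g: 0 for g in keys}
    total = 0
    for cr in per_sample:
        for g, c in cr.per_genome_mapped.items():
            pooled[g] += c
        total += cr.total_reads
    return MappingRateTable.from_counts(pooled, total, sample_ids)


def merge_subdb(
    per_subdb: Sequence[Sequence[AlignmentRecord]],
    config: FilterConfig = FilterConfig(),
    catalog_ids: Iterable[str] = (),
    total_reads: int = 0,
) -> CountResult:
    """Integrate per-read best alignments from disjoint sub-database runs.

    Each inner sequence holds, for one sub-database, every read's surviving
    best alignment there (i.e. the output of per-read filtering +
    ``select_best``).  For each read the global best across sub-databases is
    selected with the same deterministic ordering, so the result equals a
    monolithic run against the undivided database by construction.
    """
    seen_genomes: list[set[str]] = [
        {r.genome_id for r in recs if r.is_mapped} for recs in per_subdb
    ]
    for i in range(len(seen_genomes)):
        for j in range(i + 1, len(seen_genomes)):
            overlap = seen_genomes[i] & seen_genomes[j]
            if overlap:
                raise CatalogMismatchError(
                    f"sub-databases share genome_ids: {sorted(overlap)}"
                )
    by_read: dict[tuple[str, int], list[AlignmentRecord]] = {}
    for recs in per_subdb:
        for rec in recs:
            if rec.is_mapped:
                by_read.setdefault(rec.read_key, []).append(rec)
    counts = {g: 0 for g in catalog_ids}
    for g in set().union(*seen_genomes) if seen_genomes else set():
        counts.setdefault(g, 0)
    kept = 0
    for recs in by_read.values():
        best = select_best(list(recs))
        if best is not None:
            counts[best.genome_id] = counts.get(best.genome_id, 0) + 1
            kept += 1
    total = max(total_reads, len(by_read))
    return CountResult(per_genome_mapped=counts, total_reads=total, reads_kept=kept)


def top_n(table: MappingRateTable, n: int) -> CohortReference:
    """Select the top-n genomes by mapping rate.

    Genomes with zero mapped reads are excluded from the ranking proper; they
    are used only to pad (in genome_id order, with a logged warning) when
    fewer than n genomes have nonzero counts.
    """
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    if not table.rows:
        raise InvalidInputError("empty mapping-rate table")
    nonzero = [row for row in table.rows if row[1] > 0]
    zero = sorted((row for row in table.rows if row[1] == 0), key=lambda r: r[0])
    selected = nonzero[:n]
    if len(selected) < min(n, len(table.rows)):
        pad = zero[: min(n, len(table.rows)) - len(selected)]
        logger.warning(
            "only %d genomes have nonzero counts; padding top-%d with %d "
            "zero-count genomes in genome_id order",
            len(nonzero), n, len(pad),
        )
        selected = selected + pad
    return CohortReference(
        genome_ids=[g for g, _, _ in selected],
        n=n,
        cumulative_rate=sum(r for _, _, r in selected),
        rows=selected,
    )


def saturation_curve(table: MappingRateTable) -> list[tuple[int, float]]:
    """Cumulative mapping rate captured by the top-k genomes, for k = 1..rows.

    Monotone non-decreasing; the final value is the total captured rate
    (reads_kept / total_reads).  Used to choose the reference size N.
    """
    curve: list[tuple[int, float]] = []
    cum = 0.0
    for k, (_, _, rate) in enumerate(table.rows, start=1):
        cum += rate
        curve.append((k, cum))
    return curve


def write_saturation_tsv(curve: Sequence[tuple[int, float]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("k\tcumulative_mapping_rate\n")
        for k, c in curve:
            fh.write(f"{k}\t{c:.10g}\n")


def emit_reference(
    catalog: Catalog,
    ref: CohortReference,
    out_fasta: str | Path,
    out_tsv: str | Path | None = None,
) -> None:
    """Write the cohort-specific reference multi-FASTA (ranked order).

    Sequences are emitted exactly as stored in the catalog (already gap-free).
    A sidecar TSV (rank, genome_id, mapped_reads, mapping_rate) is written
    next to the FASTA unless ``out_tsv`` overrides the location.
    """
    missing = [g for g in ref.genome_ids if g not in catalog]
    if missing:
        raise CatalogMismatchError(f"genome_id(s) not in catalog: {missing}")
    out_fasta = Path(out_fasta)
    with open(out_fasta, "w") as fa:
        for gid in ref.genome_ids:
            rec = catalog[gid]
            header = f">{gid}"
            if rec.label:
                header += f" {rec.label}"
            fa.write(header + "\n")
            fa.write(wrap_fasta(rec.sequence) + "\n")
    ref.fasta_path = out_fasta
    if out_tsv is None:
        out_tsv = out_fasta.with_suffix(".ranks.tsv")
    stats = {g: (c, r) for g, c, r in ref.rows}
    with open(out_tsv, "w") as fh:
        fh.write("rank\tgenome_id\tmapped_reads\tmapping_rate\n")
        for rank, gid in enumerate(ref.genome_ids, start=1):
            c, r = stats.get(gid, (0, 0.0))
            fh.write(f"{rank}\t{gid}\t{c}\t{r:.10g}\n")
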