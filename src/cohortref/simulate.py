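"""Synthetic microbial communities with known truth.

Generates random reference genomes, a skewed (lognormal) community abundance
profile, and paired-end shotgun reads with substitution errors — plus
optional one-base indels and N bases to exercise the CIGAR and read-QC
filters — so every pipeline stage can be tested end-to-end without any
genome downloads.  All draws are deterministic under a seed.

The lognormal profile (default sigma 1.5) emulates the common observation in
shotgun metagenomes that a small number of species contributes most of the
community abundance; :func:`abundant_species_proportion` quantifies this as
the fraction of species needed to reach 80% of total abundance.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .align import reverse_complement
from .catalog import Catalog, normalize_genome
from .errors import InvalidInputError

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class CommunityProfile:
    """Relative abundances of the community's genomes (sum to 1)."""

    species: list[str]
    abundance: np.ndarray

    def __post_init__(self) -> None:
        self.abundance = np.asarray(self.abundance, dtype=float)
        if len(self.species) != len(self.abundance):
            raise InvalidInputError("species/abundance length mismatch")
        if len(self.species) == 0:
            raise InvalidInputError("empty profile")
        if np.any(self.abundance < 0):
            raise InvalidInputError("abundances must be nonnegative")
        if abs(float(self.abundance.sum()) - 1.0) > 1e-9:
            raise InvalidInputError("abundances must sum to 1")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\tabundance\n")
            for g, a in zip(self.species, self.abundance):
                fh.write(f"{g}\t{a:.10g}\n")


@dataclass(frozen=True)
class ReadSimConfig:
    """Noise and geometry parameters for paired-end read simulation.

    Defaults give 100-base reads (so the length-60 QC passes unless
    deliberately violated), a 300 +- 30 base insert, and a 0.5% per-base
    substitution rate; indels and N bases are off by default and exist only
    as explicit knobs for exercising the filters.
    """

    read_length: int = 100
    n_read_pairs: int = 10_000
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    sub_error_rate: float = 0.005
    indel_read_fraction: float = 0.0
    n_base_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sub_error_rate", "indel_read_fraction", "n_base_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise InvalidInputError(f"{name} must be in [0, 1), got {v}")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_genomes(
    n: int,
    length: int,
    seed: int,
    gap_fraction: float = 0.0,
) -> tuple[dict[str, list[str]], Catalog]:
    """Simulate ``n`` uniform-ACGT genomes of ``length`` bases.

    Returns the raw segment sets (with inserted N-run gaps when
    ``gap_fraction > 0``, to exercise normalization) and the truth catalog of
    normalized, gap-free records.  Gaps are additions: normalization always
    recovers exactly ``length`` bases per genome.
    """
    if n < 1 or length < 1000:
        raise InvalidInputError("need n >= 1 genomes of length >= 1000")
    rng = np.random.default_rng(seed)
    segments: dict[str, list[str]] = {}
    records = []
    for i in range(n):
        gid = f"g{i:03d}"
        seq = _random_sequence(rng, length)
        if gap_fraction > 0:
            n_gap_bases = int(round(gap_fraction * length))
            n_gaps = max(1, n_gap_bases // 50)
            cuts = np.sort(rng.integers(1, length, size=n_gaps))
            gap_lens = rng.multinomial(n_gap_bases, np.ones(n_gaps) / n_gaps)
            gapped_parts = []
            prev = 0
            for cut, gl in zip(cuts, gap_lens):
                gapped_parts.append(seq[prev:cut] + "N" * int(gl))
                prev = int(cut)
            gapped_parts.append(seq[prev:])
            gapped = "".join(gapped_parts)
            # split into up to 3 segments to exercise concatenation
            third = max(1, len(gapped) // 3)
            segs = [gapped[:third], gapped[third : 2 * third], gapped[2 * third :]]
            segs = [s for s in segs if s]
        else:
            segs = [seq]
        segments[gid] = segs
        records.append(normalize_genome(segs, gid, label=f"synthetic genome {i}"))
    return segments, Catalog(records)


def sample_profile(
    n_species: int,
    sigma: float = 1.5,
    seed: int = 0,
    species: Sequence[str] | None = None,
) -> CommunityProfile:
    """Skewed community profile: normalized lognormal(0, sigma) draws, sorted
    descending so the first species is the most abundant."""
    if n_species < 1:
        raise InvalidInputError("n_species must be >= 1")
    if sigma <= 0:
        raise InvalidInputError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    draws = rng.lognormal(mean=0.0, sigma=sigma, size=n_species)
    ab = np.sort(draws)[::-1]
    ab = ab / ab.sum()
    if species is None:
        species = [f"g{i:03d}" for i in range(n_species)]
    elif len(species) != n_species:
        raise InvalidInputError("species list length must equal n_species")
    return CommunityProfile(species=list(species), abundance=ab)


@dataclass
class SimulatedReads:
    """Paired reads plus per-mate truth rows (1-based fragment coordinates)."""

    r1: list[tuple[str, str]]  # (read_id, sequence), mate 1
    r2: list[tuple[str, str]]
    truth: list[tuple[str, int, str, int, str]]  # (read_id, mate, genome_id, pos, strand)

    def write(self, out_prefix: str | Path) -> dict[str, Path]:
        """Write gzipped paired FASTQ plus the truth TSV; returns the paths."""
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        paths = {
            "r1": Path(f"{prefix}_1.fastq.gz"),
            "r2": Path(f"{prefix}_2.fastq.gz"),
            "truth": Path(f"{prefix}.truth.tsv"),
        }
        for key, reads, mate in (("r1", self.r1, 1), ("r2", self.r2, 2)):
            with gzip.open(paths[key], "wt") as fh:
                for rid, seq in reads:
                    fh.write(f"@{rid}/{mate}\n{seq}\n+\n{'I' * len(seq)}\n")
        with open(paths["truth"], "w") as fh:
            fh.write("read_id\tmate\tgenome_id\tpos\tstrand\n")
            for rid, mate, gid, pos, strand in self.truth:
                fh.write(f"{rid}\t{mate}\t{gid}\t{pos}\t{strand}\n")
        return paths


def _inject_noise(
    rng: np.random.Generator,
    seq: str,
    sub_rate: float,
    do_indel: bool,
    do_n: bool,
) -> str:
    buf = bytearray(seq.encode())
    if sub_rate > 0:
        n_err = rng.binomial(len(buf), sub_rate)
        if n_err:
            for p in rng.choice(len(buf), size=n_err, replace=False):
                old = buf[p]
                choices = [b for b in b"ACGT" if b != old]
                buf[p] = choices[rng.integers(0, 3)]
    if do_indel:
        p = int(rng.integers(0, len(buf)))
        if rng.random() < 0.5:
            buf.insert(p, _BASES[rng.integers(0, 4)])
        else:
            del buf[p]
    if do_n:
        buf[int(rng.integers(0, len(buf)))] = ord("N")
    return buf.decode()


def simulate_reads(
    catalog: Catalog,
    profile: CommunityProfile,
    config: ReadSimConfig,
) -> SimulatedReads:
    """Simulate paired-end reads from a community.

    Per pair: the genome is drawn proportionally to abundance, the fragment
    start is uniform, mate 1 reads the forward strand from the fragment start
    and mate 2 the reverse strand from the fragment end.  Substitutions are
    i.i.d. per base; a fraction of reads receive one 1-base indel and/or one
    N base when configured.  Truth positions are 1-based on the normalized
    (gap-free) genome, matching SAM conventions.
    """
    missing = [g for g in profile.species if g not in catalog]
    if missing:
        raise InvalidInputError(f"profile species not in catalog: {missing}")
    rl = config.read_length
    min_len = config.insert_mean + 4 * config.insert_sd
    for gid in profile.species:
        if catalog[gid].length <= min_len:
            raise InvalidInputError(
                f"genome {gid} shorter than insert_mean + 4*insert_sd ({min_len:.0f})"
            )
    rng = np.random.default_rng(config.seed)
    n = config.n_read_pairs
    genome_idx = rng.choice(len(profile.species), size=n, p=profile.abundance)
    inserts = np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n))
    inserts = np.maximum(inserts, rl).astype(int)
    seqs = {g: catalog[g].sequence for g in profile.species}
    lengths = np.array([catalog[g].length for g in profile.species])
    starts = (rng.random(n) * (lengths[genome_idx] - inserts + 1)).astype(int)

    indel_mask1 = rng.random(n) < config.indel_read_fraction
    indel_mask2 = rng.random(n) < config.indel_read_fraction
    n_mask1 = rng.random(n) < config.n_base_fraction
    n_mask2 = rng.random(n) < config.n_base_fraction

    r1: list[tuple[str, str]] = []
    r2: list[tuple[str, str]] = []
    truth: list[tuple[str, int, str, int, str]] = []
    for i in range(n):
        gid = profile.species[genome_idx[i]]
        seq = seqs[gid]
        start, insert = int(starts[i]), int(inserts[i])
        rid = f"r{i:07d}"
        fwd = seq[start : start + rl]
        rev = reverse_complement(seq[start + insert - rl : start + insert])
        fwd = _inject_noise(rng, fwd, config.sub_error_rate,
                            bool(indel_mask1[i]), bool(n_mask1[i]))
        rev = _inject_noise(rng, rev, config.sub_error_rate,
                            bool(indel_mask2[i]), bool(n_mask2[i]))
        r1.append((rid, fwd))
        r2.append((rid, rev))
        truth.append((rid, 1, gid, start + 1, "+"))
        truth.append((rid, 2, gid, start + insert - rl + 1, "-"))
    return SimulatedReads(r1=r1, r2=r2, truth=truth)


def abundant_species_proportion(
    profile: CommunityProfile,
    threshold: float = 0.8,
) -> float:
    """Fraction of species forming the top ``threshold`` of total abundance.

    Abundances are ranked in decreasing order and the smallest prefix whose
    cumulative abundance reaches the threshold (the species first crossing
    the threshold is included) is divided by the total species count.
    """
    if not 0 < threshold <= 1:
        raise InvalidInputError(f"threshold must be in (0, 1], got {threshold}")
    ab = np.sort(np.asarray(profile.abundance, dtype=float))[::-1]
    cum = np.cumsum(ab)
    m = int(np.searchsorted(cum, threshold - 1e-12)) + 1
    m = min(m, len(ab))
    return m / len(ab)
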