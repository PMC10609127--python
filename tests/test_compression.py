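import gzip

import numpy as np
import pytest

from cohortref import (
    EncodedRead,
    KmerIndex,
    ReadSimConfig,
    compress_fastq,
    compression_ratio,
    decode_reads,
    decompress_fastq,
    deserialize_container,
    encode_reads,
    reverse_complement,
    run_external_compressor,
    serialize_container,
    simulate_reads,
)
from cohortref.compression import encode_read, pack_2bit, unpack_2bit
from cohortref.errors import (
    CorruptStreamError,
    ExternalToolNotFoundError,
    InvalidInputError,
    ReferenceChecksumError,
)


@pytest.fixture(scope="module")
def reference():
    from cohortref import simulate_genomes

    _, cat = simulate_genomes(3, 3000, seed=8)
    return cat


@pytest.fixture(scope="module")
def index(reference):
    return KmerIndex(reference)


class TestEncodeDecode:
    def test_perfect_read_has_no_diffs(self, reference, index):
        g = reference.records[0]
        er = encode_read(index, g.sequence[100:200])
        assert er.mode == "REF" and er.diffs == ()
        assert er.pos == 101 and er.strand == "+"

    def test_random_read_falls_back_to_raw(self, index):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        er = encode_read(index, seq)
        assert er.mode == "RAW" and er.sequence == seq

    def test_single_substitution_single_diff(self, reference, index):
        g = reference.records[1]
        read = list(g.sequence[50:150])
        read[73] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[73]]
        er = encode_read(index, "".join(read))
        assert er.mode == "REF"
        assert er.diffs == ((73, read[73]),)

    def test_reverse_strand_round_trip(self, reference, index):
        g = reference.records[2]
        read = reverse_complement(g.sequence[200:300])
        er = encode_read(index, read)
        assert er.mode == "REF" and er.strand == "-"
        [decoded] = decode_reads([er], reference)
        assert decoded == read

    def test_too_many_diffs_raw(self, reference, index):
        read = list(reference.records[0].sequence[0:100])
        for off in (30, 45, 60, 75):  # 4 substitutions > max_diffs=3
            read[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[off]]
        er = encode_read(index, "".join(read))
        assert er.mode == "RAW"

    def test_lossless_on_simulated_community(self, small_community):
        catalog, profile = small_community
        cfg = ReadSimConfig(n_read_pairs=300, sub_error_rate=0.01, seed=3)
        sim = simulate_reads(catalog, profile, cfg)
        rng = np.random.default_rng(0)
        # mix in unmappable reads to force RAW fallback
        extras = [
            (f"x{i}", "".join(rng.choice(list("ACGT"), size=100))) for i in range(30)
        ]
        reads = sim.r1 + sim.r2 + extras
        stream = list(encode_reads(reads, catalog))
        modes = {er.mode for er in stream}
        assert modes == {"REF", "RAW"}
        decoded = list(decode_reads(stream, catalog))
        assert decoded == [seq for _, seq in reads]

    def test_empty_stream(self, reference):
        assert list(decode_reads([], reference)) == []

    def test_corrupt_records_rejected(self, reference):
        too_far = EncodedRead(mode="REF", genome_index=0, pos=2999, length=100)
        with pytest.raises(CorruptStreamError):
            list(decode_reads([too_far], reference))
        bad_genome = EncodedRead(mode="REF", genome_index=9, pos=1, length=50)
        with pytest.raises(CorruptStreamError):
            list(decode_reads([bad_genome], reference))


class TestContainer:
    def test_round_trip_through_file(self, tmp_path, reference, index):
        reads = [("r%d" % i, reference.records[i % 3].sequence[i : i + 100])
                 for i in range(50)]
        stream = list(encode_reads(reads, reference, index=index))
        out = tmp_path / "c.crz"
        size = serialize_container(stream, reference, out)
        assert size == out.stat().st_size >= 21
        back, ids, quals = deserialize_container(out, reference)
        assert back == stream
        assert list(decode_reads(back, reference)) == [s for _, s in reads]

    def test_checksum_refusal(self, tmp_path, reference):
        from cohortref import simulate_genomes

        out = tmp_path / "c.crz"
        serialize_container([], reference, out)
        _, other = simulate_genomes(2, 1500, seed=99)
        with pytest.raises(ReferenceChecksumError):
            deserialize_container(out, other)

    def test_ref_records_beat_two_bit_packing(self, tmp_path, reference, index):
        # perfect-match reads: positional encoding must undercut 2-bit packing
        reads = [("r%d" % i, reference.records[0].sequence[i * 25 : i * 25 + 100])
                 for i in range(100)]
        stream = list(encode_reads(reads, reference, index=index))
        assert all(er.mode == "REF" and not er.diffs for er in stream)
        container_size = serialize_container(stream, reference, tmp_path / "c.crz")
        two_bit_size = sum(len(pack_2bit(s)) for _, s in reads)
        assert container_size < two_bit_size

    def test_two_bit_pack_round_trip(self):
        seq = "ACGTGGTACACGT"
        assert unpack_2bit(pack_2bit(seq), len(seq)) == seq
        assert pack_2bit("ACGTN") is None


def _write_fastq(path, reads, gz=False):
    opener = gzip.open if gz else open
    with opener(path, "wt") as fh:
        for rid, seq in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


class TestFastqLevel:
    def test_fastq_round_trip(self, tmp_path, reference):
        reads = [("read%d" % i, reference.records[i % 3].sequence[i : i + 100])
                 for i in range(40)]
        fq = tmp_path / "in.fastq"
        _write_fastq(fq, reads)
        report = compress_fastq(fq, reference, tmp_path / "out.crz")
        assert report.reads_ref_encoded == 40 and report.reads_raw == 0
        assert report.ratio > 1
        out_fq = tmp_path / "back.fastq"
        decompress_fastq(tmp_path / "out.crz", reference, out_fq)
        assert out_fq.read_text() == fq.read_text()


class TestCompressionRatio:
    def test_definition(self, tmp_path):
        a = tmp_path / "orig"
        b = tmp_path / "comp"
        a.write_bytes(b"x" * 1_000_000)
        b.write_bytes(b"y" * 100_000)
        assert compression_ratio(a, b).ratio == 10.0

    def test_identity_and_scale_invariance(self, tmp_path):
        a = tmp_path / "orig"
        a.write_bytes(b"z" * 4096)
        assert compression_ratio(a, a).ratio == 1.0
        a2, b2 = tmp_path / "o2", tmp_path / "c2"
        a2.write_bytes(b"x" * 2000)
        b2.write_bytes(b"y" * 500)
        a4, b4 = tmp_path / "o4", tmp_path / "c4"
        a4.write_bytes(b"x" * 4000)
        b4.write_bytes(b"y" * 1000)
        assert compression_ratio(a2, b2).ratio == compression_ratio(a4, b4).ratio

    def test_missing_file(self, tmp_path):
        a = tmp_path / "orig"
        a.write_bytes(b"x")
        with pytest.raises(FileNotFoundError):
            compression_ratio(a, tmp_path / "absent")

    def test_gzip_size_cross_check(self, tmp_path):
        import os

        src = tmp_path / "f.fastq"
        _write_fastq(src, [("r", "ACGT" * 100)] * 20)
        gz = tmp_path / "f.gz"
        with open(src, "rb") as fi, gzip.open(gz, "wb") as fo:
            fo.write(fi.read())
        rep = compression_ratio(src, gz)
        assert rep.ratio == os.stat(src).st_size / os.stat(gz).st_size


class TestExternalAdapters:
    def test_gzip_adapter(self, tmp_path):
        fq = tmp_path / "s.fastq"
        _write_fastq(fq, [("r%d" % i, "ACGTACGTAA" * 10) for i in range(50)])
        rep = run_external_compressor("gzip", fq, out=tmp_path / "s.gz")
        assert rep.ratio > 1
        assert rep.command.startswith("gzip")

    def test_absent_tool_named(self, tmp_path, monkeypatch):
        fq = tmp_path / "s.fastq"
        _write_fastq(fq, [("r", "ACGT" * 30)])
        monkeypatch.setattr("shutil.which", lambda _: None)
        with pytest.raises(ExternalToolNotFoundError, match="gzip"):
            run_external_compressor("gzip", fq)

    def test_unknown_adapter(self, tmp_path):
        fq = tmp_path / "s.fastq"
        _write_fastq(fq, [("r", "ACGT" * 30)])
        with pytest.raises(InvalidInputError):
            run_external_compressor("xz", fq)
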