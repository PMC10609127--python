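import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from cohortref import (
    AlignmentRecord,
    CountResult,
    FilterConfig,
    count_mapped,
    passes_filters,
    qc_read,
    select_best,
)
from cohortref.errors import (
    CatalogMismatchError,
    CigarParseError,
    ContractViolationError,
)


def rec(read_id="r1", genome_id="g1", pos=1, mapq=60, cigar="100M",
        mismatches=0, align_score=None, mate=0, **kw):
    return AlignmentRecord(
        read_id=read_id, genome_id=genome_id, pos=pos, mapq=mapq, cigar=cigar,
        mismatches=mismatches, align_score=align_score, mate=mate, **kw,
    )


class TestQcRead:
    @pytest.mark.parametrize(
        "seq, keep",
        [
            ("A" * 100, True),
            ("A" * 60, True),   # boundary: minimum length passes
            ("A" * 59, False),  # below minimum length
            ("A" * 50 + "N" + "A" * 49, False),  # a single N fails
        ],
    )
    def test_defaults(self, seq, keep):
        assert qc_read(seq) is keep

    def test_thresholds_configurable(self):
        cfg = FilterConfig(read_min_len=30, max_n_bases=2)
        assert qc_read("A" * 29 + "NN", cfg) is True
        assert qc_read("A" * 29 + "NNN", cfg) is False


class TestPassesFilters:
    @pytest.mark.parametrize(
        "mapq, cigar, nm, expected",
        [
            (60, "100M", 0, True),    # perfect alignment
            (5, "100M", 0, True),     # MAPQ boundary: 5 passes
            (4, "100M", 0, False),    # MAPQ < 5
            (60, "50M1I49M", 1, False),   # insertion
            (60, "50M1D50M", 1, False),   # deletion
            (60, "50M100N50M", 0, False),  # skipped region
            (60, "5S95M", 0, False),  # soft clip
            (60, "5H95M", 0, False),  # hard clip
            (60, "100M", 3, True),    # mismatch boundary: 3 passes
            (60, "100M", 4, False),   # more than three mismatches
            (60, "60=40X", 2, True),  # = and X count as match operations
        ],
    )
    def test_rules(self, mapq, cigar, nm, expected):
        assert passes_filters(rec(mapq=mapq, cigar=cigar, mismatches=nm)) is expected

    def test_unparsable_cigar(self):
        with pytest.raises(CigarParseError):
            passes_filters(rec(cigar="100Q"))
        with pytest.raises(CigarParseError):
            passes_filters(rec(cigar="M100"))

    @given(
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=6),
    )
    def test_tightening_is_monotone(self, mapq, nm):
        loose = FilterConfig(mapq_min=0, max_mismatches=6)
        tight = FilterConfig(mapq_min=20, max_mismatches=1)
        r = rec(mapq=mapq, mismatches=nm)
        if passes_filters(r, tight):
            assert passes_filters(r, loose)


class TestSelectBest:
    def test_empty_and_singleton(self):
        assert select_best([]) is None
        only = rec()
        assert select_best([only]) is only

    def test_score_dominates(self):
        a = rec(genome_id="g2", align_score=95)
        b = rec(genome_id="g1", align_score=90, mismatches=0)
        assert select_best([a, b]) is a

    def test_unscored_ranks_below_scored(self):
        scored = rec(genome_id="g2", align_score=10, mismatches=3)
        unscored = rec(genome_id="g1", align_score=None, mismatches=0)
        assert select_best([scored, unscored]) is scored

    def test_mismatch_tiebreak_then_coordinates(self):
        worse = rec(genome_id="g1", mismatches=3)
        better = rec(genome_id="g2", mismatches=1)
        assert select_best([worse, better]) is better
        tie_a = rec(genome_id="g2", pos=5)
        tie_b = rec(genome_id="g1", pos=9)
        assert select_best([tie_a, tie_b]) is tie_b  # smaller (genome_id, pos)

    def test_mixed_reads_rejected(self):
        with pytest.raises(ContractViolationError):
            select_best([rec(read_id="a"), rec(read_id="b")])
        with pytest.raises(ContractViolationError):
            select_best([rec(mate=1), rec(mate=2)])


class TestCountMapped:
    def test_simple_stream(self):
        stream = [rec(read_id=f"r{i}") for i in range(10)]
        res = count_mapped(stream, ["g1", "g2"], total_reads=20)
        assert res.per_genome_mapped == {"g1": 10, "g2": 0}
        assert res.reads_kept == 10
        assert res.total_reads == 20

    def test_empty_stream(self):
        res = count_mapped([], ["g1"], total_reads=5)
        assert res.per_genome_mapped == {"g1": 0}
        assert res.reads_kept == 0

    def test_one_contribution_per_read(self):
        stream = [
            rec(read_id="r1", genome_id="g1", align_score=90),
            rec(read_id="r1", genome_id="g2", align_score=95),
        ]
        res = count_mapped(stream, ["g1", "g2"], total_reads=1)
        assert sum(res.per_genome_mapped.values()) == 1
        assert res.per_genome_mapped["g2"] == 1

    def test_mates_counted_independently(self):
        stream = [
            rec(read_id="r1", mate=1, genome_id="g1"),
            rec(read_id="r1", mate=2, genome_id="g2"),
        ]
        res = count_mapped(stream, ["g1", "g2"], total_reads=2)
        assert res.per_genome_mapped == {"g1": 1, "g2": 1}

    def test_unknown_genome_errors(self):
        with pytest.raises(CatalogMismatchError, match="g9"):
            count_mapped([rec(genome_id="g9")], ["g1"], total_reads=1)

    def test_unmapped_and_failing_records_ignored(self):
        stream = [
            AlignmentRecord(read_id="r1", is_mapped=False),
            rec(read_id="r2", mapq=2),
            rec(read_id="r3", cigar="5S95M"),
        ]
        res = count_mapped(stream, ["g1"], total_reads=3)
        assert res.reads_kept == 0

    @given(st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=20),   # read number
            st.sampled_from(["g1", "g2", "g3"]),
            st.integers(min_value=0, max_value=10),   # mapq
            st.integers(min_value=0, max_value=5),    # mismatches
        ),
        max_size=40,
    ))
    def test_conservation_and_order_invariance(self, raw):
        stream = [
            rec(read_id=f"r{i}", genome_id=g, mapq=q, mismatches=nm, pos=j + 1)
            for j, (i, g, q, nm) in enumerate(raw)
        ]
        res = count_mapped(stream, ["g1", "g2", "g3"], total_reads=30)
        assert sum(res.per_genome_mapped.values()) == res.reads_kept
        assert res.reads_kept <= res.total_reads
        shuffled = stream[:]
        random.Random(0).shuffle(shuffled)
        res2 = count_mapped(shuffled, ["g1", "g2", "g3"], total_reads=30)
        assert res2.per_genome_mapped == res.per_genome_mapped

    @given(st.lists(
        st.tuples(
            st.integers(min_value=0, max_value=15),
            st.integers(min_value=0, max_value=10),
            st.integers(min_value=0, max_value=5),
        ),
        max_size=30,
    ))
    def test_filter_monotonicity(self, raw):
        stream = [
            rec(read_id=f"r{i}", mapq=q, mismatches=nm)
            for i, q, nm in raw
        ]
        kept = {}
        for mapq_min, max_mm in [(0, 5), (5, 3), (8, 1)]:
            cfg = FilterConfig(mapq_min=mapq_min, max_mismatches=max_mm)
            kept[(mapq_min, max_mm)] = count_mapped(
                stream, ["g1"], cfg, total_reads=20
            ).reads_kept
        assert kept[(0, 5)] >= kept[(5, 3)] >= kept[(8, 1)]
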