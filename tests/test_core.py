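"""Tag container, FASTQ decoding, collapsing and normalization."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bolmir.core import (
    FastqParseError,
    PipelineConfig,
    SmallRNARead,
    collapse_tags,
    length_distribution,
    normalize_counts,
    read_fastq,
    revcomp,
    rna,
)


def _write(tmp_path, text):
    p = tmp_path / "reads.fastq"
    p.write_text(text)
    return p


class TestReadFastq:
    def test_phred33_decoding(self, tmp_path):
        recs = list(read_fastq(_write(tmp_path, "@r1\nACGT\n+\nIIII\n")))
        assert len(recs) == 1
        assert recs[0].seq == "ACGT"
        assert recs[0].qual == (40, 40, 40, 40)

    def test_length_mismatch_names_record(self, tmp_path):
        with pytest.raises(FastqParseError, match="record 0"):
            list(read_fastq(_write(tmp_path, "@r1\nACGT\n+\nIII\n")))

    def test_truncated_record(self, tmp_path):
        with pytest.raises(FastqParseError, match="record 1"):
            list(read_fastq(_write(tmp_path, "@r1\nACGT\n+\nIIII\n@r2\nACGT\n")))

    def test_empty_file_is_empty_stream(self, tmp_path):
        assert list(read_fastq(_write(tmp_path, ""))) == []


class TestSmallRNARead:
    def test_invariants(self):
        with pytest.raises(ValueError):
            SmallRNARead("r", "ACG", (40, 40))
        with pytest.raises(ValueError):
            SmallRNARead("r", "", ())


class TestCollapse:
    def test_counting(self):
        t = collapse_tags({"lib1": ["ACGU", "ACGU", "GGGC"]})
        by = t.by_seq()
        assert by["ACGU"].counts == {"lib1": 2}
        assert by["GGGC"].counts == {"lib1": 1}

    def test_t_u_identified(self):
        t = collapse_tags({"lib1": ["ACGT", "ACGU"]})
        assert len(t.tags) == 1
        assert t.tags[0].counts["lib1"] == 2

    def test_shared_tag_across_libraries(self):
        t = collapse_tags({"L1": ["ACGU"], "L2": ["ACGU", "ACGU"]})
        assert len(t.tags) == 1
        assert t.tags[0].counts == {"L1": 1, "L2": 2}

    def test_empty_input(self):
        t = collapse_tags({})
        assert t.tags == []

    @given(
        st.dictionaries(
            st.sampled_from(["L1", "L2", "L3"]),
            st.lists(st.text(alphabet="ACGU", min_size=1, max_size=8), max_size=30),
            min_size=1,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_conserves_reads(self, reads):
        table = collapse_tags(reads)
        for lib, lst in reads.items():
            assert sum(t.counts.get(lib, 0) for t in table.tags) == len(lst)


class TestNormalize:
    def test_rpm(self):
        t = collapse_tags({"L1": ["ACGU"] * 50})
        t.library_totals["L1"] = 500_000
        normalize_counts(t)
        assert t.tags[0].norm["L1"] == pytest.approx(100.0)

    def test_mean_over_all_libraries_including_zeros(self):
        t = collapse_tags({"L1": ["ACGU"] * 10, "L2": []})
        t.library_totals = {"L1": 1_000_000, "L2": 1_000_000}
        normalize_counts(t)
        tag = t.tags[0]
        assert tag.norm == {"L1": 10.0, "L2": 0.0}
        assert tag.mean_norm == pytest.approx(5.0)

    def test_zero_total_errors(self):
        t = collapse_tags({"L1": []})
        with pytest.raises(ValueError):
            normalize_counts(t)

    @given(st.integers(1, 1000), st.integers(1, 10))
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, count, c):
        t1 = collapse_tags({"L1": ["ACGU"] * count})
        t1.library_totals["L1"] = 10_000
        t2 = collapse_tags({"L1": ["ACGU"] * (count * c)})
        t2.library_totals["L1"] = 10_000 * c
        normalize_counts(t1)
        normalize_counts(t2)
        assert t1.tags[0].norm["L1"] == pytest.approx(t2.tags[0].norm["L1"])

    def test_norm_sum_identical_across_full_libraries(self):
        t = collapse_tags({"L1": ["ACGU", "GGCC", "ACGU"], "L2": ["AAAA"] * 7})
        normalize_counts(t)
        s1 = sum(tag.norm["L1"] for tag in t.tags)
        s2 = sum(tag.norm["L2"] for tag in t.tags)
        assert s1 == pytest.approx(s2, rel=1e-6)


class TestLengthDistribution:
    def test_unweighted(self):
        t = collapse_tags({"L1": ["A" * 21, "C" * 21, "G" * 24]})
        d = length_distribution(t)
        assert d[21] == pytest.approx(2 / 3)
        assert d[24] == pytest.approx(1 / 3)

    def test_single_tag(self):
        t = collapse_tags({"L1": ["ACGUA"]})
        assert length_distribution(t) == {5: 1.0}

    def test_weighted(self):
        t = collapse_tags({"L1": ["A" * 21] * 90 + ["G" * 24] * 10})
        d = length_distribution(t, weighted=True)
        assert d == {21: pytest.approx(0.9), 24: pytest.approx(0.1)}

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            length_distribution(collapse_tags({}))

    def test_fractions_sum_to_one(self, small_sim):
        _, _, _, truth, libs = small_sim
        t = collapse_tags({lib: [r.seq[:21] for r in reads] for lib, reads in libs.items()})
        for weighted in (False, True):
            d = length_distribution(t, weighted=weighted)
            assert all(v >= 0 for v in d.values())
            assert math.isclose(sum(d.values()), 1.0, abs_tol=1e-9)


def test_revcomp_involution():
    assert revcomp(revcomp("ACGUUGCA")) == "ACGUUGCA"
    assert revcomp("AUGC") == "GCAU"
    assert rna("acgt") == "ACGU"


def test_config_invariants():
    with pytest.raises(ValueError):
        PipelineConfig(seed_start=8, seed_end=2)
    with pytest.raises(ValueError):
        PipelineConfig(precursor_mfe_max=5.0)
    with pytest.raises(ValueError):
        PipelineConfig(min_duplex_pairs=-1)
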